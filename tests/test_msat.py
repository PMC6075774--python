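import itertools
import math

import numpy as np
import pytest
from oracles_util import brute_force_exclusion, equifrequent_summaries

from pedqg import msat
from pedqg.msat import (
    CATEGORIES,
    GenotypeError,
    GenotypeTable,
    assign_parentage,
    classify_relationship,
    combined_exclusion,
    estimate_null_allele_frequency,
    exclusion_probabilities,
    expected_heterozygosity,
    hwe_exact_test,
    locus_summary,
    pair_genotype_probability,
    pair_log_likelihood,
    partition_full_sibs,
)


def _table(genos, loci=("L1",)):
    """GenotypeTable from {id: ((a,b), ...)} per locus tuples."""
    ids = list(genos)
    arr = np.array([genos[i] for i in ids], dtype=np.int64)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    return GenotypeTable(ids, list(loci), arr)


def _all_genotypes(alleles):
    return [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]


# ---------------------------------------------------------------------------
# pair likelihoods


class TestPairProbability:
    # hand-enumerated values for (AA, AA) at a biallelic locus with p = 0.5
    @pytest.mark.parametrize(
        "cat,expected",
        [("U", 0.0625), ("HS", 0.09375), ("FS", 0.140625), ("PO", 0.125)],
    )
    def test_worked_example(self, cat, expected):
        freqs = {1: 0.5, 2: 0.5}
        assert pair_genotype_probability((1, 1), (1, 1), freqs, CATEGORIES[cat]) == expected

    @pytest.mark.parametrize("n_alleles", [2, 3, 4, 6])
    @pytest.mark.parametrize("cat", list(CATEGORIES))
    def test_normalization(self, cat, n_alleles, rng):
        raw = rng.dirichlet(np.ones(n_alleles))
        freqs = {a + 1: float(p) for a, p in enumerate(raw)}
        genos = _all_genotypes(sorted(freqs))
        total = sum(
            pair_genotype_probability(g1, g2, freqs, CATEGORIES[cat])
            for g1 in genos
            for g2 in genos
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        freqs = {1: 0.2, 2: 0.3, 3: 0.5}
        genos = _all_genotypes([1, 2, 3])
        for cat in CATEGORIES:
            for g1, g2 in itertools.product(genos, repeat=2):
                assert pair_genotype_probability(
                    g1, g2, freqs, CATEGORIES[cat]
                ) == pytest.approx(
                    pair_genotype_probability(g2, g1, freqs, CATEGORIES[cat]), abs=1e-14
                )

    def test_monomorphic_locus_equal_across_categories(self):
        freqs = {7: 1.0}
        vals = {
            cat: pair_genotype_probability((7, 7), (7, 7), freqs, CATEGORIES[cat])
            for cat in CATEGORIES
        }
        assert len(set(vals.values())) == 1


class TestClassify:
    def test_monomorphic_tie_returns_U(self):
        gt = _table({"a": (3, 3), "b": (3, 3)})
        summ = {"L1": msat.LocusSummary("L1", {3: 1.0}, 1, 2, 0.0, 0.0)}
        res = classify_relationship(gt, "a", "b", summ)
        assert res.category == "U"

    def test_identical_multilocus_prefers_relatives(self, rng):
        summ = equifrequent_summaries(7, 8)
        g = rng.integers(1, 9, size=(7, 2))
        gt = GenotypeTable(["a", "b"], list(summ), np.stack([g, g]))
        res = classify_relationship(gt, "a", "b", summ)
        assert res.category in ("FS", "PO")
        assert res.llr("U") > 0

    def test_unrelated_majority(self, rng):
        summ = equifrequent_summaries(7, 8)
        hits = 0
        n = 300
        for _ in range(n):
            g1 = rng.integers(1, 9, size=(7, 2))
            g2 = rng.integers(1, 9, size=(7, 2))
            gt = GenotypeTable(["a", "b"], list(summ), np.stack([g1, g2]))
            if classify_relationship(gt, "a", "b", summ).category == "U":
                hits += 1
        assert hits > n / 2

    def test_po_pairs_never_unrelated(self, rng):
        """Simulated parent-offspring pairs share an allele everywhere, so U
        (which the data cannot exclude only by chance) never wins."""
        summ = equifrequent_summaries(7, 8)
        for _ in range(200):
            parent = rng.integers(1, 9, size=(7, 2))
            off = np.stack(
                [parent[np.arange(7), rng.integers(0, 2, 7)], rng.integers(1, 9, 7)],
                axis=1,
            )
            gt = GenotypeTable(["p", "o"], list(summ), np.stack([parent, off]))
            assert classify_relationship(gt, "p", "o", summ).category != "U"

    def test_no_shared_loci_raises(self):
        gt = _table({"a": (1, 1), "b": (0, 0)})
        summ = {"L1": msat.LocusSummary("L1", {1: 1.0}, 1, 1, 0.0, 0.0)}
        with pytest.raises(GenotypeError):
            pair_log_likelihood(gt, "a", "b", "U", summ)


# ---------------------------------------------------------------------------
# locus summaries


class TestLocusSummary:
    def test_monomorphic(self):
        gt = _table({"a": (1, 1), "b": (1, 1), "c": (1, 1)})
        s = locus_summary(gt, "L1")
        assert s.freqs == {1: 1.0}
        assert s.ho == 0.0
        assert s.he == 0.0
        assert s.hwe_p == 1.0
        assert s.p_null == 0.0

    def test_two_heterozygotes(self):
        gt = _table({"a": (1, 2), "b": (1, 2)})
        s = locus_summary(gt, "L1")
        assert s.freqs == {1: 0.5, 2: 0.5}
        assert s.ho == 1.0

    def test_unbiased_he(self):
        # n = 2, p = q = 0.5: He = (4/3) * 0.5 = 2/3
        assert expected_heterozygosity({1: 0.5, 2: 0.5}, 2) == pytest.approx(2 / 3)

    def test_all_missing_errors(self):
        gt = _table({"a": (0, 0), "b": (0, 0)})
        with pytest.raises(GenotypeError):
            locus_summary(gt, "L1")

    def test_frequencies_sum_with_null(self, rng):
        gt = _table(
            {f"i{k}": tuple(sorted(rng.integers(1, 5, 2))) for k in range(60)}
        )
        s = locus_summary(gt, "L1")
        assert sum(s.freqs_with_null.values()) == pytest.approx(1.0, abs=1e-9)


class TestHWE:
    def test_biallelic_matches_dfs_enumeration(self, rng):
        from pedqg.msat import _enumerate_tables, _log_table_probability

        for _ in range(5):
            genos = [tuple(sorted(rng.integers(1, 3, 2))) for _ in range(25)]
            closed = hwe_exact_test(genos)
            ac: dict[int, int] = {}
            obs: dict[tuple[int, int], int] = {}
            for a, b in genos:
                ac[a] = ac.get(a, 0) + 1
                ac[b] = ac.get(b, 0) + 1
                obs[(min(a, b), max(a, b))] = obs.get((min(a, b), max(a, b)), 0) + 1
            if len(ac) < 2:
                continue
            lp_obs = _log_table_probability(obs, len(genos), ac)
            p_dfs = sum(
                math.exp(lp)
                for tab in _enumerate_tables(sorted(ac), ac, 10**6)
                for lp in [_log_table_probability(tab, len(genos), ac)]
                if lp <= lp_obs + 1e-9
            )
            assert closed == pytest.approx(p_dfs, rel=1e-9)

    def test_five_allele_enumeration_consistent_with_montecarlo(self, rng):
        genos = [tuple(sorted(rng.integers(1, 6, 2))) for _ in range(20)]
        p_enum = hwe_exact_test(genos)
        p_mc = hwe_exact_test(genos, enumeration_cap=0, n_permutations=20_000, seed=5)
        assert p_mc == pytest.approx(p_enum, abs=0.02)

    def test_extreme_disequilibrium_small_p(self):
        genos = [(1, 2)] * 25  # all heterozygotes, p = q = 0.5
        assert hwe_exact_test(genos) < 0.01


class TestNullAllele:
    def test_no_deficit_gives_zero(self):
        gt = _table({"a": (1, 2), "b": (1, 2), "c": (1, 2), "d": (1, 2)})
        p0, freqs, conv = estimate_null_allele_frequency(gt, "L1")
        assert conv
        assert p0 == pytest.approx(0.0, abs=1e-6)

    def test_monomorphic_visible_gives_zero(self):
        gt = _table({"a": (1, 1), "b": (1, 1)})
        p0, freqs, conv = estimate_null_allele_frequency(gt, "L1")
        assert p0 == 0.0
        assert freqs == {1: 1.0}

    @staticmethod
    def _simulate(p_null, n, seed, k=5):
        rng = np.random.default_rng(seed)
        eff = np.append(np.full(k, (1 - p_null) / k), p_null)
        g = rng.choice(np.arange(1, k + 2), p=eff, size=(n, 2))
        null = k + 1
        a, b = g[:, 0].copy(), g[:, 1].copy()
        both = (a == null) & (b == null)
        a_null = (a == null) & ~both
        b_null = (b == null) & ~both
        a[a_null] = b[a_null]
        b[b_null] = a[b_null]
        a[both] = 0
        b[both] = 0
        return _table({f"i{j}": (a[j], b[j]) for j in range(n)})

    def test_recovery_at_n500(self):
        gt = self._simulate(0.2, 500, seed=42)
        p0, _, _ = estimate_null_allele_frequency(gt, "L1")
        assert abs(p0 - 0.2) < 0.05

    @pytest.mark.parametrize("truth", [0.0, 0.1, 0.3])
    def test_consistency_at_n2000(self, truth):
        ests = [
            estimate_null_allele_frequency(self._simulate(truth, 2000, seed=s), "L1")[0]
            for s in range(5)
        ]
        assert abs(float(np.mean(ests)) - truth) < 0.02


# ---------------------------------------------------------------------------
# exclusion probabilities


class TestExclusion:
    def test_single_allele_zero(self):
        assert exclusion_probabilities({1: 1.0}) == (0.0, 0.0)

    def test_combined_identity(self):
        assert combined_exclusion([0.0, 0.0, 0.0]) == 0.0
        assert combined_exclusion([0.5, 0.5]) == 0.75

    @pytest.mark.parametrize(
        "freqs",
        [
            {1: 0.5, 2: 0.5},
            {1: 0.2, 2: 0.3, 3: 0.5},
            {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25},
            {1: 0.1, 2: 0.2, 3: 0.3, 4: 0.4},
        ],
    )
    def test_matches_brute_force(self, freqs):
        q1, q2 = exclusion_probabilities(freqs)
        b1, b2 = brute_force_exclusion(freqs)
        assert q1 == pytest.approx(b1, abs=1e-12)
        assert q2 == pytest.approx(b2, abs=1e-12)

    def test_monotone_in_locus_count(self):
        q1, _ = exclusion_probabilities({a: 0.125 for a in range(1, 9)})
        combined = [combined_exclusion([q1] * k) for k in range(1, 8)]
        assert all(b > a for a, b in zip(combined, combined[1:]))

    def test_monotone_in_allelic_richness(self):
        qs = [
            exclusion_probabilities({a: 1.0 / k for a in range(1, k + 1)})
            for k in (2, 4, 8, 16)
        ]
        assert all(b[0] > a[0] and b[1] > a[1] for a, b in zip(qs, qs[1:]))


# ---------------------------------------------------------------------------
# parentage and sibship


def _mate(rng, g1, g2):
    """Mendelian offspring of two (L, 2) genotype arrays."""
    L = g1.shape[0]
    return np.stack(
        [g1[np.arange(L), rng.integers(0, 2, L)], g2[np.arange(L), rng.integers(0, 2, L)]],
        axis=1,
    )


class TestParentage:
    def test_incompatible_candidate_excluded(self):
        summ = equifrequent_summaries(3, 8)
        gt = GenotypeTable(
            ["off", "cand"],
            list(summ),
            np.array([[[1, 1], [1, 1], [1, 1]], [[2, 2], [2, 2], [2, 2]]]),
        )
        res = assign_parentage("off", None, ["cand"], gt, summ)
        assert res.assigned is None
        assert res.mismatches["cand"] == 3

    def test_self_candidate_ignored(self):
        summ = equifrequent_summaries(3, 8)
        gt = GenotypeTable(["off"], list(summ), np.ones((1, 3, 2), dtype=np.int64))
        res = assign_parentage("off", None, ["off"], gt, summ)
        assert res.assigned is None
        assert res.posterior == {}

    def test_empty_candidates(self):
        summ = equifrequent_summaries(3, 8)
        gt = GenotypeTable(["off"], list(summ), np.ones((1, 3, 2), dtype=np.int64))
        res = assign_parentage("off", None, [], gt, summ)
        assert res.assigned is None

    def test_true_parent_recovered(self, rng):
        summ = equifrequent_summaries(7, 8)
        correct = 0
        trials = 60
        for _ in range(trials):
            mother = rng.integers(1, 9, size=(7, 2))
            father = rng.integers(1, 9, size=(7, 2))
            off = _mate(rng, mother, father)
            ids = ["off", "mom", "dad"] + [f"c{k}" for k in range(10)]
            arr = np.stack(
                [off, mother, father] + [rng.integers(1, 9, size=(7, 2)) for _ in range(10)]
            )
            gt = GenotypeTable(ids, list(summ), arr)
            res = assign_parentage("off", "mom", ["dad"] + [f"c{k}" for k in range(10)], gt, summ)
            if res.assigned == "dad":
                correct += 1
        assert correct >= 0.9 * trials

    def test_null_compatible_homozygote_not_counted(self):
        summ = equifrequent_summaries(1, 8)
        summ["L01"].p_null = 0.2
        gt = GenotypeTable(
            ["off", "cand"], ["L01"], np.array([[[1, 1]], [[2, 2]]])
        )
        res = assign_parentage("off", None, ["cand"], gt, summ, use_null=True)
        assert res.mismatches["cand"] == 0


class TestSibshipPartition:
    def test_identical_pair_grouped(self):
        summ = equifrequent_summaries(7, 8)
        g = np.tile(np.array([[1, 2]]), (7, 1))
        gt = GenotypeTable(["a", "b"], list(summ), np.stack([g, g]))
        groups = partition_full_sibs(["a", "b"], gt, summ)
        assert groups == [["a", "b"]]

    def test_two_clutches_recovered(self, rng):
        summ = equifrequent_summaries(7, 8)
        ids, arr = [], []
        for fam in range(2):
            dam = rng.integers(1, 9, size=(7, 2))
            sire = rng.integers(1, 9, size=(7, 2))
            for o in range(4):
                ids.append(f"f{fam}o{o}")
                arr.append(_mate(rng, dam, sire))
        gt = GenotypeTable(ids, list(summ), np.stack(arr))
        groups = partition_full_sibs(ids, gt, summ)
        assert sorted(tuple(sorted(g)) for g in groups) == [
            tuple(f"f0o{o}" for o in range(4)),
            tuple(f"f1o{o}" for o in range(4)),
        ]

    def test_unrelated_mostly_singletons(self, rng):
        # at 7 loci x 8 alleles pairwise likelihoods occasionally false-merge
        # a chance-similar pair; require singletons to dominate strongly
        summ = equifrequent_summaries(7, 8)
        n_groups = []
        for _ in range(10):
            ids = [f"u{k}" for k in range(6)]
            arr = np.stack([rng.integers(1, 9, size=(7, 2)) for _ in ids])
            gt = GenotypeTable(ids, list(summ), arr)
            groups = partition_full_sibs(ids, gt, summ)
            n_groups.append(len(groups))
            assert max(len(g) for g in groups) <= 3
        assert float(np.mean(n_groups)) >= 5.0

    def test_unrelated_all_singletons_with_rich_loci(self, rng):
        summ = equifrequent_summaries(10, 16)
        ids = [f"u{k}" for k in range(6)]
        arr = np.stack([rng.integers(1, 17, size=(10, 2)) for _ in ids])
        gt = GenotypeTable(ids, list(summ), arr)
        assert all(len(g) == 1 for g in partition_full_sibs(ids, gt, summ))


# ---------------------------------------------------------------------------
# I/O


class TestIO:
    def test_wide_csv_roundtrip(self, tmp_path, rng):
        ids = [f"i{k}" for k in range(5)]
        arr = rng.integers(1, 9, size=(5, 3, 2))
        arr[0, 1] = 0
        gt = GenotypeTable(ids, ["La", "Lb", "Lc"], arr)
        path = tmp_path / "geno.csv"
        gt.to_wide_csv(path)
        back = GenotypeTable.from_wide_csv(path)
        assert back.ids == ids
        assert back.loci == ["La", "Lb", "Lc"]
        assert np.array_equal(back.alleles, arr)

    def test_genepop_roundtrip(self, tmp_path, rng):
        ids = [f"i{k}" for k in range(4)]
        arr = rng.integers(1, 250, size=(4, 2, 2))
        arr[2, 0] = 0
        gt = GenotypeTable(ids, ["L1", "L2"], arr)
        path = tmp_path / "geno.gen"
        gt.to_genepop(path)
        back = GenotypeTable.from_genepop(path)
        assert back.ids == ids
        assert np.array_equal(back.alleles, arr)

    def test_half_call_rejected(self):
        with pytest.raises(GenotypeError, match="half-call"):
            GenotypeTable(["a"], ["L1"], np.array([[[1, 0]]]))
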