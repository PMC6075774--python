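"""Microsatellite locus diagnostics, relationship likelihoods and parentage.

Covers per-locus summaries (allele frequencies, heterozygosities, exact
Hardy-Weinberg tests), EM estimation of null-allele frequency from
homozygote excess, parent-pair exclusion probabilities, pairwise
relationship likelihoods over IBD categories {U, HS, FS, PO}, likelihood
parentage assignment at a posterior threshold, and greedy full-sib
partitioning.
"""

from __future__ import annotations

import csv
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = 0
#: internal allele code for a non-amplifying (null) allele
NULL_ALLELE = -1

#: IBD coefficients (k0, k1, k2) per relationship category
CATEGORIES: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}
#: tie-break priority: prefer the less related category
CATEGORY_PRIORITY = ("U", "HS", "FS", "PO")


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Individuals x loci table of unordered allele pairs.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)``; allele codes are
    positive integers and a missing cell is ``(0, 0)``.  Half-calls are
    rejected.
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    population: str | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.shape != (len(self.ids), len(self.loci), 2):
            raise GenotypeError("alleles array shape mismatch")
        a, b = self.alleles[..., 0], self.alleles[..., 1]
        if np.any((a == MISSING) != (b == MISSING)):
            raise GenotypeError("half-called genotypes are not allowed")
        if np.any(self.alleles < 0):
            raise GenotypeError("allele codes must be positive (0 = missing)")
        self._index = {iid: i for i, iid in enumerate(self.ids)}
        self._locus_index = {loc: j for j, loc in enumerate(self.loci)}

    def genotype(self, iid: str, locus: str) -> tuple[int, int] | None:
        """Sorted allele pair, or None when missing."""
        g = self.alleles[self._index[iid], self._locus_index[locus]]
        if g[0] == MISSING:
            return None
        return (int(min(g)), int(max(g)))

    def locus_genotypes(self, locus: str) -> list[tuple[int, int]]:
        """All non-missing genotypes at a locus (sorted pairs)."""
        col = self.alleles[:, self._locus_index[locus]]
        keep = col[:, 0] != MISSING
        return [(int(min(g)), int(max(g))) for g in col[keep]]

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_wide_csv(cls, path) -> "GenotypeTable":
        """Read ``id,locus1_a,locus1_b,...`` CSV (0 or blank = missing)."""
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            loci = []
            for j in range(1, len(header), 2):
                name = header[j]
                if name.endswith("_a"):
                    name = name[:-2]
                loci.append(name)
            ids, rows = [], []
            for row in reader:
                if not row or not row[0].strip():
                    continue
                ids.append(row[0].strip())
                vals = [int(v) if v.strip() else 0 for v in row[1:]]
                rows.append(np.array(vals, dtype=np.int64).reshape(len(loci), 2))
        return cls(ids, loci, np.array(rows))

    def to_wide_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["id"]
            for loc in self.loci:
                header += [f"{loc}_a", f"{loc}_b"]
            w.writerow(header)
            for i, iid in enumerate(self.ids):
                w.writerow([iid] + [int(v) for v in self.alleles[i].ravel()])

    @classmethod
    def from_genepop(cls, path) -> "GenotypeTable":
        """Read a single-population GenePop file (2- or 3-digit codes)."""
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if not lines:
            raise GenotypeError("empty GenePop file")
        loci: list[str] = []
        i = 1
        while i < len(lines) and lines[i].strip().lower() != "pop":
            part = lines[i].strip()
            if part:
                loci.extend(x.strip() for x in part.split(",") if x.strip())
            i += 1
        if i == len(lines):
            raise GenotypeError("GenePop file has no 'pop' line")
        ids, rows = [], []
        for ln in lines[i + 1 :]:
            if not ln.strip():
                continue
            if ln.strip().lower() == "pop":
                raise GenotypeError("multi-population GenePop files are not supported")
            name, _, geno = ln.partition(",")
            codes = geno.split()
            if len(codes) != len(loci):
                raise GenotypeError(f"wrong number of loci for {name.strip()!r}")
            pair_rows = []
            for c in codes:
                a, b = int(c[: len(c) // 2]), int(c[len(c) // 2 :])
                if (a == 0) != (b == 0):
                    a = b = 0  # half-call in file -> treat as missing
                pair_rows.append((a, b))
            ids.append(name.strip())
            rows.append(pair_rows)
        return cls(ids, loci, np.array(rows, dtype=np.int64))

    def to_genepop(self, path, title: str = "pedqg genotypes") -> None:
        digits = 3 if int(self.alleles.max(initial=0)) > 99 else 2
        with open(path, "w") as fh:
            fh.write(title + "\n")
            for loc in self.loci:
                fh.write(loc + "\n")
            fh.write("pop\n")
            for i, iid in enumerate(self.ids):
                codes = [
                    f"{int(a):0{digits}d}{int(b):0{digits}d}"
                    for a, b in self.alleles[i]
                ]
                fh.write(f"{iid}, " + " ".join(codes) + "\n")


@dataclass
class LocusSummary:
    locus: str
    freqs: dict[int, float]
    allelic_richness: int
    n_typed: int
    ho: float
    he: float
    p_null: float = 0.0
    hwe_p: float = 1.0
    q1: float = 0.0
    q2: float = 0.0
    null_converged: bool = True

    @property
    def freqs_with_null(self) -> dict[int, float]:
        """Frequency map including the null allele (key ``NULL_ALLELE``)."""
        if self.p_null <= 0.0:
            return dict(self.freqs)
        out = {a: p * (1.0 - self.p_null) for a, p in self.freqs.items()}
        out[NULL_ALLELE] = self.p_null
        return out


@dataclass
class ClassificationResult:
    category: str
    log_likelihoods: dict[str, float]

    def llr(self, other: str) -> float:
        return self.log_likelihoods[self.category] - self.log_likelihoods[other]


@dataclass
class ParentageResult:
    offspring: str
    assigned: str | None
    posterior: dict[str, float]
    mismatches: dict[str, int]
    threshold: float = 0.99


# ---------------------------------------------------------------------------
# genotype probabilities


def genotype_probability(g: tuple[int, int], freqs: Mapping[int, float]) -> float:
    """HWE probability of an unordered genotype."""
    a, b = g
    pa = freqs.get(a, 0.0)
    pb = freqs.get(b, 0.0)
    return pa * pa if a == b else 2.0 * pa * pb


def transition_probability(
    g1: tuple[int, int], g2: tuple[int, int], freqs: Mapping[int, float]
) -> float:
    """P(g2 | g1, one allele IBD): one of g2's alleles is a random allele of
    g1, the other a random draw from the population."""
    a, b = g1
    c, d = g2
    p = 0.0
    for shared, rest in ((c, d), (d, c)):
        share_prob = ((shared == a) + (shared == b)) / 2.0
        p += share_prob * freqs.get(rest, 0.0)
    if c == d:
        p /= 2.0  # both passes identical for homozygous g2
    return p


def pair_genotype_probability(
    g1: tuple[int, int],
    g2: tuple[int, int],
    freqs: Mapping[int, float],
    k: tuple[float, float, float],
) -> float:
    """P(g1, g2 | k0, k1, k2) at one locus under HWE allele frequencies."""
    k0, k1, k2 = k
    p1 = genotype_probability(g1, freqs)
    prob = k0 * p1 * genotype_probability(g2, freqs)
    if k1:
        prob += k1 * p1 * transition_probability(g1, g2, freqs)
    if k2 and tuple(sorted(g1)) == tuple(sorted(g2)):
        prob += k2 * p1
    return prob


def _expand_observed(g: tuple[int, int], p_null: float):
    """Possible true genotypes behind an observed one when nulls are modeled."""
    a, b = g
    if p_null <= 0.0 or a != b:
        return [g]
    return [(a, a), tuple(sorted((NULL_ALLELE, a)))]


def pair_log_likelihood(
    gt: GenotypeTable,
    id1: str,
    id2: str,
    category: str,
    summaries: Mapping[str, LocusSummary],
    *,
    use_null: bool = False,
) -> float:
    """Multilocus log-likelihood of a pair under one IBD category.

    Loci missing in either individual are skipped; with ``use_null`` the
    likelihood of an observed homozygote marginalizes over the hidden
    null-carrier state.
    """
    k = CATEGORIES[category]
    total = 0.0
    n_used = 0
    for locus, summ in summaries.items():
        g1 = gt.genotype(id1, locus)
        g2 = gt.genotype(id2, locus)
        if g1 is None or g2 is None:
            continue
        if use_null and summ.p_null > 0.0:
            freqs = summ.freqs_with_null
            prob = sum(
                pair_genotype_probability(t1, t2, freqs, k)
                for t1 in _expand_observed(g1, summ.p_null)
                for t2 in _expand_observed(g2, summ.p_null)
            )
        else:
            prob = pair_genotype_probability(g1, g2, summ.freqs, k)
        if prob <= 0.0:
            return -math.inf
        total += math.log(prob)
        n_used += 1
    if n_used == 0:
        raise GenotypeError(f"no shared non-missing loci for {id1!r}, {id2!r}")
    return total


def classify_relationship(
    gt: GenotypeTable,
    id1: str,
    id2: str,
    summaries: Mapping[str, LocusSummary],
    *,
    use_null: bool = False,
) -> ClassificationResult:
    """Argmax category over {U, HS, FS, PO}; ties resolved toward less
    relatedness (priority U > HS > FS > PO)."""
    lls = {
        cat: pair_log_likelihood(gt, id1, id2, cat, summaries, use_null=use_null)
        for cat in CATEGORIES
    }
    best = max(lls.values())
    for cat in CATEGORY_PRIORITY:
        if lls[cat] >= best - 1e-9:
            return ClassificationResult(cat, lls)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# locus summaries


def allele_frequencies(gt: GenotypeTable, locus: str) -> dict[int, float]:
    genos = gt.locus_genotypes(locus)
    if not genos:
        raise GenotypeError(f"locus {locus!r} has no typed individuals")
    counts: dict[int, int] = {}
    for a, b in genos:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(genos)
    return {a: c / total for a, c in sorted(counts.items())}


def observed_heterozygosity(gt: GenotypeTable, locus: str) -> float:
    genos = gt.locus_genotypes(locus)
    if not genos:
        raise GenotypeError(f"locus {locus!r} has no typed individuals")
    return sum(1 for a, b in genos if a != b) / len(genos)


def expected_heterozygosity(freqs: Mapping[int, float], n: int) -> float:
    """Unbiased expected heterozygosity ``(2n/(2n-1)) * (1 - sum p^2)``."""
    if n < 1:
        raise GenotypeError("need at least one typed individual")
    h = 1.0 - sum(p * p for p in freqs.values())
    if n == 1:
        return h
    return (2 * n / (2 * n - 1)) * h


# -- exact Hardy-Weinberg test ----------------------------------------------


def _log_table_probability(cells: Mapping[tuple[int, int], int], n: int, allele_counts: Mapping[int, int]) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    h = sum(c for (a, b), c in cells.items() if a != b)
    lp = math.lgamma(n + 1) + h * math.log(2.0)
    for c in cells.values():
        lp -= math.lgamma(c + 1)
    for ac in allele_counts.values():
        lp += math.lgamma(ac + 1)
    lp -= math.lgamma(2 * n + 1)
    return lp


def _enumerate_tables(alleles: Sequence[int], counts: Mapping[int, int], node_cap: int):
    """Yield all genotype tables consistent with the allele counts.

    DFS over genotype cells in a fixed order; raises RuntimeError if more
    than ``node_cap`` nodes are visited.
    """
    cells = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]
    visited = 0

    def rec(idx: int, remaining: dict[int, int], current: dict):
        nonlocal visited
        visited += 1
        if visited > node_cap:
            raise RuntimeError("table enumeration too large")
        if idx == len(cells):
            if all(v == 0 for v in remaining.values()):
                yield dict(current)
            return
        a, b = cells[idx]
        # remaining cells can still absorb leftovers? prune by feasibility:
        if a == b:
            cmax = remaining[a] // 2
        else:
            cmax = min(remaining[a], remaining[b])
        for c in range(cmax, -1, -1):
            if a == b:
                remaining[a] -= 2 * c  # homozygote consumes two copies
            else:
                remaining[a] -= c
                remaining[b] -= c
            if _feasible(idx + 1, cells, remaining):
                current[(a, b)] = c
                yield from rec(idx + 1, remaining, current)
                del current[(a, b)]
            if a == b:
                remaining[a] += 2 * c
            else:
                remaining[a] += c
                remaining[b] += c

    def _feasible(idx: int, cells, remaining) -> bool:
        future = {a: 0 for a in remaining}
        for a, b in cells[idx:]:
            future[a] += 2 if a == b else 1
            if a != b:
                future[b] += 1
        return all(remaining[a] == 0 or future.get(a, 0) > 0 for a in remaining)

    yield from rec(0, dict(counts), {})


def _hwe_exact_biallelic(n: int, allele_counts: dict[int, int], obs_het: int) -> float:
    """Levene-style exact test for two alleles: enumerate heterozygote counts."""
    a, b = sorted(allele_counts)
    ca = allele_counts[a]
    lps = []
    lp_obs = None
    # n_ab must match allele-count parity and feasibility
    for h in range(ca % 2, min(ca, allele_counts[b]) + 1, 2):
        naa = (ca - h) // 2
        nbb = (allele_counts[b] - h) // 2
        cells = {(a, a): naa, (a, b): h, (b, b): nbb}
        lp = _log_table_probability(cells, n, allele_counts)
        lps.append(lp)
        if h == obs_het:
            lp_obs = lp
    assert lp_obs is not None
    return min(1.0, sum(math.exp(lp) for lp in lps if lp <= lp_obs + 1e-9))


def hwe_exact_test(
    genotypes: Sequence[tuple[int, int]],
    *,
    enumeration_cap: int = 300_000,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Exact (or permutation) Hardy-Weinberg test p-value.

    Complete enumeration of genotype tables conditional on the observed
    allele counts when feasible; otherwise Monte-Carlo pairing of permuted
    alleles with a fixed seed.  The p-value sums the probabilities of tables
    no more probable than the observed one.
    """
    n = len(genotypes)
    if n < 1:
        raise GenotypeError("no genotypes for HWE test")
    allele_counts: dict[int, int] = {}
    for a, b in genotypes:
        allele_counts[a] = allele_counts.get(a, 0) + 1
        allele_counts[b] = allele_counts.get(b, 0) + 1
    alleles = sorted(allele_counts)
    if len(alleles) == 1:
        return 1.0
    obs_cells: dict[tuple[int, int], int] = {}
    for a, b in genotypes:
        key = (min(a, b), max(a, b))
        obs_cells[key] = obs_cells.get(key, 0) + 1
    if len(alleles) == 2:
        obs_het = sum(c for (a, b), c in obs_cells.items() if a != b)
        return _hwe_exact_biallelic(n, allele_counts, obs_het)
    lp_obs = _log_table_probability(obs_cells, n, allele_counts)

    # enumeration is worthwhile only for few alleles or small samples
    if len(alleles) <= 3 or n <= 25:
        try:
            p = 0.0
            for table in _enumerate_tables(alleles, allele_counts, enumeration_cap):
                lp = _log_table_probability(table, n, allele_counts)
                if lp <= lp_obs + 1e-9:
                    p += math.exp(lp)
            return min(1.0, p)
        except RuntimeError:
            pass

    rng = np.random.default_rng(seed)
    pool = np.array(
        [a for a, c in allele_counts.items() for _ in range(c)], dtype=np.int64
    )
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pool)
        pairs = pool.reshape(n, 2)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        _, counts = np.unique(lo * (1 << 32) + hi, return_counts=True)
        het = int(np.sum(lo != hi))
        lp = (
            math.lgamma(n + 1)
            + het * math.log(2.0)
            - float(np.sum([math.lgamma(c + 1) for c in counts]))
            + sum(math.lgamma(ac + 1) for ac in allele_counts.values())
            - math.lgamma(2 * n + 1)
        )
        if lp <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def estimate_null_allele_frequency(
    gt: GenotypeTable,
    locus: str,
    *,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[float, dict[int, float], bool]:
    """EM estimate of the null-allele frequency from homozygote excess.

    Observed homozygotes are treated as a mixture of true homozygotes and
    visible/null heterozygotes; individuals that are null/null are assumed
    to appear as missing cells, handled by a zero-truncation correction.
    Returns ``(p_null, frequency map including the null, converged)``; the
    returned frequencies sum to 1.
    """
    genos = gt.locus_genotypes(locus)
    if not genos:
        raise GenotypeError(f"locus {locus!r} has no typed individuals")
    n_obs = len(genos)
    hom_counts: dict[int, int] = {}
    het_allele_counts: dict[int, int] = {}
    for a, b in genos:
        if a == b:
            hom_counts[a] = hom_counts.get(a, 0) + 1
        else:
            het_allele_counts[a] = het_allele_counts.get(a, 0) + 1
            het_allele_counts[b] = het_allele_counts.get(b, 0) + 1
    alleles = sorted(set(hom_counts) | set(het_allele_counts))
    if len(alleles) == 1 and not het_allele_counts:
        out = {alleles[0]: 1.0}
        return 0.0, out, True

    # initial frequencies: straight counting; p0 small positive (0 is a fixed point)
    p = {a: 0.0 for a in alleles}
    for a, c in hom_counts.items():
        p[a] += 2 * c
    for a, c in het_allele_counts.items():
        p[a] += c
    total = sum(p.values())
    p = {a: v / total for a, v in p.items()}
    p0 = 0.1
    p = {a: v * (1 - p0) for a, v in p.items()}

    converged = False
    for _ in range(max_iter):
        n_eff = n_obs / max(1.0 - p0 * p0, 1e-12)
        e_null = 0.0
        e_vis = {a: float(het_allele_counts.get(a, 0)) for a in alleles}
        for a, c in hom_counts.items():
            w = 2 * p0 / (p[a] + 2 * p0) if (p[a] + 2 * p0) > 0 else 0.0
            e_null += c * w
            e_vis[a] += c * (2.0 - w)
        null_alleles = e_null + 2.0 * (n_eff - n_obs)
        p0_new = null_alleles / (2.0 * n_eff)
        p0_new = min(max(p0_new, 0.0), 0.5)
        p_new = {a: e_vis[a] / (2.0 * n_eff) for a in alleles}
        # renormalize visible mass to 1 - p0
        vis = sum(p_new.values())
        if vis > 0:
            p_new = {a: v * (1.0 - p0_new) / vis for a, v in p_new.items()}
        delta = abs(p0_new - p0)
        p, p0 = p_new, p0_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("null-allele EM did not converge at locus %s", locus)
    out = dict(p)
    if p0 > 0:
        out[NULL_ALLELE] = p0
    return p0, out, converged


# ---------------------------------------------------------------------------
# exclusion probabilities


def exclusion_probabilities(freqs: Mapping[int, float]) -> tuple[float, float]:
    """Single-locus parentage exclusion probabilities (Q1, Q2).

    Q1: probability that a random non-father is excluded given a known
    mother-offspring pair.  Q2: probability that a random non-parent pair
    is excluded for an offspring of unknown parents.  Both are computed by
    exact enumeration over HWE-weighted genotypes.
    """
    if not freqs:
        raise GenotypeError("empty allele frequency map")
    alleles = sorted(freqs)
    pr = {a: float(freqs[a]) for a in alleles}

    q1 = 0.0
    for a in alleles:
        for b in alleles:
            p_gm = pr[a] * pr[b]  # ordered mother genotype
            if p_gm == 0.0:
                continue
            for m in (a, b):  # transmitted maternal allele, prob 1/2 each
                for f in alleles:  # true paternal allele from the population
                    w = p_gm * 0.5 * pr[f]
                    if w == 0.0:
                        continue
                    u, v = m, f
                    pat: set[int] = set()
                    if u in (a, b):
                        pat.add(v)
                    if v in (a, b):
                        pat.add(u)
                    p_s = sum(pr[x] for x in pat)
                    q1 += w * (1.0 - p_s) ** 2

    q2 = 0.0
    contains = {a: 1.0 - (1.0 - pr[a]) ** 2 for a in alleles}
    for u in alleles:
        for v in alleles:
            w = pr[u] * pr[v]  # ordered offspring allele pair
            if w == 0.0:
                continue
            if u == v:
                p_comp = contains[u] ** 2
            else:
                gamma = 2.0 * pr[u] * pr[v]  # P(genotype is exactly {u,v})
                p_comp = 2.0 * contains[u] * contains[v] - gamma * gamma
            q2 += w * (1.0 - p_comp)
    return q1, q2


def combined_exclusion(per_locus: Iterable[float]) -> float:
    """Combine per-locus exclusion probabilities: ``1 - prod(1 - q)``."""
    prod = 1.0
    for q in per_locus:
        prod *= 1.0 - q
    return 1.0 - prod


def locus_summary(
    gt: GenotypeTable,
    locus: str,
    *,
    estimate_null: bool = True,
    hwe_seed: int = 0,
) -> LocusSummary:
    """Full per-locus summary (frequencies, Ho/He, null, HWE, Q1/Q2)."""
    genos = gt.locus_genotypes(locus)
    if len(genos) < 2:
        raise GenotypeError(f"locus {locus!r} needs >= 2 typed genotypes")
    freqs = allele_frequencies(gt, locus)
    n = len(genos)
    ho = observed_heterozygosity(gt, locus)
    he = expected_heterozygosity(freqs, n)
    hwe_p = hwe_exact_test(genos, seed=hwe_seed) if len(freqs) > 1 else 1.0
    p_null, adj, converged = (
        estimate_null_allele_frequency(gt, locus)
        if estimate_null
        else (0.0, dict(freqs), True)
    )
    q1, q2 = exclusion_probabilities(freqs)
    return LocusSummary(
        locus=locus,
        freqs=freqs,
        allelic_richness=len(freqs),
        n_typed=n,
        ho=ho,
        he=he,
        p_null=p_null,
        hwe_p=hwe_p,
        q1=q1,
        q2=q2,
        null_converged=converged,
    )


def summarize_loci(gt: GenotypeTable, **kwargs) -> dict[str, LocusSummary]:
    return {loc: locus_summary(gt, loc, **kwargs) for loc in gt.loci}


def write_locus_summaries(summaries: Mapping[str, LocusSummary], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["locus", "n_typed", "allelic_richness", "ho", "he", "p_null", "hwe_p", "q1", "q2"]
        )
        for s in summaries.values():
            w.writerow(
                [s.locus, s.n_typed, s.allelic_richness, s.ho, s.he, s.p_null, s.hwe_p, s.q1, s.q2]
            )


# ---------------------------------------------------------------------------
# parentage


def _transmission_probability(
    go: tuple[int, int],
    gp1: tuple[int, int],
    gp2: tuple[int, int] | None,
    freqs: Mapping[int, float],
) -> float:
    """P(offspring genotype | one or two parental genotypes).

    With one parent the other allele is drawn from the population.
    """
    o1, o2 = go
    prob = 0.0
    for x in gp1:
        p_other_list = (
            [(y, 0.5) for y in gp2] if gp2 is not None else list(freqs.items())
        )
        for y, py in p_other_list:
            if (x, y) == (o1, o2) or (y, x) == (o1, o2):
                prob += 0.5 * py
    return prob


def _duo_compatible(go, gc) -> bool:
    return bool(set(go) & set(gc))


def _trio_compatible(go, gm, gc) -> bool:
    o1, o2 = go
    for m, f in ((o1, o2), (o2, o1)):
        if m in gm and f in gc:
            return True
    return False


def assign_parentage(
    offspring: str,
    known_parent: str | None,
    candidates: Sequence[str],
    gt: GenotypeTable,
    summaries: Mapping[str, LocusSummary],
    *,
    threshold: float = 0.99,
    max_mismatch: int = 0,
    use_null: bool = False,
) -> ParentageResult:
    """Likelihood-based parentage assignment at a posterior threshold.

    Candidates with Mendelian mismatches at more than ``max_mismatch`` loci
    are excluded (with ``use_null`` a homozygote-vs-homozygote mismatch is
    not counted, as both could carry a null).  Among survivors the posterior
    is the candidate's trio (or duo) likelihood normalized against the other
    survivors plus an unsampled random parent; assignment requires the
    posterior to reach ``threshold``.
    """
    cands = [c for c in candidates if c != offspring and c != known_parent]
    mismatches: dict[str, int] = {}
    logls: dict[str, float] = {}
    gm_by_locus = {}
    if known_parent is not None:
        gm_by_locus = {loc: gt.genotype(known_parent, loc) for loc in summaries}

    log_alt = 0.0  # likelihood of an unsampled random parent
    for locus, summ in summaries.items():
        go = gt.genotype(offspring, locus)
        if go is None:
            continue
        gm = gm_by_locus.get(locus)
        if gm is not None:
            p = _transmission_probability(go, gm, None, summ.freqs)
        else:
            p = genotype_probability(go, summ.freqs)
        log_alt += math.log(max(p, 1e-300))

    for c in cands:
        mm = 0
        ll = 0.0
        for locus, summ in summaries.items():
            go = gt.genotype(offspring, locus)
            gc = gt.genotype(c, locus)
            if go is None or gc is None:
                continue
            gm = gm_by_locus.get(locus)
            if gm is not None:
                compatible = _trio_compatible(go, gm, gc)
                p = _transmission_probability(go, gm, gc, summ.freqs)
            else:
                compatible = _duo_compatible(go, gc)
                p = _transmission_probability(go, gc, None, summ.freqs)
            if not compatible:
                if use_null and go[0] == go[1] and gc[0] == gc[1]:
                    # both observed homozygous: a shared null explains the clash
                    p = max(p, summ.p_null * summ.freqs.get(go[0], 0.0))
                else:
                    mm += 1
                    p = 1e-300
            ll += math.log(max(p, 1e-300))
        mismatches[c] = mm
        if mm <= max_mismatch:
            logls[c] = ll

    posterior: dict[str, float] = {}
    if logls:
        keys = list(logls)
        lls = np.array([logls[c] for c in keys] + [log_alt])
        w = np.exp(lls - lls.max())
        w /= w.sum()
        posterior = {c: float(w[i]) for i, c in enumerate(keys)}
    assigned = None
    if posterior:
        best = max(posterior, key=posterior.get)
        if posterior[best] >= threshold:
            assigned = best
    return ParentageResult(
        offspring=offspring,
        assigned=assigned,
        posterior=posterior,
        mismatches=mismatches,
        threshold=threshold,
    )


def partition_full_sibs(
    nestlings: Sequence[str],
    gt: GenotypeTable,
    summaries: Mapping[str, LocusSummary],
    *,
    use_null: bool = False,
) -> list[list[str]]:
    """Greedy agglomerative full-sib partition.

    Starts from singletons and repeatedly merges the pair of groups with the
    largest positive summed pairwise FS-vs-U log-likelihood gain, refusing
    merges that would place a pair classified as unrelated in one group.
    Deterministic given input order.
    """
    ids = list(nestlings)
    if len(ids) < 2:
        return [[i] for i in ids]
    n = len(ids)
    gain = np.zeros((n, n))
    unrelated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            res = classify_relationship(gt, ids[i], ids[j], summaries, use_null=use_null)
            g = res.log_likelihoods["FS"] - res.log_likelihoods["U"]
            gain[i, j] = gain[j, i] = g
            unrelated[i, j] = unrelated[j, i] = res.category == "U"

    groups: list[list[int]] = [[i] for i in range(n)]
    while len(groups) > 1:
        best = None
        best_gain = 0.0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                cross = [(i, j) for i in groups[a] for j in groups[b]]
                if any(unrelated[i, j] for i, j in cross):
                    continue
                g = sum(gain[i, j] for i, j in cross)
                if g > best_gain:
                    best_gain = g
                    best = (a, b)
        if best is None:
            break
        a, b = best
        groups[a] = groups[a] + groups[b]
        del groups[b]
    return [[ids[i] for i in grp] for grp in groups]


def write_parentage_results(results: Iterable[ParentageResult], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["offspring", "assigned", "posterior", "n_candidates"])
        for r in results:
            post = r.posterior.get(r.assigned, 0.0) if r.assigned else ""
            w.writerow([r.offspring, r.assigned or "", post, len(r.mismatches)])
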