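"""Independent oracles shared across test modules.

These deliberately avoid the library's own algorithms: the relationship
matrix oracle enumerates every Mendelian inheritance pattern exactly, and
the exclusion oracle brute-forces all genotype combinations.
"""

from __future__ import annotations

import numpy as np

from pedqg.msat import genotype_probability
from pedqg.pedigree import Pedigree, PedigreeRecord


def exact_relationship_by_enumeration(ped: Pedigree) -> np.ndarray:
    """Exact A matrix via exhaustive enumeration of inheritance patterns.

    Every known-parent link contributes one binary meiosis choice; all
    ``2^L`` patterns are propagated and allele identity-by-descent is
    averaged.  Exact (dyadic rational) as long as ``L <= 24``.
    """
    n = len(ped)
    dam_idx, sire_idx = ped.parent_indices()
    order = [ped.index(x) for x in ped.topological_order()]

    # assign bit positions to known-parent links
    bit_of: dict[tuple[int, int], int] = {}
    for i in range(n):
        for slot, p in ((0, dam_idx[i]), (1, sire_idx[i])):
            if p >= 0:
                bit_of[(i, slot)] = len(bit_of)
    L = len(bit_of)
    if L > 24:
        raise ValueError("pedigree too deep for exhaustive enumeration")
    P = 1 << L
    patterns = np.arange(P, dtype=np.int64)

    next_founder_allele = [0]

    def fresh() -> int:
        next_founder_allele[0] += 1
        return next_founder_allele[0]

    a1 = np.zeros((n, P), dtype=np.int32)
    a2 = np.zeros((n, P), dtype=np.int32)
    for i in order:
        for slot, p, target in ((0, dam_idx[i], a1), (1, sire_idx[i], a2)):
            if p < 0:
                target[i, :] = fresh()
            else:
                bit = (patterns >> bit_of[(i, slot)]) & 1
                target[i, :] = np.where(bit == 1, a1[p], a2[p])

    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            matches = (
                (a1[i] == a1[j]).sum()
                + (a1[i] == a2[j]).sum()
                + (a2[i] == a1[j]).sum()
                + (a2[i] == a2[j]).sum()
            )
            f = matches / (4.0 * P)  # kinship coefficient
            A[i, j] = A[j, i] = 2.0 * f
    return A


def random_pedigree(
    rng: np.random.Generator,
    *,
    n_founders: int = 5,
    n_nonfounders: int = 6,
    max_depth: int = 4,
    p_unknown_parent: float = 0.2,
) -> Pedigree:
    """Random valid pedigree with bounded depth for oracle comparisons."""
    recs = [PedigreeRecord(f"F{i}", None, None, "U") for i in range(n_founders)]
    depth = {f"F{i}": 0 for i in range(n_founders)}
    for k in range(n_nonfounders):
        iid = f"X{k}"
        eligible = [i for i in depth if depth[i] < max_depth]
        dam = sire = None
        if rng.random() > p_unknown_parent:
            dam = eligible[rng.integers(len(eligible))]
        if rng.random() > p_unknown_parent:
            choices = [i for i in eligible if i != dam]
            if choices:
                sire = choices[rng.integers(len(choices))]
        recs.append(PedigreeRecord(iid, dam, sire, "U"))
        parents = [p for p in (dam, sire) if p is not None]
        depth[iid] = 1 + max((depth[p] for p in parents), default=-1)
    return Pedigree(recs)


def brute_force_exclusion(freqs: dict[int, float]) -> tuple[float, float]:
    """Exhaustive enumeration over mother/true-father/offspring/candidate
    genotype combinations (quadruple/quintuple loop)."""
    alleles = sorted(freqs)
    genos = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]

    def gp(g):
        return genotype_probability(g, freqs)

    def trans(go, g1, g2):
        p = 0.0
        for x in g1:
            for y in g2:
                if tuple(sorted((x, y))) == tuple(sorted(go)):
                    p += 0.25
        return p

    q1 = 0.0
    q2 = 0.0
    for gm in genos:
        for gf in genos:
            for go in genos:
                pt = trans(go, gm, gf)
                if pt == 0.0:
                    continue
                w = gp(gm) * gp(gf) * pt
                for gc in genos:
                    if trans(go, gm, gc) == 0.0:
                        q1 += w * gp(gc)
                for gc1 in genos:
                    for gc2 in genos:
                        if trans(go, gc1, gc2) == 0.0:
                            q2 += w * gp(gc1) * gp(gc2)
    return q1, q2


def brute_force_sib_counts(ped: Pedigree) -> tuple[int, int, int]:
    """O(n^2) full-sib / maternal-half / paternal-half pair counts."""
    recs = ped.records
    full = mat = pat = 0
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            shared_dam = a.dam is not None and a.dam == b.dam
            shared_sire = a.sire is not None and a.sire == b.sire
            if shared_dam and shared_sire:
                full += 1
            elif shared_dam:
                mat += 1
            elif shared_sire:
                pat += 1
    return full, mat, pat


def equifrequent_summaries(n_loci: int = 7, n_alleles: int = 8):
    """LocusSummary stand-ins with equifrequent alleles for likelihood tests."""
    from pedqg.msat import LocusSummary

    freqs = {a: 1.0 / n_alleles for a in range(1, n_alleles + 1)}
    out = {}
    for l in range(n_loci):
        name = f"L{l + 1:02d}"
        out[name] = LocusSummary(
            locus=name, freqs=dict(freqs), allelic_richness=n_alleles,
            n_typed=0, ho=0.0, he=0.0,
        )
    return out
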