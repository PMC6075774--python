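"""Synthetic colony generator.

Builds breeding colonies that mimic the assumed field structure: nests with
1-4 chambers, one breeding pair per chamber, extra-pair paternity and
intra-brood parasitism at configurable per-chamber rates, Mendelian
gene-dropped microsatellite genotypes with null alleles, and six correlated
traits generated from additive, maternal, nest and residual (co)variance
components.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pedqg.msat import MISSING, GenotypeTable
from pedqg.pedigree import (
    FEMALE,
    MALE,
    Pedigree,
    PedigreeRecord,
    inbreeding_coefficients,
)

TRAIT_NAMES = ("weight", "wing", "tarsus", "tail", "bill_length", "bill_width")
#: nestling-scale trait means used as cosmetic defaults
TRAIT_MEANS = (101.35, 95.88, 18.44, 64.52, 9.82, 11.31)
TRAIT_SDS = (8.24, 33.67, 1.35, 25.56, 2.64, 0.52)


class SimulationError(ValueError):
    pass


def _default_components() -> dict[str, np.ndarray]:
    """Diagonal defaults: h2 = 0.3, me2 = 0.2, ne2 = 0.1 per trait."""
    vp = np.array(TRAIT_SDS) ** 2
    return {
        "G": np.diag(0.3 * vp),
        "M": np.diag(0.2 * vp),
        "N": np.diag(0.1 * vp),
        "R": np.diag(0.4 * vp),
    }


@dataclass
class SimConfig:
    """Generative description of a synthetic colony."""

    n_nests: int = 28
    #: (chambers per nest, number of such nests); scaled to n_nests if the
    #: counts do not sum to it
    chamber_distribution: tuple[tuple[int, int], ...] = ((1, 21), (2, 6), (4, 1))
    clutch_lambda: float = 4.0
    clutch_range: tuple[int, int] = (1, 8)
    epp_rate: float = 0.40
    parasitism_rate: float = 0.03
    n_loci: int = 7
    n_alleles: int = 8
    allele_freqs: tuple | None = None  # per-locus frequency vectors; None = equifrequent
    null_freq: float | tuple = 0.0
    missing_rate: float = 0.0
    trait_names: tuple[str, ...] = TRAIT_NAMES
    trait_means: tuple[float, ...] = TRAIT_MEANS
    G: np.ndarray | None = None
    M: np.ndarray | None = None
    N: np.ndarray | None = None
    R: np.ndarray | None = None
    fledge_cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nests < 1:
            raise SimulationError("need at least one nest")
        for rate in (self.epp_rate, self.parasitism_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("rates must lie in [0, 1]")
        defaults = _default_components()
        for key in ("G", "M", "N", "R"):
            v = getattr(self, key)
            v = defaults[key] if v is None else np.atleast_2d(np.asarray(v, dtype=float))
            if v.shape[0] != v.shape[1]:
                raise SimulationError(f"{key} must be square")
            if not np.allclose(v, v.T):
                raise SimulationError(f"{key} must be symmetric")
            if np.any(np.linalg.eigvalsh(v) < -1e-8):
                raise SimulationError(f"{key} must be positive semi-definite")
            setattr(self, key, v)
        t = self.G.shape[0]
        for key in ("M", "N", "R"):
            if getattr(self, key).shape[0] != t:
                raise SimulationError("G, M, N, R dimensions differ")
        if len(self.trait_names) < t:
            self.trait_names = tuple(f"trait{i + 1}" for i in range(t))
        if len(self.trait_means) < t:
            self.trait_means = tuple([0.0] * t)

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]

    def locus_frequencies(self, locus: int) -> np.ndarray:
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs[locus], dtype=float)
        else:
            f = np.full(self.n_alleles, 1.0 / self.n_alleles)
        if abs(f.sum() - 1.0) > 1e-9:
            raise SimulationError("allele frequencies must sum to 1")
        return f

    def locus_null_freq(self, locus: int) -> float:
        if np.isscalar(self.null_freq):
            return float(self.null_freq)
        return float(self.null_freq[locus])

    def truth_ratios(self) -> dict[str, list[float]]:
        vg = np.diag(self.G)
        vp = vg + np.diag(self.M) + np.diag(self.N) + np.diag(self.R)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.sqrt(np.outer(vg, vg))
            rg = np.where(sd > 0, self.G / np.where(sd > 0, sd, 1.0), 0.0)
            safe_vp = np.where(vp > 0, vp, 1.0)
            return {
                "h2": list(np.where(vp > 0, vg / safe_vp, 0.0)),
                "me2": list(np.where(vp > 0, np.diag(self.M) / safe_vp, 0.0)),
                "ne2": list(np.where(vp > 0, np.diag(self.N) / safe_vp, 0.0)),
                "r_G": [[float(x) for x in row] for row in rg],
            }


@dataclass
class Colony:
    pedigree: Pedigree
    structure: pd.DataFrame  # id, age_class, nest, chamber, social dam/sire, flags
    truth: dict


def simulate_colony_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Colony:
    """Simulate the colony breeding structure and its true pedigree.

    One unrelated founder pair per chamber; per chamber the brood contains at
    least one extra-pair offspring with probability ``epp_rate`` and one
    parasitic (foreign-dam) offspring with probability ``parasitism_rate``.
    The pedigree records genetic parents; social parents and flags are in
    ``structure``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    counts = [c for _, c in cfg.chamber_distribution]
    sizes = [s for s, _ in cfg.chamber_distribution]
    total = sum(counts)
    nest_sizes: list[int] = []
    for s, c in zip(sizes, counts):
        nest_sizes += [s] * round(c * cfg.n_nests / total)
    while len(nest_sizes) < cfg.n_nests:
        nest_sizes.append(sizes[0])
    nest_sizes = nest_sizes[: cfg.n_nests]

    records: list[PedigreeRecord] = []
    rows = []
    chambers = []  # (nest, chamber, dam, sire)
    for ni, n_ch in enumerate(nest_sizes, start=1):
        for ci in range(1, n_ch + 1):
            dam = f"N{ni:02d}C{ci}_F"
            sire = f"N{ni:02d}C{ci}_M"
            records.append(PedigreeRecord(dam, None, None, FEMALE))
            records.append(PedigreeRecord(sire, None, None, MALE))
            for iid, sex in ((dam, "F"), (sire, "M")):
                rows.append(
                    dict(
                        id=iid, age_class="adult", nest=f"N{ni:02d}", chamber=f"N{ni:02d}C{ci}",
                        social_dam="", social_sire="", genetic_dam="", genetic_sire="",
                        sex=sex, is_epp=False, is_parasitic=False,
                    )
                )
            chambers.append((f"N{ni:02d}", f"N{ni:02d}C{ci}", dam, sire))

    all_males = [c[3] for c in chambers]
    all_females = [c[2] for c in chambers]
    mate_of = {c[2]: c[3] for c in chambers}

    lo, hi = cfg.clutch_range
    epp_chambers = 0
    parasitized = 0
    for nest, chamber, dam, sire in chambers:
        clutch = int(np.clip(rng.poisson(cfg.clutch_lambda), lo, hi))
        has_epp = rng.random() < cfg.epp_rate
        if has_epp:
            epp_chambers += 1
        epp_flags = rng.random(clutch) < 0.5 if has_epp else np.zeros(clutch, dtype=bool)
        if has_epp and not epp_flags.any():
            epp_flags[rng.integers(clutch)] = True
        parasite_idx = -1
        if rng.random() < cfg.parasitism_rate:
            parasite_idx = int(rng.integers(clutch))
            parasitized += 1
        for oi in range(clutch):
            iid = f"{chamber}_o{oi + 1}"
            gdam, gsire = dam, sire
            is_epp = False
            is_par = False
            if oi == parasite_idx:
                others = [f for f in all_females if f != dam]
                if others:
                    gdam = others[rng.integers(len(others))]
                    gsire = mate_of[gdam]
                    is_par = True
            elif epp_flags[oi]:
                others = [m for m in all_males if m != sire]
                if others:
                    gsire = others[rng.integers(len(others))]
                    is_epp = True
            records.append(PedigreeRecord(iid, gdam, gsire, "U"))
            rows.append(
                dict(
                    id=iid, age_class="nestling", nest=nest, chamber=chamber,
                    social_dam=dam, social_sire=sire, genetic_dam=gdam,
                    genetic_sire=gsire, sex="U", is_epp=is_epp, is_parasitic=is_par,
                )
            )

    structure = pd.DataFrame(rows)
    truth = {
        "n_chambers": len(chambers),
        "n_epp_chambers": epp_chambers,
        "n_parasitized_chambers": parasitized,
        "epp_fraction": epp_chambers / len(chambers),
    }
    return Colony(Pedigree(records), structure, truth)


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, GenotypeTable]:
    """Mendelian gene dropping of microsatellite genotypes.

    Returns ``(observed, true)`` tables.  Null alleles mask genotypes: a
    null homozygote becomes missing and a null heterozygote an apparent
    homozygote; extra missingness is applied at ``missing_rate``.  In the
    true table the null allele is reported as allele code ``n_alleles + 1``.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = len(ped)
    order = [ped.index(i) for i in ped.topological_order()]
    dam_idx, sire_idx = ped.parent_indices()

    L = cfg.n_loci
    true = np.zeros((n, L, 2), dtype=np.int64)  # 0 reserved: internal null -> code k+1
    for l in range(L):
        freqs = cfg.locus_frequencies(l)
        k = len(freqs)
        p_null = cfg.locus_null_freq(l)
        eff = np.concatenate([freqs * (1.0 - p_null), [p_null]])
        codes = np.arange(1, k + 2)  # k+1 encodes the null allele
        for i in order:
            d, s = dam_idx[i], sire_idx[i]
            g = np.zeros(2, dtype=np.int64)
            for slot, parent in ((0, d), (1, s)):
                if parent < 0:
                    g[slot] = rng.choice(codes, p=eff)
                else:
                    g[slot] = true[parent, l, rng.integers(2)]
            true[i, l] = g

    observed = true.copy()
    for l in range(L):
        k = len(cfg.locus_frequencies(l))
        null_code = k + 1
        a, b = observed[:, l, 0], observed[:, l, 1]
        both_null = (a == null_code) & (b == null_code)
        a_null = (a == null_code) & ~both_null
        b_null = (b == null_code) & ~both_null
        a[a_null] = b[a_null]  # apparent homozygote
        b[b_null] = a[b_null]
        a[both_null] = MISSING
        b[both_null] = MISSING
        drop = rng.random(n) < cfg.missing_rate
        a[drop] = MISSING
        b[drop] = MISSING

    loci = [f"L{l + 1:02d}" for l in range(L)]
    ids = list(ped.ids)
    return (
        GenotypeTable(ids, loci, observed),
        GenotypeTable(ids, list(loci), true),
    )


def simulate_breeding_values(
    ped: Pedigree,
    G: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Multivariate breeding values by the standard pedigree recursion.

    Founders are MVN(0, G); a non-founder is the mean of its known parents'
    vectors plus a Mendelian-sampling deviate whose variance restores the
    unknown-parent share:  both parents known ->
    ``0.5 * (1 - (F_s + F_d)/2) * G``; one known ->
    ``(0.75 - 0.25 F_known) * G``; none -> ``G``.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if np.any(np.linalg.eigvalsh(G) < -1e-8):
        raise SimulationError("G must be positive semi-definite")
    t = G.shape[0]
    n = len(ped)
    if np.all(G == 0):
        return np.zeros((n, t))
    F = inbreeding_coefficients(ped)
    Fv = np.array([F[i] for i in ped.ids])
    dam_idx, sire_idx = ped.parent_indices()
    # eigen square root handles PSD G
    w, V = np.linalg.eigh(G)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T

    a = np.zeros((n, t))
    for i in (ped.index(x) for x in ped.topological_order()):
        d, s = dam_idx[i], sire_idx[i]
        mean = np.zeros(t)
        if d >= 0 and s >= 0:
            mean = 0.5 * (a[d] + a[s])
            scale = 0.5 * (1.0 - (Fv[d] + Fv[s]) / 2.0)
        elif d >= 0 or s >= 0:
            p = d if d >= 0 else s
            mean = 0.5 * a[p]
            scale = 0.75 - 0.25 * Fv[p]
        else:
            scale = 1.0
        a[i] = mean + math.sqrt(scale) * (root @ rng.standard_normal(t))
    return a


def gene_drop_single_trait(
    ped: Pedigree, sigma2_a: float, n_reps: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Vectorized single-trait gene dropping: ``(n_reps, n)`` breeding values.

    Used as a Monte-Carlo oracle for the relationship matrix: the empirical
    covariance across replicates converges to ``sigma2_a * A``.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    F = inbreeding_coefficients(ped)
    Fv = np.array([F[i] for i in ped.ids])
    dam_idx, sire_idx = ped.parent_indices()
    n = len(ped)
    out = np.zeros((n_reps, n))
    sd = math.sqrt(sigma2_a)
    for i in (ped.index(x) for x in ped.topological_order()):
        d, s = dam_idx[i], sire_idx[i]
        if d >= 0 and s >= 0:
            scale = 0.5 * (1.0 - (Fv[d] + Fv[s]) / 2.0)
            mean = 0.5 * (out[:, d] + out[:, s])
        elif d >= 0 or s >= 0:
            p = d if d >= 0 else s
            scale = 0.75 - 0.25 * Fv[p]
            mean = 0.5 * out[:, p]
        else:
            scale = 1.0
            mean = 0.0
        out[:, i] = mean + sd * math.sqrt(scale) * rng.standard_normal(n_reps)
    return out


def simulate_phenotypes(
    ped: Pedigree,
    structure: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    breeding_values: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Phenotypes ``y = mean + a + m_dam + n_nest + e`` per trait vector.

    Maternal deviates are drawn per pedigree dam (individuals with an
    unknown dam each get their own), nest deviates per nest id, residuals
    per individual.  Returns the trait table and the true variance-ratio
    record implied by the config.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    t = cfg.n_traits
    if breeding_values is None:
        breeding_values = simulate_breeding_values(ped, cfg.G, rng)
    if breeding_values.shape != (len(ped), t):
        raise SimulationError("breeding values shape mismatch")

    struct = structure.set_index("id")
    dam_of = {}
    for iid in ped.ids:
        d = ped.record(iid).dam
        dam_of[iid] = d if d is not None else f"__own_{iid}"
    dams = sorted(set(dam_of.values()))
    m_dev = {d: rng.multivariate_normal(np.zeros(t), cfg.M) for d in dams}
    nests = sorted(set(struct["nest"]))
    n_dev = {x: rng.multivariate_normal(np.zeros(t), cfg.N) for x in nests}

    means = np.array(cfg.trait_means[:t])
    rows = []
    for i, iid in enumerate(ped.ids):
        e = rng.multivariate_normal(np.zeros(t), cfg.R)
        y = means + breeding_values[i] + m_dev[dam_of[iid]] + n_dev[struct.loc[iid, "nest"]] + e
        row = dict(
            id=iid,
            age_class=struct.loc[iid, "age_class"],
            nest=struct.loc[iid, "nest"],
            chamber=struct.loc[iid, "chamber"],
            sex=struct.loc[iid, "sex"],
        )
        for j, name in enumerate(cfg.trait_names[:t]):
            row[name] = float(y[j])
        rows.append(row)
    traits = pd.DataFrame(rows)
    truth = cfg.truth_ratios()
    return traits, truth


@dataclass
class SimulatedDataset:
    config: SimConfig
    colony: Colony
    genotypes: GenotypeTable
    true_genotypes: GenotypeTable
    traits: pd.DataFrame
    truth: dict


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full bundle: pedigree + genotypes + phenotypes + truth record."""
    rng = np.random.default_rng(cfg.seed)
    colony = simulate_colony_pedigree(cfg, rng)
    gt_obs, gt_true = simulate_genotypes(colony.pedigree, cfg, rng)
    traits, ratio_truth = simulate_phenotypes(colony.pedigree, colony.structure, cfg, rng)
    truth = dict(colony.truth)
    truth.update(ratio_truth)
    return SimulatedDataset(cfg, colony, gt_obs, gt_true, traits, truth)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write pedigree CSV, GenePop genotypes, phenotype CSV and truth JSON."""
    import os

    from pedqg.pedigree import write_pedigree

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "pedigree": os.path.join(outdir, "pedigree.csv"),
        "genotypes": os.path.join(outdir, "genotypes.gen"),
        "phenotypes": os.path.join(outdir, "phenotypes.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_pedigree(ds.colony.pedigree, paths["pedigree"])
    ds.genotypes.to_genepop(paths["genotypes"])
    ds.traits.to_csv(paths["phenotypes"], index=False)
    truth = dict(ds.truth)
    truth["structure"] = ds.colony.structure.to_dict(orient="records")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return paths
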