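"""Descriptive and inferential phenotype statistics.

Fledging-weight filter, pairwise Pearson trait correlations, one-way ANOVA
and MANOVA (Wilks' lambda with Rao's F approximation) for sexual
dimorphism, and the mate-pair assortative-mating correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pedqg.pedigree import Pedigree

logger = logging.getLogger(__name__)

TRAITS = ("weight", "wing", "tarsus", "tail", "bill_length", "bill_width")

DEFAULT_FLEDGE_CUTOFF = 82.0


class StatsError(ValueError):
    pass


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def filter_fledged(table: pd.DataFrame, cutoff: float = DEFAULT_FLEDGE_CUTOFF) -> pd.DataFrame:
    """Retain rows with weight strictly above ``cutoff`` (idempotent)."""
    if "weight" not in table.columns:
        raise StatsError("trait table has no 'weight' column")
    out = table.loc[table["weight"] > cutoff].reset_index(drop=True)
    if out.empty:
        logger.warning("fledging filter at %.1f g removed every record", cutoff)
    return out


def trait_correlations(
    table: pd.DataFrame, traits: tuple[str, ...] = TRAITS
) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided t-based p-values.

    Pairwise-complete deletion; a zero-variance column yields NaN for its
    pairs.  Returns a long-format frame (trait_x, trait_y, r, p, n, stars).
    """
    rows = []
    for i, tx in enumerate(traits):
        for ty in traits[i + 1 :]:
            sub = table[[tx, ty]].dropna()
            n = len(sub)
            if n < 3:
                raise StatsError(f"fewer than 3 complete pairs for {tx}/{ty}")
            x, y = sub[tx].to_numpy(), sub[ty].to_numpy()
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                rows.append(dict(trait_x=tx, trait_y=ty, r=np.nan, p=np.nan, n=n, stars=""))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                dict(trait_x=tx, trait_y=ty, r=float(r), p=float(p), n=n,
                     stars=significance_stars(float(p)))
            )
    return pd.DataFrame(rows)


def correlation_matrix(long: pd.DataFrame, traits: tuple[str, ...] = TRAITS) -> pd.DataFrame:
    """Square symmetric matrix view of :func:`trait_correlations` output."""
    mat = pd.DataFrame(np.eye(len(traits)), index=list(traits), columns=list(traits))
    for _, row in long.iterrows():
        mat.loc[row.trait_x, row.trait_y] = row.r
        mat.loc[row.trait_y, row.trait_x] = row.r
    return mat


@dataclass
class ManovaResult:
    wilks_lambda: float
    f: float
    df1: float
    df2: float
    p: float


@dataclass
class DimorphismResult:
    anova: pd.DataFrame  # trait, f, p
    manova: ManovaResult


def wilks_manova(groups: list[np.ndarray]) -> ManovaResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    ``groups`` is a list of (n_g, p) arrays (listwise-complete rows).
    """
    g = len(groups)
    if g < 2:
        raise StatsError("MANOVA needs at least two groups")
    p = groups[0].shape[1]
    N = sum(len(x) for x in groups)
    grand = np.vstack(groups).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for x in groups:
        if len(x) < 2:
            raise StatsError("each group needs >= 2 complete records")
        d = x - x.mean(axis=0)
        W += d.T @ d
        db = (x.mean(axis=0) - grand)[:, None]
        B += len(x) * (db @ db.T)
    lam = float(np.linalg.det(W) / np.linalg.det(W + B))
    q = g - 1
    m = N - 1 - (p + q + 1) / 2.0
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f = (1.0 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return ManovaResult(wilks_lambda=lam, f=float(f), df1=float(df1), df2=float(df2), p=pval)


def sex_dimorphism_tests(
    table: pd.DataFrame, traits: tuple[str, ...] = TRAITS
) -> DimorphismResult:
    """Per-trait one-way ANOVA plus MANOVA of sex differences in adults."""
    adults = table
    if "age_class" in table.columns:
        adults = table.loc[table["age_class"] == "adult"]
    adults = adults.loc[adults["sex"].isin(["F", "M"])]
    sexes = sorted(adults["sex"].unique())
    if len(sexes) < 2:
        raise StatsError("both sexes required for dimorphism tests")

    rows = []
    for tr in traits:
        samples = [adults.loc[adults["sex"] == s, tr].dropna().to_numpy() for s in sexes]
        f, p = stats.f_oneway(*samples)
        rows.append(dict(trait=tr, f=float(f), p=float(p)))
    complete = adults.dropna(subset=list(traits))
    groups = [complete.loc[complete["sex"] == s, list(traits)].to_numpy() for s in sexes]
    manova = wilks_manova(groups)
    return DimorphismResult(anova=pd.DataFrame(rows), manova=manova)


def build_pair_table(
    ped: Pedigree, table: pd.DataFrame, traits: tuple[str, ...] = TRAITS
) -> pd.DataFrame:
    """Mated pairs (dam, sire sharing at least one offspring) with both
    members' trait values; columns ``<trait>_f`` / ``<trait>_m``."""
    seen = set()
    rows = []
    tab = table.set_index("id")
    for rec in ped:
        if rec.dam is None or rec.sire is None:
            continue
        key = (rec.dam, rec.sire)
        if key in seen:
            continue
        seen.add(key)
        if rec.dam not in tab.index or rec.sire not in tab.index:
            continue
        row = dict(dam=rec.dam, sire=rec.sire)
        for tr in traits:
            row[f"{tr}_f"] = tab.loc[rec.dam, tr]
            row[f"{tr}_m"] = tab.loc[rec.sire, tr]
        rows.append(row)
    return pd.DataFrame(rows)


def assortative_mating(pairs: pd.DataFrame, trait: str) -> tuple[float, float, int]:
    """Pearson correlation between mates' trait values: ``(r, p, n)``."""
    cols = [f"{trait}_f", f"{trait}_m"]
    sub = pairs[cols].dropna()
    n = len(sub)
    if n < 3:
        raise StatsError("need at least 3 complete pairs")
    if n < 10:
        logger.warning("assortative mating test on only %d pairs (low power)", n)
    r, p = stats.pearsonr(sub[cols[0]], sub[cols[1]])
    return float(r), float(p), n


def summary_table(table: pd.DataFrame, traits: tuple[str, ...] = TRAITS) -> pd.DataFrame:
    """Per-trait, per-age-class N/mean/SD/min/max."""
    rows = []
    for ac, grp in table.groupby("age_class"):
        for tr in traits:
            x = grp[tr].dropna()
            rows.append(
                dict(age_class=ac, trait=tr, n=len(x), mean=x.mean(), sd=x.std(),
                     min=x.min(), max=x.max())
            )
    return pd.DataFrame(rows)
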