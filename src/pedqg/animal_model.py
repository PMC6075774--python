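"""Bayesian pedigree mixed models ("animal models") fit by Gibbs sampling.

The univariate model is ``y = Xb + Z_a a + Z_m m + Z_n n + e`` with
``a ~ N(0, A sigma2_A)`` (``A`` the additive relationship matrix),
``m ~ N(0, I sigma2_M)`` over dam identities, ``n ~ N(0, I sigma2_N)`` over
nest identities and iid residuals.  Location effects are drawn jointly from
their multivariate-normal full conditional (mixed-model equations); each
variance is drawn from its scaled-inverse-chi-square full conditional.  The
variance prior ``(V, nu)`` is inverse-gamma(shape nu/2, rate nu*V/2); for
bivariate fits the 2x2 covariance blocks are inverse-Wishart with scale
``nu*V`` and ``nu`` degrees of freedom.

Bivariate additive-only fits use an eigendecomposition of the relationship
matrix so each per-individual effect has a small independent full
conditional; this is a pure speed optimization and targets the same
posterior.

The deviance stored for DIC is the conditional (lowest-level) Gaussian
likelihood given sampled location effects and the residual (co)variance:
``DIC = 2*mean(D) - D(theta_bar)`` with ``theta_bar`` the posterior means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, stats

from pedqg.pedigree import Pedigree, additive_relationship_matrix

logger = logging.getLogger(__name__)

RANDOM_TERMS = ("additive", "maternal", "nest")

#: (total iterations, burn-in, thinning interval)
SCHEDULES: dict[str, tuple[int, int, int]] = {
    "paper": (1_000_000, 100_000, 100),
    "paper_bivariate": (4_000_000, 400_000, 1_000),
    "fast": (15_000, 3_000, 12),
    "fast_bivariate": (9_000, 3_000, 6),
}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class AnimalModelSpec:
    """Specification of an animal-model fit.

    ``priors`` maps term name ('additive', 'maternal', 'nest', 'residual')
    to ``(V, nu)``; missing entries default to ``V = 0.05 * sample variance``
    and ``nu = 1`` for univariate responses and ``V = I_2``,
    ``nu = 1.002`` for bivariate ones.
    """

    traits: tuple[str, ...]
    random_terms: tuple[str, ...] = ("additive",)
    fixed: tuple[str, ...] = ("intercept",)
    priors: Mapping[str, tuple] | None = None
    n_iter: int = 15_000
    burn_in: int = 3_000
    thin: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.traits) <= 2:
            raise ModelError("1 or 2 response traits required")
        for t in self.random_terms:
            if t not in RANDOM_TERMS:
                raise ModelError(f"unknown random term {t!r}")
        if self.burn_in >= self.n_iter:
            raise ModelError("burn-in must be smaller than total iterations")
        if self.thin < 1:
            raise ModelError("thinning interval must be >= 1")

    @classmethod
    def with_schedule(cls, name: str, **kwargs) -> "AnimalModelSpec":
        total, burn, thin = SCHEDULES[name]
        return cls(n_iter=total, burn_in=burn, thin=thin, **kwargs)

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained Gibbs samples plus cached quantities for DIC."""

    spec: AnimalModelSpec
    params: pd.DataFrame
    deviance: np.ndarray
    deviance_at_mean: float
    n_records: int

    @property
    def n_samples(self) -> int:
        return len(self.params)

    def column(self, name: str) -> np.ndarray:
        return self.params[name].to_numpy()

    def to_csv(self, path) -> None:
        self.params.assign(deviance=self.deviance).to_csv(path, index=False)


@dataclass
class RatioSummary:
    mode: float
    hpd_low: float
    hpd_high: float
    samples: np.ndarray


@dataclass
class VarianceDecomposition:
    h2: RatioSummary
    me2: RatioSummary
    ne2: RatioSummary
    vp: np.ndarray


@dataclass
class ModelComparison:
    labels: list[str]
    dic: dict[str, float]
    delta: dict[str, float]
    retained: list[str]
    threshold: float = 7.0


# ---------------------------------------------------------------------------
# posterior summaries


def posterior_mode_hpd(samples: np.ndarray, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Posterior mode (Gaussian KDE, Silverman bandwidth, 512-point grid) and
    narrowest interval containing ``level`` posterior mass."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ModelError("samples must be a non-empty 1-d vector")
    if not 0.0 < level < 1.0:
        raise ModelError("level must be in (0, 1)")
    if np.ptp(x) == 0.0:
        v = float(x[0])
        return v, (v, v)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    mode = float(grid[np.argmax(kde(grid))])

    xs = np.sort(x)
    n = len(xs)
    n_incl = max(2, int(math.ceil(level * n)))
    if n_incl >= n:
        return mode, (float(xs[0]), float(xs[-1]))
    widths = xs[n_incl - 1 :] - xs[: n - n_incl + 1]
    j = int(np.argmin(widths))
    return mode, (float(xs[j]), float(xs[j + n_incl - 1]))


def _ratio_summary(samples: np.ndarray, level: float = 0.95) -> RatioSummary:
    mode, (lo, hi) = posterior_mode_hpd(samples, level)
    return RatioSummary(mode=mode, hpd_low=lo, hpd_high=hi, samples=samples)


def variance_ratios(samples: PosteriorSamples, level: float = 0.95) -> VarianceDecomposition:
    """Per-sample h2, me2, ne2 with VP the sum of all variance components."""
    if len(samples.spec.traits) != 1:
        raise ModelError("variance_ratios expects univariate samples")
    cols = samples.params
    va = cols["VA"].to_numpy() if "VA" in cols else np.zeros(len(cols))
    vm = cols["VM"].to_numpy() if "VM" in cols else np.zeros(len(cols))
    vn = cols["VN"].to_numpy() if "VN" in cols else np.zeros(len(cols))
    ve = cols["VE"].to_numpy()
    vp = va + vm + vn + ve
    h2, me2, ne2 = va / vp, vm / vp, vn / vp
    for r in (h2, me2, ne2):
        if np.any((r < 0) | (r > 1)):
            raise ModelError("variance ratio outside [0, 1]")
    if np.any(h2 + me2 + ne2 > 1.0 + 1e-12):
        raise ModelError("ratios exceed 1")
    return VarianceDecomposition(
        h2=_ratio_summary(h2, level),
        me2=_ratio_summary(me2, level),
        ne2=_ratio_summary(ne2, level),
        vp=vp,
    )


def genetic_correlation(samples: PosteriorSamples, level: float = 0.95) -> dict[str, RatioSummary]:
    """Per-block correlation posteriors from a bivariate fit.

    Returns a mapping like ``{'r_G': ..., 'r_E': ...}`` including maternal /
    nest correlations when those terms were fitted.
    """
    if len(samples.spec.traits) != 2:
        raise ModelError("genetic_correlation expects bivariate samples")
    blocks = {"A": "r_G", "M": "r_M", "N": "r_N", "E": "r_E"}
    out: dict[str, RatioSummary] = {}
    for blk, label in blocks.items():
        cols = {f"V{blk}_11", f"V{blk}_12", f"V{blk}_22"}
        if not cols <= set(samples.params.columns):
            continue
        v1 = samples.column(f"V{blk}_11")
        v2 = samples.column(f"V{blk}_22")
        c12 = samples.column(f"V{blk}_12")
        r = c12 / np.sqrt(v1 * v2)
        if np.any(np.abs(r) > 1.0 + 1e-9):
            raise ModelError("correlation sample outside [-1, 1]")
        out[label] = _ratio_summary(np.clip(r, -1.0, 1.0), level)
    return out


def compute_dic(samples: PosteriorSamples) -> float:
    """``DIC = 2 * mean(D) - D(theta_bar)`` with conditional-likelihood focus."""
    return float(2.0 * samples.deviance.mean() - samples.deviance_at_mean)


def select_models(dics: Mapping[str, float], threshold: float = 7.0) -> ModelComparison:
    """Delta-DIC table; models within ``threshold`` of the best are retained."""
    if len(dics) < 2:
        raise ModelError("need at least two candidate models")
    best = min(dics.values())
    delta = {k: v - best for k, v in dics.items()}
    retained = [k for k, d in delta.items() if d < threshold]
    return ModelComparison(
        labels=list(dics),
        dic=dict(dics),
        delta=delta,
        retained=retained,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# design construction


def _default_prior(v_scale: float, nu: float, t: int):
    if t == 1:
        return (v_scale, nu)
    return (np.eye(t), nu)


def _resolve_priors(spec: AnimalModelSpec, y: np.ndarray, t: int):
    """Fill in (V, nu) for every term; defaults follow the reference
    conventions (univariate: V = 0.05 * var(y), nu = 1; bivariate: V = I,
    nu = 1.002)."""
    priors = dict(spec.priors or {})
    out = {}
    terms = list(spec.random_terms) + ["residual"]
    for term in terms:
        if term in priors:
            v, nu = priors[term]
            v = np.asarray(v, dtype=float) if t == 2 else float(v)
        elif t == 1:
            v, nu = 0.05 * float(np.var(y, ddof=1)), 1.0
        else:
            v, nu = np.eye(2), 1.002
        out[term] = (v, nu)
    return out


def _build_records(spec, traits: pd.DataFrame, ped: Pedigree):
    """Select usable records and build factor index arrays."""
    df = traits.copy()
    if "id" not in df.columns:
        raise ModelError("trait table needs an 'id' column")
    for tr in spec.traits:
        if tr not in df.columns:
            raise ModelError(f"trait {tr!r} not in table")
    mask = np.ones(len(df), dtype=bool)
    for tr in spec.traits:
        mask &= df[tr].notna().to_numpy()
    if "additive" in spec.random_terms:
        mask &= df["id"].isin(ped.ids).to_numpy()
    df = df.loc[mask].reset_index(drop=True)
    if len(df) < 10:
        raise ModelError(f"only {len(df)} usable records (need >= 10)")
    return df


def _design(spec: AnimalModelSpec, df: pd.DataFrame, ped: Pedigree):
    """Return (X, term blocks) where each block is (name, Z indices, K or None)."""
    n = len(df)
    X_cols = []
    if "intercept" in spec.fixed:
        X_cols.append(np.ones(n))
    if "age_class" in spec.fixed:
        ac = df["age_class"].astype(str).to_numpy()
        X_cols.append((ac == "adult").astype(float))  # nestling = baseline
    X = np.column_stack(X_cols) if X_cols else np.empty((n, 0))

    blocks = []
    for term in spec.random_terms:
        if term == "additive":
            ids = df["id"].tolist()
            uniq = list(dict.fromkeys(ids))
            idx = np.array([uniq.index(i) for i in ids]) if len(uniq) < n else np.arange(n)
            A = additive_relationship_matrix(ped).submatrix(uniq)
            blocks.append(("additive", idx, len(uniq), A.values))
        elif term == "maternal":
            dams = []
            for iid in df["id"]:
                d = ped.record(iid).dam if iid in ped else None
                dams.append(d if d is not None else f"__pseudo_dam_{iid}")
            uniq = list(dict.fromkeys(dams))
            if all(d.startswith("__pseudo_dam_") for d in uniq):
                raise ModelError("maternal term requested but every dam is unknown")
            idx = np.array([uniq.index(d) for d in dams])
            blocks.append(("maternal", idx, len(uniq), None))
        elif term == "nest":
            if "nest" not in df.columns:
                raise ModelError("nest term requested but no 'nest' column")
            nests = df["nest"].astype(str).tolist()
            uniq = list(dict.fromkeys(nests))
            idx = np.array([uniq.index(x) for x in nests])
            blocks.append(("nest", idx, len(uniq), None))
    return X, blocks


def _draw_variance(rng, nu, v, q, ssq):
    """Scaled-inverse-chi-square full conditional draw."""
    shape = 0.5 * (nu + q)
    rate = 0.5 * (nu * v + ssq)
    return rate / rng.standard_gamma(shape)


def _draw_cov_block(rng, nu, V, q, S):
    """Inverse-Wishart full conditional draw for a t x t block."""
    df = nu + q
    scale = nu * V + S
    t = scale.shape[0]
    if df <= t - 1:
        df = t - 1 + 1e-6
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


# ---------------------------------------------------------------------------
# univariate sampler


def fit_univariate(spec: AnimalModelSpec, traits: pd.DataFrame, ped: Pedigree) -> PosteriorSamples:
    """Gibbs sampler for a univariate animal model.

    Seed-reproducible: identical spec (including seed) gives bit-identical
    retained samples.
    """
    if len(spec.traits) != 1:
        raise ModelError("fit_univariate needs exactly one trait")
    df = _build_records(spec, traits, ped)
    y = df[spec.traits[0]].to_numpy(dtype=float)
    if np.var(y) == 0.0:
        raise ModelError("response has zero variance")
    priors = _resolve_priors(spec, y, 1)
    X, blocks = _design(spec, df, ped)

    if [b[0] for b in blocks] == ["additive"] and blocks[0][2] == len(df):
        return _fit_additive_only(spec, y, X, blocks[0][3], priors, bivariate=False)
    return _fit_general(spec, y[:, None], X, blocks, priors, t=1)


def fit_bivariate(spec: AnimalModelSpec, traits: pd.DataFrame, ped: Pedigree) -> PosteriorSamples:
    """Gibbs sampler for a bivariate animal model with unstructured 2x2
    covariance blocks per random term and residual."""
    if len(spec.traits) != 2:
        raise ModelError("fit_bivariate needs exactly two traits")
    df = _build_records(spec, traits, ped)
    Y = df[list(spec.traits)].to_numpy(dtype=float)
    priors = _resolve_priors(spec, Y, 2)
    X, blocks = _design(spec, df, ped)
    if [b[0] for b in blocks] == ["additive"] and blocks[0][2] == len(df):
        return _fit_additive_only(spec, Y, X, blocks[0][3], priors, bivariate=True)
    return _fit_general(spec, Y, X, blocks, priors, t=2)


def _retained_iter(spec):
    for it in range(1, spec.n_iter + 1):
        keep = it > spec.burn_in and (it - spec.burn_in) % spec.thin == 0
        yield it, keep


_VAR_LABEL = {"additive": "VA", "maternal": "VM", "nest": "VN", "residual": "VE"}


def _fit_general(spec, Y, X, blocks, priors, t):
    """Dense mixed-model-equation Gibbs sampler (1 or 2 traits)."""
    rng = np.random.default_rng(spec.seed)
    n, p = X.shape
    term_names = [b[0] for b in blocks]
    sizes = [p] + [b[2] for b in blocks]
    offsets = np.cumsum([0] + sizes)
    d = offsets[-1]

    # dense design W = [X | Z_1 | ... ]
    W = np.zeros((n, d))
    W[:, :p] = X
    for (name, idx, q, _), off in zip(blocks, offsets[1:]):
        W[np.arange(n), off + idx] += 1.0
    WtW = W.T @ W

    Kinvs = {}
    for name, idx, q, K in blocks:
        if K is not None:
            Kinvs[name] = np.linalg.inv(K)

    # state
    if t == 1:
        var = {name: max(priors[name][0], 1e-8) for name in term_names}
        var["residual"] = max(priors["residual"][0], 1e-8)
    else:
        var = {name: np.array(priors[name][0], dtype=float) for name in term_names}
        var["residual"] = np.array(priors["residual"][0], dtype=float)

    n_keep = spec.n_samples
    rows = np.zeros((n_keep, 0))
    col_names: list[str] = []
    if t == 1:
        col_names += [f"b{i}" for i in range(p)]
        col_names += [_VAR_LABEL[nm] for nm in term_names] + ["VE"]
    else:
        for tr in range(2):
            col_names += [f"b{i}_{tr + 1}" for i in range(p)]
        for nm in term_names + ["residual"]:
            lab = _VAR_LABEL[nm][-1]  # A/M/N/E
            col_names += [f"V{lab}_11", f"V{lab}_12", f"V{lab}_22"]
    rows = np.zeros((n_keep, len(col_names)))
    devs = np.zeros(n_keep)
    theta_sum = np.zeros(d * t)
    resid_sum = np.zeros((t, t)) if t == 2 else 0.0

    WtY = W.T @ Y  # (d, t)
    k = 0
    for it, keep in _retained_iter(spec):
        if t == 1:
            s2e = var["residual"]
            if d == 0:
                # known-mean model: only the residual variance is sampled
                sse = float(Y[:, 0] @ Y[:, 0])
                nu_e, v_e = priors["residual"][1], priors["residual"][0]
                var["residual"] = _draw_variance(rng, nu_e, v_e, n, sse)
                if keep:
                    rows[k] = [var["residual"]]
                    devs[k] = n * math.log(2 * math.pi * var["residual"]) + sse / var["residual"]
                    resid_sum += var["residual"]
                    k += 1
                continue
            C = WtW / s2e
            rhs = (WtY[:, 0] / s2e).copy()
            diag = np.einsum("ii->i", C)
            for (name, idx, q, K), off in zip(blocks, offsets[1:]):
                if K is not None:
                    C[off : off + q, off : off + q] += Kinvs[name] / var[name]
                else:
                    diag[off : off + q] += 1.0 / var[name]
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
            mean = linalg.cho_solve(cf, rhs, check_finite=False)
            z = rng.standard_normal(d)
            theta = mean + linalg.solve_triangular(
                cf[0].T, z, lower=False, check_finite=False
            )
            resid = Y[:, 0] - W @ theta
            sse = float(resid @ resid)
            nu_e, v_e = priors["residual"][1], priors["residual"][0]
            var["residual"] = _draw_variance(rng, nu_e, v_e, n, sse)
            for (name, idx, q, K), off in zip(blocks, offsets[1:]):
                u = theta[off : off + q]
                ssq = float(u @ Kinvs[name] @ u) if K is not None else float(u @ u)
                v0, nu0 = priors[name]
                var[name] = _draw_variance(rng, nu0, v0, q, ssq)
            if keep:
                vals = list(theta[:p]) + [var[nm] for nm in term_names] + [var["residual"]]
                rows[k] = vals
                devs[k] = n * math.log(2 * math.pi * var["residual"]) + sse / var["residual"]
                theta_sum += theta
                resid_sum += var["residual"]
                k += 1
        else:
            Se_inv = np.linalg.inv(var["residual"])
            C = np.zeros((2 * d, 2 * d))
            rhs = np.zeros(2 * d)
            for i in range(2):
                for j in range(2):
                    C[i * d : (i + 1) * d, j * d : (j + 1) * d] = Se_inv[i, j] * WtW
                rhs[i * d : (i + 1) * d] = WtY @ Se_inv[:, i]
            for (name, idx, q, K), off in zip(blocks, offsets[1:]):
                Sinv = np.linalg.inv(var[name])
                Kin = Kinvs[name] if K is not None else np.eye(q)
                for i in range(2):
                    for j in range(2):
                        sl_i = slice(i * d + off, i * d + off + q)
                        sl_j = slice(j * d + off, j * d + off + q)
                        C[sl_i, sl_j] += Sinv[i, j] * Kin
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
            mean = linalg.cho_solve(cf, rhs, check_finite=False)
            z = rng.standard_normal(2 * d)
            theta = mean + linalg.solve_triangular(
                cf[0].T, z, lower=False, check_finite=False
            )
            Theta = theta.reshape(2, d).T  # (d, 2)
            E = Y - W @ Theta
            S_res = E.T @ E
            v0, nu0 = priors["residual"]
            var["residual"] = _draw_cov_block(rng, nu0, np.asarray(v0), n, S_res)
            for (name, idx, q, K), off in zip(blocks, offsets[1:]):
                U = Theta[off : off + q]
                Kin = Kinvs[name] if K is not None else None
                S = U.T @ (Kin @ U) if Kin is not None else U.T @ U
                v0, nu0 = priors[name]
                var[name] = _draw_cov_block(rng, nu0, np.asarray(v0), q, S)
            if keep:
                vals = list(Theta[:p, 0]) + list(Theta[:p, 1])
                for nm in term_names + ["residual"]:
                    V = var[nm]
                    if np.linalg.det(V) <= 0:
                        raise ModelError("non-positive-definite covariance draw")
                    vals += [V[0, 0], V[0, 1], V[1, 1]]
                rows[k] = vals
                Se = var["residual"]
                Se_i = np.linalg.inv(Se)
                quad = float(np.einsum("ij,jk,ik->", E, Se_i, E))
                devs[k] = n * (2 * math.log(2 * math.pi) + math.log(np.linalg.det(Se))) + quad
                theta_sum += theta
                resid_sum = resid_sum + Se
                k += 1

    params = pd.DataFrame(rows, columns=col_names)
    theta_bar = theta_sum / n_keep
    if t == 1:
        s2e_bar = resid_sum / n_keep
        r = Y[:, 0] - W @ theta_bar
        dev_mean = n * math.log(2 * math.pi * s2e_bar) + float(r @ r) / s2e_bar
    else:
        Se_bar = resid_sum / n_keep
        Theta_bar = theta_bar.reshape(2, d).T
        E = Y - W @ Theta_bar
        Se_i = np.linalg.inv(Se_bar)
        quad = float(np.einsum("ij,jk,ik->", E, Se_i, E))
        dev_mean = n * (2 * math.log(2 * math.pi) + math.log(np.linalg.det(Se_bar))) + quad
    return PosteriorSamples(
        spec=spec, params=params, deviance=devs, deviance_at_mean=dev_mean, n_records=n
    )


def _fit_additive_only(spec, Y, X, A, priors, *, bivariate):
    """Fast path: additive + residual only, one record per individual.

    Works in the eigenbasis of A so the per-individual full conditionals are
    independent; statistically equivalent to the dense sampler.
    """
    rng = np.random.default_rng(spec.seed)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    n, t = Y.shape
    lam, Q = np.linalg.eigh(A)
    lam = np.clip(lam, 1e-10, None)
    Yt = Q.T @ Y
    Xt = Q.T @ X if X.shape[1] else np.empty((n, 0))
    p = X.shape[1]
    XtX = Xt.T @ Xt
    XtX_inv = np.linalg.inv(XtX) if p else None

    nu_a_V, nu_a = priors["additive"]
    nu_e_V, nu_e = priors["residual"]

    if t == 1:
        s2a = max(float(nu_a_V), 1e-8)
        s2e = max(float(nu_e_V), 1e-8)
    else:
        Sa = np.array(nu_a_V, dtype=float)
        Se = np.array(nu_e_V, dtype=float)

    B = np.zeros((p, t))
    n_keep = spec.n_samples
    if t == 1:
        col_names = [f"b{i}" for i in range(p)] + ["VA", "VE"]
    else:
        col_names = [f"b{i}_{tr + 1}" for tr in range(2) for i in range(p)]
        col_names += ["VA_11", "VA_12", "VA_22", "VE_11", "VE_12", "VE_22"]
    rows = np.zeros((n_keep, len(col_names)))
    devs = np.zeros(n_keep)
    a_sum = np.zeros((n, t))
    b_sum = np.zeros((p, t))
    se_sum = np.zeros((t, t)) if t == 2 else 0.0

    k = 0
    for it, keep in _retained_iter(spec):
        R = Yt - (Xt @ B if p else 0.0)
        if t == 1:
            prec = 1.0 / (lam * s2a) + 1.0 / s2e
            mean = (R[:, 0] / s2e) / prec
            a = mean + rng.standard_normal(n) / np.sqrt(prec)
            # fixed effects
            if p:
                resid = Yt[:, 0] - a
                bm = XtX_inv @ (Xt.T @ resid)
                Lb = np.linalg.cholesky(XtX_inv * s2e)
                B[:, 0] = bm + Lb @ rng.standard_normal(p)
            ssa = float(np.sum(a * a / lam))
            s2a = _draw_variance(rng, nu_a, nu_a_V, n, ssa)
            e = Yt[:, 0] - (Xt @ B[:, 0] if p else 0.0) - a
            sse = float(e @ e)
            s2e = _draw_variance(rng, nu_e, nu_e_V, n, sse)
            if keep:
                rows[k] = list(B[:, 0]) + [s2a, s2e]
                devs[k] = n * math.log(2 * math.pi * s2e) + sse / s2e
                a_sum[:, 0] += a
                b_sum[:, 0] += B[:, 0]
                se_sum += s2e
                k += 1
        else:
            Sa_inv = np.linalg.inv(Sa)
            Se_inv = np.linalg.inv(Se)
            # per-individual 2x2 precision: Sa_inv/lam_i + Se_inv
            P00 = Sa_inv[0, 0] / lam + Se_inv[0, 0]
            P01 = Sa_inv[0, 1] / lam + Se_inv[0, 1]
            P11 = Sa_inv[1, 1] / lam + Se_inv[1, 1]
            det = P00 * P11 - P01 * P01
            rhs0 = R @ Se_inv[:, 0]
            rhs1 = R @ Se_inv[:, 1]
            m0 = (P11 * rhs0 - P01 * rhs1) / det
            m1 = (P00 * rhs1 - P01 * rhs0) / det
            # sample via per-i Cholesky of the 2x2 covariance (= inv precision)
            c00 = P11 / det
            c01 = -P01 / det
            c11 = P00 / det
            l00 = np.sqrt(c00)
            l10 = c01 / l00
            l11 = np.sqrt(np.maximum(c11 - l10 * l10, 1e-300))
            z0 = rng.standard_normal(n)
            z1 = rng.standard_normal(n)
            a = np.column_stack([m0 + l00 * z0, m1 + l10 * z0 + l11 * z1])
            if p:
                resid = Yt - a
                Bm = XtX_inv @ (Xt.T @ resid)
                Lcov = np.linalg.cholesky(np.kron(Se, XtX_inv))
                bvec = Bm.T.ravel() + Lcov @ rng.standard_normal(2 * p)
                B = bvec.reshape(2, p).T
            Sa_S = (a.T * (1.0 / lam)) @ a
            Sa = _draw_cov_block(rng, nu_a, np.asarray(nu_a_V), n, Sa_S)
            E = Yt - (Xt @ B if p else 0.0) - a
            Se = _draw_cov_block(rng, nu_e, np.asarray(nu_e_V), n, E.T @ E)
            if keep:
                rows[k] = (
                    list(B[:, 0]) + list(B[:, 1])
                    + [Sa[0, 0], Sa[0, 1], Sa[1, 1], Se[0, 0], Se[0, 1], Se[1, 1]]
                )
                Se_i = np.linalg.inv(Se)
                quad = float(np.einsum("ij,jk,ik->", E, Se_i, E))
                devs[k] = n * (2 * math.log(2 * math.pi) + math.log(np.linalg.det(Se))) + quad
                a_sum += a
                b_sum += B
                se_sum = se_sum + Se
                k += 1

    params = pd.DataFrame(rows, columns=col_names)
    a_bar = a_sum / n_keep
    b_bar = b_sum / n_keep
    if t == 1:
        s2e_bar = se_sum / n_keep
        e = Yt[:, 0] - (Xt @ b_bar[:, 0] if p else 0.0) - a_bar[:, 0]
        dev_mean = n * math.log(2 * math.pi * s2e_bar) + float(e @ e) / s2e_bar
    else:
        Se_bar = se_sum / n_keep
        E = Yt - (Xt @ b_bar if p else 0.0) - a_bar
        Se_i = np.linalg.inv(Se_bar)
        quad = float(np.einsum("ij,jk,ik->", E, Se_i, E))
        dev_mean = n * (2 * math.log(2 * math.pi) + math.log(np.linalg.det(Se_bar))) + quad
    return PosteriorSamples(
        spec=spec, params=params, deviance=devs, deviance_at_mean=dev_mean, n_records=n
    )


# ---------------------------------------------------------------------------
# residual-only model (used for conjugate checks and prior-predictive draws)


def sample_residual_variance(
    y: np.ndarray, v: float, nu: float, n_samples: int, seed: int = 0
) -> np.ndarray:
    """Posterior draws of the residual variance of a known-mean (zero)
    normal model under the (V, nu) prior.

    With no data (``len(y) == 0``) this returns prior-predictive draws from
    inverse-gamma(nu/2, nu*V/2).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = len(y)
    ssq = float(y @ y)
    shape = 0.5 * (nu + n)
    rate = 0.5 * (nu * v + ssq)
    return rate / rng.standard_gamma(shape, size=n_samples)
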