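import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedqg import animal_model as am
from pedqg.animal_model import (
    AnimalModelSpec,
    ModelError,
    PosteriorSamples,
    compute_dic,
    fit_bivariate,
    fit_univariate,
    genetic_correlation,
    posterior_mode_hpd,
    sample_residual_variance,
    select_models,
    variance_ratios,
)
from pedqg.pedigree import Pedigree, PedigreeRecord


def _sib_data(rng, n_fam=60, n_off=4, h2=0.4, vp=1.0, mean=5.0):
    """Full-sib families with additive-only architecture."""
    va, ve = h2 * vp, (1 - h2) * vp
    recs, rows = [], []
    for f in range(n_fam):
        d, s = f"d{f}", f"s{f}"
        recs += [PedigreeRecord(d, None, None, "F"), PedigreeRecord(s, None, None, "M")]
        ad, asir = rng.standard_normal(2) * np.sqrt(va)
        for o in range(n_off):
            iid = f"f{f}o{o}"
            recs.append(PedigreeRecord(iid, d, s, "U"))
            a = 0.5 * (ad + asir) + rng.standard_normal() * np.sqrt(0.5 * va)
            rows.append(dict(id=iid, y=mean + a + rng.standard_normal() * np.sqrt(ve)))
    return Pedigree(recs), pd.DataFrame(rows)


def _mock_samples(spec, columns):
    df = pd.DataFrame(columns)
    return PosteriorSamples(
        spec=spec, params=df, deviance=np.zeros(len(df)), deviance_at_mean=0.0,
        n_records=10,
    )


class TestSpec:
    def test_paper_schedule_sample_counts(self):
        spec = AnimalModelSpec.with_schedule("paper", traits=("y",))
        assert (spec.n_iter, spec.burn_in, spec.thin) == (1_000_000, 100_000, 100)
        assert spec.n_samples == 9_000

    def test_paper_bivariate_sample_counts(self):
        spec = AnimalModelSpec.with_schedule("paper_bivariate", traits=("y", "z"))
        assert spec.n_iter == 4_000_000
        assert spec.n_samples == 3_600

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ModelError):
            AnimalModelSpec(traits=("y",), n_iter=100, burn_in=100)
        with pytest.raises(ModelError):
            AnimalModelSpec(traits=("y",), thin=0)
        with pytest.raises(ModelError):
            AnimalModelSpec(traits=("y",), random_terms=("dominance",))
        with pytest.raises(ModelError):
            AnimalModelSpec(traits=())


class TestPosteriorModeHpd:
    def test_constant_vector(self):
        mode, (lo, hi) = posterior_mode_hpd(np.full(50, 0.3))
        assert (mode, lo, hi) == (0.3, 0.3, 0.3)

    def test_standard_normal(self):
        x = np.random.default_rng(1).standard_normal(100_000)
        mode, (lo, hi) = posterior_mode_hpd(x, 0.95)
        assert abs(mode) < 0.05
        assert abs(lo + 1.96) < 0.05
        assert abs(hi - 1.96) < 0.05

    def test_right_skew_mode_below_median(self):
        x = np.exp(np.random.default_rng(2).standard_normal(20_000))
        mode, _ = posterior_mode_hpd(x)
        assert mode < np.median(x)

    def test_bad_level(self):
        with pytest.raises(ModelError):
            posterior_mode_hpd(np.arange(20.0), level=1.5)


class TestVarianceRatios:
    def _spec(self):
        return AnimalModelSpec(traits=("y",), n_iter=20, burn_in=10, thin=1)

    def test_single_sample_arithmetic(self):
        s = _mock_samples(self._spec(), {"VA": [1.0], "VM": [1.0], "VE": [2.0]})
        vd = variance_ratios(s)
        assert vd.h2.mode == pytest.approx(0.25)
        assert vd.me2.mode == pytest.approx(0.25)
        assert vd.ne2.mode == 0.0

    def test_zero_va(self):
        s = _mock_samples(self._spec(), {"VA": np.zeros(20), "VE": np.ones(20)})
        assert np.all(variance_ratios(s).h2.samples == 0.0)

    def test_ratios_bounded(self, rng):
        s = _mock_samples(
            self._spec(),
            {"VA": rng.gamma(2, 1, 50), "VM": rng.gamma(2, 1, 50), "VE": rng.gamma(2, 1, 50)},
        )
        vd = variance_ratios(s)
        total = vd.h2.samples + vd.me2.samples + vd.ne2.samples
        assert np.all((total >= 0) & (total <= 1))


class TestGeneticCorrelation:
    def _spec(self):
        return AnimalModelSpec(traits=("y", "z"), n_iter=20, burn_in=10, thin=1)

    def test_zero_covariance(self):
        s = _mock_samples(
            self._spec(),
            {"VA_11": np.ones(20), "VA_12": np.zeros(20), "VA_22": np.ones(20),
             "VE_11": np.ones(20), "VE_12": np.zeros(20), "VE_22": np.ones(20)},
        )
        assert np.all(genetic_correlation(s)["r_G"].samples == 0.0)

    def test_half_covariance(self):
        s = _mock_samples(
            self._spec(),
            {"VA_11": np.ones(5), "VA_12": np.full(5, 0.5), "VA_22": np.ones(5)},
        )
        assert genetic_correlation(s)["r_G"].mode == pytest.approx(0.5)


class TestSelectModels:
    def test_paper_pattern_both_retained(self):
        cmp = select_models({"a": 100.0, "b": 105.17})
        assert cmp.delta == {"a": 0.0, "b": pytest.approx(5.17)}
        assert cmp.retained == ["a", "b"]

    def test_large_delta_excluded(self):
        cmp = select_models({"a": 100.0, "b": 112.4})
        assert cmp.retained == ["a"]

    def test_equal_dics(self):
        cmp = select_models({"a": 50.0, "b": 50.0})
        assert cmp.delta == {"a": 0.0, "b": 0.0}
        assert sorted(cmp.retained) == ["a", "b"]

    def test_needs_two(self):
        with pytest.raises(ModelError):
            select_models({"only": 1.0})


class TestConjugateChecks:
    def test_posterior_matches_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(150) * 1.7
        v, nu = 0.5, 1.0
        draws = sample_residual_variance(y, v, nu, 50_000, seed=11)
        shape = 0.5 * (nu + len(y))
        rate = 0.5 * (nu * v + float(y @ y))
        ks = stats.kstest(draws, stats.invgamma(shape, scale=rate).cdf)
        assert ks.statistic < 0.02

    def test_prior_predictive_matches_inverse_gamma(self):
        v, nu = 0.3, 1.0
        draws = sample_residual_variance(np.array([]), v, nu, 50_000, seed=12)
        ks = stats.kstest(draws, stats.invgamma(nu / 2, scale=nu * v / 2).cdf)
        assert ks.statistic < 0.02


class TestFitUnivariate:
    def test_determinism(self, rng):
        ped, df = _sib_data(rng, n_fam=20)
        spec = AnimalModelSpec(traits=("y",), n_iter=600, burn_in=100, thin=5, seed=3)
        f1 = fit_univariate(spec, df, ped)
        f2 = fit_univariate(spec, df, ped)
        assert f1.params.equals(f2.params)
        assert np.array_equal(f1.deviance, f2.deviance)

    def test_zero_variance_response(self, rng):
        ped, df = _sib_data(rng, n_fam=5)
        df["y"] = 1.0
        with pytest.raises(ModelError, match="zero variance"):
            fit_univariate(AnimalModelSpec(traits=("y",)), df, ped)

    def test_maternal_all_unknown_dams(self):
        recs = [PedigreeRecord(f"x{i}", None, None, "U") for i in range(12)]
        df = pd.DataFrame({"id": [f"x{i}" for i in range(12)], "y": np.arange(12.0)})
        with pytest.raises(ModelError, match="dam"):
            fit_univariate(
                AnimalModelSpec(traits=("y",), random_terms=("additive", "maternal"),
                                n_iter=20, burn_in=10, thin=1),
                df, Pedigree(recs),
            )

    def test_sample_count_and_positivity(self, rng):
        ped, df = _sib_data(rng, n_fam=15)
        spec = AnimalModelSpec(traits=("y",), n_iter=500, burn_in=100, thin=4, seed=1)
        fit = fit_univariate(spec, df, ped)
        assert fit.n_samples == spec.n_samples == 100
        assert np.all(fit.column("VA") > 0)
        assert np.all(fit.column("VE") > 0)

    def test_fast_and_general_paths_agree(self, rng):
        """Dual-route check: eigen fast path vs dense MME sampler."""
        ped, df = _sib_data(rng, n_fam=40, h2=0.5)
        spec = AnimalModelSpec(traits=("y",), n_iter=4_000, burn_in=1_000, thin=3, seed=5)
        fast = fit_univariate(spec, df, ped)

        y = df["y"].to_numpy()
        priors = am._resolve_priors(spec, y, 1)
        X, blocks = am._design(spec, df, ped)
        general = am._fit_general(spec, y[:, None], X, blocks, priors, t=1)
        for col in ("VA", "VE"):
            a, b = fast.column(col), general.column(col)
            assert np.mean(a) == pytest.approx(np.mean(b), rel=0.25)

    def test_h2_recovery_balanced_design(self, rng):
        # 200 families x 5 offspring, h2 = 0.5, schedule 50k/10k/10
        ped, df = _sib_data(rng, n_fam=200, n_off=5, h2=0.5)
        spec = AnimalModelSpec(traits=("y",), n_iter=50_000, burn_in=10_000, thin=10, seed=2)
        fit = fit_univariate(spec, df, ped)
        h2 = fit.column("VA") / (fit.column("VA") + fit.column("VE"))
        assert abs(float(h2.mean()) - 0.5) < 0.1

    def test_age_class_fixed_effect(self, rng):
        ped, df = _sib_data(rng, n_fam=15)
        df["age_class"] = np.where(np.arange(len(df)) % 2 == 0, "adult", "nestling")
        spec = AnimalModelSpec(
            traits=("y",), fixed=("intercept", "age_class"),
            n_iter=300, burn_in=100, thin=2, seed=4,
        )
        fit = fit_univariate(spec, df, ped)
        assert "b1" in fit.params.columns


class TestDic:
    def test_single_sample_equals_plugin(self, rng):
        ped, df = _sib_data(rng, n_fam=10)
        spec = AnimalModelSpec(traits=("y",), n_iter=2, burn_in=1, thin=1, seed=9)
        fit = fit_univariate(spec, df, ped)
        assert fit.n_samples == 1
        assert compute_dic(fit) == pytest.approx(float(fit.deviance[0]), rel=1e-9)

    def test_duplicated_data_doubles_mean_deviance(self, rng):
        ped, df = _sib_data(rng, n_fam=25, h2=0.3)
        spec = AnimalModelSpec(traits=("y",), n_iter=3_000, burn_in=1_000, thin=4, seed=6)
        fit1 = fit_univariate(spec, df, ped)
        # disjoint copy of the whole dataset: same design, twice the records
        recs2 = [r for r in ped] + [
            type(r)(r.id + "_b", r.dam and r.dam + "_b", r.sire and r.sire + "_b", r.sex)
            for r in ped
        ]
        ped2 = Pedigree(recs2)
        df2 = pd.concat([df, df.assign(id=df["id"] + "_b")], ignore_index=True)
        fit2 = fit_univariate(spec, df2, ped2)
        ratio = float(fit2.deviance.mean() / fit1.deviance.mean())
        assert 1.6 < ratio < 2.4


class TestFitBivariate:
    def test_identical_traits_rg_near_one(self, rng):
        ped, df = _sib_data(rng, n_fam=40, h2=0.5)
        df = df.rename(columns={"y": "t1"})
        df["t2"] = df["t1"]
        spec = AnimalModelSpec(traits=("t1", "t2"), n_iter=2_500, burn_in=800, thin=2, seed=8)
        fit = fit_bivariate(spec, df, ped)
        assert genetic_correlation(fit)["r_G"].mode > 0.95

    def test_blocks_positive_definite(self, rng):
        ped, df = _sib_data(rng, n_fam=30)
        df = df.rename(columns={"y": "t1"})
        df["t2"] = df["t1"] * 0.5 + rng.standard_normal(len(df))
        spec = AnimalModelSpec(traits=("t1", "t2"), n_iter=1_200, burn_in=400, thin=2, seed=3)
        fit = fit_bivariate(spec, df, ped)
        for blk in ("VA", "VE"):
            det = (
                fit.column(f"{blk}_11") * fit.column(f"{blk}_22")
                - fit.column(f"{blk}_12") ** 2
            )
            assert np.all(det > 0)
        r = genetic_correlation(fit)
        assert np.all(np.abs(r["r_G"].samples) <= 1.0)

    def test_determinism(self, rng):
        ped, df = _sib_data(rng, n_fam=15)
        df = df.rename(columns={"y": "t1"})
        df["t2"] = df["t1"] + rng.standard_normal(len(df))
        spec = AnimalModelSpec(traits=("t1", "t2"), n_iter=400, burn_in=100, thin=3, seed=7)
        assert fit_bivariate(spec, df, ped).params.equals(fit_bivariate(spec, df, ped).params)
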