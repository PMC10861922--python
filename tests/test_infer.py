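"""Statistical layer: mixtures, centering, mixed models, LRT/AICc, bootstrap."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shearshift import infer as inf
from shearshift import synthetic as syn


class TestMeanSstProxy:
    def test_uniform_field(self):
        cfg = syn.PopulationConfig(n_individuals=2, seed=0, sst_trend=0.0, sst_noise_sd=0.0)
        ds = syn.simulate_sst_grid(cfg, seed=0, lat_gradient=0.0)
        assert inf.mean_sst_proxy(ds, year=2012) == pytest.approx(cfg.sst_base, abs=1e-9)

    def test_latitude_gradient_averages_to_scalar(self):
        # the gradient is centered on the box, so the unweighted mean recovers
        # the per-year scalar exactly
        cfg = syn.PopulationConfig(n_individuals=2, seed=1)
        ds = syn.simulate_sst_grid(cfg, seed=1, lat_gradient=-0.3)
        table = syn.sst_table(cfg, seed=1)
        for year in (2010, 2014, 2018):
            assert inf.mean_sst_proxy(ds, year=year) == pytest.approx(
                inf.mean_sst_proxy(table, year=year), abs=1e-9
            )

    def test_latitude_weighting_shifts_gradient_mean(self):
        cfg = syn.PopulationConfig(n_individuals=2, seed=1)
        ds = syn.simulate_sst_grid(cfg, seed=1, lat_gradient=-0.3)
        plain = inf.mean_sst_proxy(ds, year=2012)
        weighted = inf.mean_sst_proxy(ds, year=2012, latitude_weighted=True)
        # cos weighting favours southern (warmer, with this gradient) cells
        assert weighted > plain

    def test_missing_months_error(self):
        cfg = syn.PopulationConfig(n_individuals=2, seed=1)
        ds = syn.simulate_sst_grid(cfg, seed=1)
        with pytest.raises(ValueError, match="missing"):
            inf.mean_sst_proxy(ds, year=2012, months=(6, 7))

    def test_table_missing_year_error(self):
        with pytest.raises(ValueError, match="missing"):
            inf.mean_sst_proxy(pd.DataFrame({"year": [2010], "sst_c": [18.0]}), year=2011)


class TestMixture:
    def _sample(self, n=120, seed=0):
        r = np.random.default_rng(seed)
        lats = np.concatenate([r.normal(38.5, 0.8, n // 2), r.normal(47.5, 0.8, n - n // 2)])
        truth = np.array(["south"] * (n // 2) + ["north"] * (n - n // 2))
        return lats, truth

    def test_well_separated_components_classified_perfectly(self):
        lats, truth = self._sample()
        fit = inf.fit_mixture(lats, seed=0)
        assert (fit.labels == truth).mean() == 1.0

    def test_log_likelihood_monotone(self):
        lats, _ = self._sample(seed=3)
        fit = inf.fit_mixture(lats, seed=3)
        assert np.all(np.diff(fit.ll_trace) >= -1e-9)
        assert fit.converged

    def test_matches_sklearn_oracle_likelihood(self):
        from sklearn.mixture import GaussianMixture

        lats, _ = self._sample(seed=5)
        fit = inf.fit_mixture(lats, seed=5)
        sk = GaussianMixture(2, tol=1e-8, n_init=5, random_state=0).fit(lats[:, None])
        assert fit.log_likelihood == pytest.approx(
            float(sk.score(lats[:, None])) * lats.size, abs=0.05
        )
        assert np.sort(fit.means) == pytest.approx(np.sort(sk.means_.ravel()), abs=0.05)

    def test_identical_values_degenerate_error(self):
        with pytest.raises(ValueError):
            inf.fit_mixture(np.full(20, 40.0), seed=0)

    def test_batch_classification(self, small_summaries):
        _, s = small_summaries
        labels = inf.batch_and_classify(s, seed=0)
        assert (labels == s["area"]).mean() > 0.99

    def test_small_batch_errors(self):
        s = pd.DataFrame({"year": [2010, 2010, 2011], "median_lat": [38, 39, 47]})
        with pytest.raises(ValueError, match="< 4"):
            inf.batch_and_classify(s)

    def test_uncovered_year_errors(self):
        s = pd.DataFrame({"year": [2009] * 5, "median_lat": [38, 39, 47, 48, 40]})
        with pytest.raises(ValueError, match="not covered"):
            inf.batch_and_classify(s)


class TestSubjectCenter:
    def test_two_observation_example(self):
        cp = inf.subject_center([16.0, 18.0], ["a", "a"])
        assert list(cp.between) == [17.0, 17.0]
        assert list(cp.within) == [-1.0, 1.0]

    def test_singleton_gets_zero_deviation(self):
        cp = inf.subject_center([21.3], ["a"])
        assert cp.within.iloc[0] == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 5_000))
    def test_reconstruction_identity_and_zero_sums(self, seed):
        r = np.random.default_rng(seed)
        n = r.integers(2, 40)
        vals = r.normal(15, 3, n)
        ids = r.integers(0, max(2, n // 3), n).astype(str)
        cp = inf.subject_center(vals, ids)
        assert np.allclose(cp.reconstruct(), vals)
        sums = pd.Series(cp.within.to_numpy()).groupby(pd.Series(ids)).sum()
        assert np.allclose(sums, 0.0)


def _lmm_fixture(seed=1, n_g=8, per=3):
    r = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_g), per)
    x1, x2 = r.normal(0, 1, n_g * per), r.normal(0, 1, n_g * per)
    u = r.normal(0, 0.8, n_g)[g]
    y = 1.0 + 0.5 * x1 - 0.3 * x2 + u + r.normal(0, 0.5, n_g * per)
    return pd.DataFrame(dict(y=y, x1=x1, x2=x2, g=g.astype(str)))


def _run_r(script: str) -> list[float]:
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    return [float(v) for v in out.stdout.split()]


class TestFitMixedModel:
    def test_gaussian_matches_lme4_oracle(self, tmp_path):
        df = _lmm_fixture()
        csv = tmp_path / "fix.csv"
        df.to_csv(csv, index=False)
        fit = inf.fit_mixed_model(
            inf.ModelSpec("y", ("x1", "x2"), random_intercept="g"), df
        )
        ref = _run_r(
            f'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            f'm <- lmer(y ~ x1 + x2 + (1|g), data=d, REML=FALSE);'
            f'cat(sprintf("%.10f ", c(fixef(m), as.numeric(logLik(m)))))'
        )
        assert fit.params.to_numpy() == pytest.approx(ref[:3], abs=1e-4)
        assert fit.llf == pytest.approx(ref[3], abs=1e-4)

    def test_binomial_glmm_matches_lme4_oracle(self, tmp_path):
        r = np.random.default_rng(2)
        g = np.repeat(np.arange(10), 3)
        x1 = r.normal(0, 1, 30)
        u = r.normal(0, 0.8, 10)[g]
        y = (r.random(30) < 1 / (1 + np.exp(-(0.3 + 0.8 * x1 + u)))).astype(int)
        df = pd.DataFrame(dict(y=y, x1=x1, g=g.astype(str)))
        csv = tmp_path / "fixb.csv"
        df.to_csv(csv, index=False)
        fit = inf.fit_mixed_model(
            inf.ModelSpec("y", ("x1",), random_intercept="g", family="binomial"), df
        )
        assert fit.approximation == "gauss-hermite(31)"
        ref = _run_r(
            f'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            f'm <- glmer(y ~ x1 + (1|g), data=d, family=binomial, nAGQ=25);'
            f'cat(sprintf("%.10f ", c(fixef(m), as.numeric(logLik(m)))))'
        )
        assert fit.params.to_numpy() == pytest.approx(ref[:2], abs=2e-3)
        assert fit.llf == pytest.approx(ref[2], abs=1e-3)

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.formula.api as smf

        r = np.random.default_rng(3)
        df = pd.DataFrame(
            dict(
                y=r.normal(0, 1, 60),
                x=r.normal(0, 1, 60),
                g=np.repeat(np.arange(20), 3).astype(str),
            )
        )
        df["y"] = 2.0 + 0.7 * df["x"] + r.normal(0, 0.5, 60)  # no group effect
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # variance may sit at the boundary
            fit = inf.fit_mixed_model(inf.ModelSpec("y", ("x",), random_intercept="g"), df)
        ols = smf.ols("y ~ x", df).fit()
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=0.02)

    def test_single_individual_errors(self):
        df = pd.DataFrame(dict(y=[1.0, 2.0], x=[0.0, 1.0], g=["a", "a"]))
        with pytest.raises(ValueError):
            inf.fit_mixed_model(inf.ModelSpec("y", ("x",), random_intercept="g"), df)

    def test_recovers_generative_slopes_within_2se(self, small_summaries):
        cfg, s = small_summaries
        d = inf.add_centered(s, "sst")
        fit = inf.fit_mixed_model(
            inf.ModelSpec("median_lat", ("sst_between", "sst_within", "C(area)", "C(sex)")),
            d,
        )
        for term, truth in (("sst_between", cfg.between_slope), ("sst_within", cfg.within_slope)):
            se = np.sqrt(fit.cov_params.loc[term, term])
            assert abs(fit.params[term] - truth) < 2 * se


class TestLrtAicc:
    def test_identical_models_give_zero_chi2_p_one(self):
        df = _lmm_fixture()
        spec = inf.ModelSpec("y", ("x1",), random_intercept="g")
        fit = inf.fit_mixed_model(spec, df)
        chi2, dof, p = inf.lrt(fit, fit)
        assert chi2 == 0.0 and dof == 0 and p == 1.0

    def test_non_nested_errors(self):
        df = _lmm_fixture()
        a = inf.fit_mixed_model(inf.ModelSpec("y", ("x1",), random_intercept="g"), df)
        b = inf.fit_mixed_model(inf.ModelSpec("y", ("x2",), random_intercept="g"), df)
        with pytest.raises(ValueError, match="nested"):
            inf.lrt(a, b)

    def test_aicc_reference_value(self):
        # AIC 100, k 3, n 30 -> 100 + 2*3*4/26 = 100.923
        assert inf.aicc_from_aic(100.0, 30, 3) == pytest.approx(100.923, abs=1e-3)

    def test_aicc_small_sample_error(self):
        with pytest.raises(ValueError):
            inf.aicc_from_aic(100.0, 4, 3)

    def test_aicc_approaches_aic_for_large_n(self):
        assert inf.aicc_from_aic(100.0, 10**5, 3) - 100.0 < 0.01

    def test_compare_with_self_is_zero(self):
        df = _lmm_fixture()
        fit = inf.fit_mixed_model(inf.ModelSpec("y", ("x1",), random_intercept="g"), df)
        assert inf.compare_aicc(fit, fit) == 0.0


class TestBootstrap:
    def _fit(self):
        return inf.fit_mixed_model(
            inf.ModelSpec("y", ("x1", "x2"), random_intercept="g"), _lmm_fixture()
        )

    def test_deterministic_given_seed(self):
        fit = self._fit()
        a = inf.bootstrap_effects(fit, n_draws=200, seed=4)
        b = inf.bootstrap_effects(fit, n_draws=200, seed=4)
        pd.testing.assert_frame_equal(a["draws"], b["draws"])

    def test_degenerate_covariance_collapses_to_point(self):
        fit = self._fit()
        fit.cov_params = fit.cov_params * 0.0
        out = inf.bootstrap_effects(fit, n_draws=100, seed=0, difference=("x1", "x2"))
        assert out["ci"].loc[0.025, "x1"] == pytest.approx(fit.params["x1"])
        assert out["difference_ci"][0] == pytest.approx(out["difference_ci"][1])

    def test_difference_ci_uses_paired_draws(self):
        fit = self._fit()
        out = inf.bootstrap_effects(fit, n_draws=4000, seed=1, difference=("x1", "x2"))
        d = fit.params["x1"] - fit.params["x2"]
        var = (
            fit.cov_params.loc["x1", "x1"]
            + fit.cov_params.loc["x2", "x2"]
            - 2 * fit.cov_params.loc["x1", "x2"]
        )
        lo, hi = d - 1.96 * np.sqrt(var), d + 1.96 * np.sqrt(var)
        assert out["difference_ci"][0] == pytest.approx(lo, abs=0.15 * np.sqrt(var) + 0.02)
        assert out["difference_ci"][1] == pytest.approx(hi, abs=0.15 * np.sqrt(var) + 0.02)


class TestDecomposeEffect:
    def test_latitude_slopes_recovered_with_cis(self, small_summaries):
        cfg, s = small_summaries
        dec = inf.decompose_effect(
            s, "median_lat", "sst", extra_terms=("C(area)", "C(sex)"), n_boot=500, seed=0
        )
        assert dec.between_ci[0] < cfg.between_slope < dec.between_ci[1]
        assert dec.within_ci[0] < cfg.within_slope < dec.within_ci[1]
        assert dec.lrt_within[2] < 0.05  # flexibility detectable at n=150

    def test_north_coded_as_one(self, small_summaries):
        _, s = small_summaries
        d = inf.add_centered(s.assign(north=(s["area"] == "north").astype(int)), "sst")
        fit = inf.fit_mixed_model(inf.PAPER_MODELS["area_choice"], d)
        # higher mean SST -> higher log-odds of the northern area, under the
        # north=1 coding of the generator and the model
        assert fit.params["sst_between"] > 0


class TestPaperModelTable:
    @pytest.mark.parametrize(
        "key,response,terms,family,random",
        [
            ("first_track_latitude", "median_lat",
             {"year", "C(area)", "C(sex)", "C(island)"}, "gaussian", None),
            ("median_latitude", "median_lat",
             {"sst_between", "sst_within", "C(area)", "C(sex)"}, "gaussian",
             "individual_id"),
            ("area_choice", "north",
             {"sst_between", "sst_within", "C(island)", "C(sex)"}, "binomial",
             "individual_id"),
            ("return_speed", "return_speed",
             {"max_lat_between", "max_lat_within", "outbound_speed", "C(area)", "C(sex)"},
             "gaussian", "individual_id"),
            ("departure_date", "departure_doy",
             {"max_lat_between", "max_lat_within", "C(area)", "C(island)"}, "gaussian",
             "individual_id"),
            ("return_date", "return_doy",
             {"max_lat_between", "max_lat_within", "C(area)", "C(island)"}, "gaussian",
             "individual_id"),
        ],
    )
    def test_model_structures(self, key, response, terms, family, random):
        spec = inf.PAPER_MODELS[key]
        assert spec.response == response
        assert set(spec.fixed_effects) == terms
        assert spec.family == family
        assert spec.random_intercept == random


class TestFirstTrackTrend:
    def test_recovers_generative_trend(self):
        # with a pure between-individual SST response and no area switching,
        # the first-track latitude trend is between_slope * sst_trend
        cfg = syn.PopulationConfig(
            n_individuals=400, seed=21, p_north_logit_slope=0.0, within_slope=0.0,
            sst_noise_sd=0.0,
        )
        s = syn.simulate_summaries(cfg, seed=21)
        out = inf.first_track_trend(s)
        expect = cfg.between_slope * cfg.sst_trend
        assert abs(out["slope_per_year"] - expect) < 2.5 * out["slope_se"]

    def test_aicc_comparison_present_with_sst(self, small_summaries):
        cfg, s = small_summaries
        out = inf.first_track_trend(s, sst=syn.sst_table(cfg, seed=7))
        assert out["delta_aicc"] == pytest.approx(out["aicc_year"] - out["aicc_sst"])
        assert out["f_df"][0] == 4  # whole-model F over 4 predictors
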