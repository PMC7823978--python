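"""Screen, mixed-model and full-protocol tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import leashwalk as lw
from leashwalk.stats_pipeline import (
    DEFAULT_CANDIDATES, Diagnostics, ModelFitError, ModelResult, ModelSpec,
    bivariate_screen, build_study_table, fit_mixed_model, residual_diagnostics,
    run_full_analysis, transform_column,
)
from leashwalk.synthetic_data import SimulationParams, simulate_outcome_table
from leashwalk.ethogram_metrics import TRANSFORM_LEDGER


def _toy_table(n=200, seed=0, slope=1.0, noise=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = slope * x + rng.normal(scale=noise, size=n)
    return pd.DataFrame({"y": y, "x": x, "z": z,
                         "c": np.ones(n),
                         "g": rng.choice(["a", "b", "c"], size=n)})


class TestBivariateScreen:
    def test_planted_predictor_kept_noise_usually_dropped(self):
        tab = _toy_table(slope=2.0, noise=0.5)
        shortlist = bivariate_screen(tab, "y", ["x", "z"], screen_alpha=0.01)
        assert "x" in shortlist

    def test_forced_predictor_always_kept(self):
        tab = _toy_table(slope=0.0, seed=1)
        shortlist = bivariate_screen(tab, "y", ["x", "z"], forced=["z"],
                                     screen_alpha=0.001)
        assert "z" in shortlist

    def test_constant_candidate_warns_and_is_excluded(self):
        tab = _toy_table()
        with pytest.warns(UserWarning, match="constant"):
            shortlist = bivariate_screen(tab, "y", ["x", "c"])
        assert "c" not in shortlist

    def test_alpha_monotone(self):
        tab = _toy_table(seed=4, slope=0.15)
        tight = set(bivariate_screen(tab, "y", ["x", "z", "g"],
                                     screen_alpha=0.01))
        loose = set(bivariate_screen(tab, "y", ["x", "z", "g"],
                                     screen_alpha=0.5))
        assert tight <= loose

    def test_candidate_order_invariance(self):
        tab = _toy_table(seed=5)
        a = bivariate_screen(tab, "y", ["x", "z", "g"], screen_alpha=0.5)
        b = bivariate_screen(tab, "y", ["g", "x", "z"], screen_alpha=0.5)
        assert set(a) == set(b)

    def test_categorical_candidate_uses_block_f_test(self):
        rng = np.random.default_rng(6)
        g = rng.choice(["a", "b"], size=300)
        y = np.where(g == "a", 0.0, 2.0) + rng.normal(size=300)
        tab = pd.DataFrame({"y": y, "g": g})
        assert bivariate_screen(tab, "y", ["g"], screen_alpha=0.05) == ["g"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            bivariate_screen(_toy_table(), "y", [])


class TestFitMixedModel:
    def test_recovers_planted_effect(self, full_design, full_cohort):
        params = SimulationParams(
            covariate_effects={"nt_max": {"socialisation": -0.2}})
        tab, _ = simulate_outcome_table(full_design, full_cohort, params,
                                        seed=21)
        spec = ModelSpec(outcome="y", fixed_effects=("socialisation", "weight"))
        fit = fit_mixed_model(tab, spec)
        beta = fit.params.loc["socialisation", "beta"]
        se = fit.params.loc["socialisation", "se"]
        assert abs(beta - (-0.2)) < 4 * se
        assert fit.params.loc["socialisation", "p"] < 1e-6
        assert set(fit.vcomp) == {"dog_id", "walker_id"}
        assert fit.converged

    def test_variance_components_positive_when_planted(self, full_design,
                                                       full_cohort):
        params = SimulationParams(random_sd_dog=0.3, random_sd_walker=0.2)
        tab, _ = simulate_outcome_table(full_design, full_cohort, params,
                                        seed=22)
        fit = fit_mixed_model(tab, ModelSpec(outcome="y",
                                             fixed_effects=("weight",)))
        assert fit.vcomp["dog_id"] > 0.0
        assert fit.vcomp["walker_id"] > 0.0
        assert not fit.singular

    def test_zero_variance_limit_equals_ols(self):
        # the closed-form no-random-effects path must agree with an
        # independent least-squares implementation to 1e-6 relative
        tab = _toy_table(n=150, seed=30, slope=0.7)
        fit = fit_mixed_model(tab, ModelSpec(outcome="y",
                                             fixed_effects=("x", "z"),
                                             random_effects=()))
        X = sm.add_constant(tab[["x", "z"]].to_numpy())
        ref = sm.OLS(tab["y"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.params["beta"].to_numpy(),
                                   ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.params["se"].to_numpy(),
                                   ref.bse, rtol=1e-6)
        np.testing.assert_allclose(fit.params["p"].to_numpy(),
                                   ref.pvalues, rtol=1e-6, atol=1e-300)

    def test_empty_shortlist_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            fit_mixed_model(_toy_table(), ModelSpec(outcome="y",
                                                    fixed_effects=()))

    def test_constant_fixed_effect_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_mixed_model(_toy_table(),
                            ModelSpec(outcome="y", fixed_effects=("c",),
                                      random_effects=()))

    def test_single_level_random_effect_rejected(self):
        tab = _toy_table(n=50)
        tab["dog_id"] = "D001"
        tab["walker_id"] = [f"W{i % 5}" for i in range(50)]
        with pytest.raises(ValueError, match="levels"):
            fit_mixed_model(tab, ModelSpec(outcome="y", fixed_effects=("x",)))


class TestDiagnostics:
    def _ols_result(self, y, x):
        tab = pd.DataFrame({"y": y, "x": x})
        return fit_mixed_model(tab, ModelSpec(outcome="y",
                                              fixed_effects=("x",),
                                              random_effects=()))

    def test_gaussian_residuals_usually_pass(self):
        # the normality check is a 5%-level test: over 20 independent
        # Gaussian fits it should pass in the vast majority
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=370)
            y = 0.5 * x + rng.normal(size=370)
            diag = residual_diagnostics(self._ols_result(y, x))
            assert 0.0 <= diag.resid_shapiro_p <= 1.0
            ok += diag.resid_normality_ok
        assert ok >= 14

    def test_heavy_tailed_residuals_fail_normality(self):
        rng = np.random.default_rng(40)
        x = rng.normal(size=370)
        y = 0.5 * x + rng.standard_t(df=2, size=370)
        diag = residual_diagnostics(self._ols_result(y, x))
        assert not diag.resid_normality_ok

    def test_heteroscedastic_residuals_fail_levene(self):
        rng = np.random.default_rng(41)
        x = rng.uniform(0, 1, size=500)
        y = 2.0 * x + rng.normal(scale=0.05 + 2.0 * x, size=500)
        diag = residual_diagnostics(self._ols_result(y, x))
        assert not diag.variance_homogeneity_ok

    def test_constant_residuals_reported_degenerate(self):
        result = ModelResult(params=pd.DataFrame(), vcomp={},
                             residual_var=0.0, converged=True, singular=False,
                             n_obs=10, resid=np.zeros(10),
                             fitted=np.arange(10.0))
        diag = residual_diagnostics(result)
        assert diag.degenerate
        assert not diag.resid_normality_ok

    def test_ranef_shapiro_reported(self, full_design, full_cohort):
        params = SimulationParams(random_sd_dog=0.3)
        tab, _ = simulate_outcome_table(full_design, full_cohort, params,
                                        seed=23)
        fit = fit_mixed_model(tab, ModelSpec(outcome="y",
                                             fixed_effects=("weight",)))
        diag = residual_diagnostics(fit)
        assert "dog_id" in diag.ranef_shapiro


class TestTransformColumn:
    def test_per_row_duration_offsets(self):
        spec = TRANSFORM_LEDGER["dpf"]
        out = transform_column(np.array([0.0, 0.02]), spec,
                               durations=np.array([600.0, 600.0]))
        np.testing.assert_allclose(
            out, np.log10(np.array([0.0, 0.02]) + 1 / 600))

    def test_missing_durations_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            transform_column(np.array([0.1]), TRANSFORM_LEDGER["dpf"])


class TestFullProtocol:
    def test_build_study_table_shape(self, small_bundle):
        table = build_study_table(small_bundle)
        assert len(table) == len(small_bundle.design)
        for col in ("nt_max", "dpf", "track_pct", "factor_h",
                    "socialisation", "weight", "walker_id"):
            assert col in table.columns, col

    def test_run_full_analysis_produces_family_tables(self, small_bundle,
                                                      tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_full_analysis(small_bundle, out_dir=tmp_path)
        assert set(results) == {"tension", "dog_behaviour", "verbal_cue",
                                "body_language", "questionnaire"}
        assert (tmp_path / "run_manifest.json").exists()
        for family in results:
            assert (tmp_path / f"table_{family}.csv").exists()

    def test_run_full_analysis_deterministic(self, small_bundle):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_full_analysis(small_bundle)
            b = run_full_analysis(small_bundle)
        for family in a:
            pd.testing.assert_frame_equal(a[family], b[family])

    def test_unledgered_outcome_refused(self, small_bundle):
        with pytest.raises(KeyError, match="ledger"):
            run_full_analysis(small_bundle,
                              outcomes={"bogus": ("sit_rate",)})

    def test_end_to_end_planted_effect_detected(self, full_design,
                                                full_cohort):
        # a strong planted effect of the socialisation score on maximal
        # tension must survive detection, transformation, screening and the
        # mixed model with the correct sign
        params = SimulationParams(
            walk_duration=300.0,
            covariate_effects={"nt_max": {"socialisation": -0.1}})
        bundle = lw.simulate_study(full_design, full_cohort, params, seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_full_analysis(bundle,
                                        outcomes={"tension": ("nt_max",)})
        row = results["tension"].loc["socialisation"]
        assert row["nt_max_beta"] < 0
        assert row["nt_max_p"] < 0.01
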