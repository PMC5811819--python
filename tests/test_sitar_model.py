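"""The SITAR mixed-effects fit: recovery, likelihood accuracy, equivariance
and reporting."""

import warnings

import numpy as np
import pandas as pd
import pytest

import sitar
from quadrature_oracle import gh_marginal_loglik
from sitar.growth_tables import GrowthTable
from sitar.sitar_model import SitarFit
from sitar.synthetic_data import SurveyEffect, SyntheticSpec, make_template, simulate_surveys


def small_table(noise_sd=0.1, seed=4, ages=tuple(np.arange(1.5, 20, 2.0))):
    """Five-survey instance that fits fast, for equivariance checks."""
    eff = tuple(
        SurveyEffect(f"s{i}", 1960 + 10 * i, a, b, g)
        for i, (a, b, g) in enumerate(
            [(-3, 0.5, -0.04), (-1.5, 0.25, -0.02), (0, 0, 0), (1.5, -0.25, 0.02), (3, -0.5, 0.04)]
        )
    )
    spec = SyntheticSpec(
        template=make_template("height_like", "male"),
        surveys=eff,
        noise_sd=noise_sd,
        age_grid=ages,
        seed=seed,
    )
    return spec, simulate_surveys(spec)


def shift_values(table, k):
    df = table.data.copy()
    df["value"] = df["value"] + k
    return GrowthTable(data=df, mode=table.mode)


def shift_ages(table, k):
    df = table.data.copy()
    df["age"] = df["age"] + k
    return GrowthTable(data=df, mode=table.mode)


class TestFitRecovery:
    def test_recovers_known_effects(self, height_fit, height_spec):
        truth = height_spec.truth_effects()
        est = height_fit.random_effects
        assert height_fit.converged
        for col, tol in [("alpha", 0.3), ("beta", 0.1), ("gamma", 0.01)]:
            err = est[col].to_numpy() - truth[col].to_numpy()
            assert np.mean(np.abs(err)) < tol, col
            assert np.corrcoef(est[col], truth[col])[0, 1] > 0.95, col

    def test_random_effects_zero_mean(self, height_fit):
        for col in ("alpha", "beta", "gamma"):
            assert abs(height_fit.random_effects[col].mean()) < 1e-6

    def test_covariance_psd_and_residual_near_noise(self, height_fit, height_spec):
        eig = np.linalg.eigvalsh(height_fit.re_covariance)
        assert eig.min() > -1e-10
        # residual sd = generator noise + spline approximation error
        assert height_spec.noise_sd < height_fit.residual_sd < 3 * height_spec.noise_sd

    def test_loglik_matches_reevaluation(self, height_fit, height_table):
        assert sitar.marginal_loglik(height_fit, height_table) == pytest.approx(
            height_fit.loglik, abs=0.2
        )

    def test_deterministic(self, height_table, height_fit):
        again = sitar.fit_sitar(height_table, df=6)
        assert again.loglik == pytest.approx(height_fit.loglik, abs=1e-6)
        pd.testing.assert_frame_equal(again.random_effects, height_fit.random_effects)

    def test_single_survey_rejected(self, height_table):
        one = GrowthTable(
            data=height_table.for_survey(height_table.surveys[0]).reset_index(drop=True),
            mode="period",
        )
        with pytest.raises(ValueError, match="at least 2"):
            sitar.fit_sitar(one, df=6)

    def test_identical_surveys_have_null_effects(self):
        spec = SyntheticSpec(
            template=make_template("height_like", "male"),
            surveys=tuple(SurveyEffect(f"s{i}", 1960 + i, 0, 0, 0) for i in range(5)),
            noise_sd=0.05,
            seed=8,
        )
        table = simulate_surveys(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sitar.fit_sitar(table, df=6)
        assert np.max(np.abs(fit.random_effects["alpha"])) < 0.1
        assert np.max(np.abs(fit.random_effects["beta"])) < 0.1
        assert np.max(np.abs(fit.random_effects["gamma"])) < 0.01
        assert sitar.variance_explained(fit, table) < 15.0


@pytest.fixture(scope="module")
def base():
    _, table = small_table()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return table, sitar.fit_sitar(table, df=5)


class TestEquivariance:

    def test_value_translation_moves_only_size_intercept(self, base):
        table, fit = base
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            shifted = sitar.fit_sitar(shift_values(table, 7.0), df=5)
        assert shifted.fixed_effects["a0"] - fit.fixed_effects["a0"] == pytest.approx(7.0, abs=0.05)
        np.testing.assert_allclose(
            shifted.random_effects["beta"], fit.random_effects["beta"], atol=0.02
        )
        np.testing.assert_allclose(
            shifted.random_effects["gamma"], fit.random_effects["gamma"], atol=0.002
        )
        assert shifted.loglik == pytest.approx(fit.loglik, abs=0.5)

    def test_age_shift_moves_only_timing_intercept(self, base):
        table, fit = base
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            shifted = sitar.fit_sitar(shift_ages(table, 3.0), df=5)
        assert shifted.fixed_effects["b0"] - fit.fixed_effects["b0"] == pytest.approx(3.0, abs=0.05)
        np.testing.assert_allclose(
            shifted.random_effects["alpha"], fit.random_effects["alpha"], atol=0.05
        )
        assert shifted.loglik == pytest.approx(fit.loglik, abs=0.5)


class TestMarginalLikelihood:
    def test_agrees_with_quadrature_on_tiny_instances(self, height_fit, height_table):
        for surveys, ages in [
            (["Japan-like 1950", "Korea-like 2005"], [2.5, 12.5, 17.5]),
            (["Japan-like 1980", "Korea-like 1965"], [3.5, 10.5, 15.5]),
        ]:
            sub = height_table.data[
                height_table.data["survey"].isin(surveys)
                & height_table.data["age"].isin(ages)
            ].reset_index(drop=True)
            subtable = GrowthTable(data=sub, mode="period")
            assert subtable.n_obs <= 6
            laplace = sitar.marginal_loglik(height_fit, subtable)
            quad = gh_marginal_loglik(height_fit, subtable)
            assert abs(laplace - quad) < 0.05

    def test_zero_variance_limit_is_fixed_effects_gaussian(self, height_fit, height_table):
        from scipy.stats import norm

        collapsed = SitarFit.from_dict(height_fit.to_dict())
        collapsed.re_covariance = np.zeros((3, 3))
        ll = sitar.marginal_loglik(collapsed, height_table)
        pred = collapsed.predict_transformed(height_table.data["age"].to_numpy(), "mean")
        expected = norm.logpdf(
            height_table.data["value"].to_numpy(), pred, collapsed.residual_sd
        ).sum()
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_inflating_residual_sd_lowers_loglik(self, height_fit, height_table):
        collapsed = SitarFit.from_dict(height_fit.to_dict())
        collapsed.re_covariance = np.zeros((3, 3))
        resid = height_table.data["value"].to_numpy() - collapsed.predict_transformed(
            height_table.data["age"].to_numpy(), "mean"
        )
        # at the ML residual SD for these residuals, any inflation must cost
        collapsed.residual_sd = float(np.sqrt(np.mean(resid**2)))
        base = sitar.marginal_loglik(collapsed, height_table)
        collapsed.residual_sd *= 2
        assert sitar.marginal_loglik(collapsed, height_table) < base


class TestInformationCriteria:
    def test_bic_formula(self, height_fit):
        dummy = SitarFit.from_dict(height_fit.to_dict())
        dummy.loglik, dummy.n_param, dummy.n_obs = -100.0, 5, 240
        assert sitar.bic(dummy) == pytest.approx(200 + 5 * np.log(240))
        dummy.n_param = 6
        assert sitar.bic(dummy) > 200 + 5 * np.log(240)

    def test_parameter_count(self, height_fit):
        # df-1 spline coefficients + 3 fixed effects + 6 covariance + residual
        assert height_fit.n_param == (6 - 1) + 3 + 6 + 1

    def test_select_df_degenerate_range(self, height_table, height_fit):
        best, scan = sitar.select_df(height_table, df_range=(6,))
        assert best == 6
        assert len(scan) == 1
        assert scan["bic"].iloc[0] == pytest.approx(sitar.bic(height_fit), abs=0.5)

    def test_select_df_range_validated(self, height_table):
        with pytest.raises(ValueError, match=r"\[4, 10\]"):
            sitar.select_df(height_table, df_range=(3, 6))


class TestReporting:
    def test_effects_table_units(self, height_fit):
        eff = sitar.effects_table(height_fit)
        re = height_fit.random_effects
        np.testing.assert_allclose(eff["size"], re["alpha"])  # identity size scale
        np.testing.assert_allclose(eff["timing"], re["beta"])  # identity age scale
        np.testing.assert_allclose(eff["intensity_pct"], 100 * re["gamma"])

    def test_intensity_percent_semantics(self, height_fit):
        modified = SitarFit.from_dict(height_fit.to_dict())
        modified.random_effects.loc[0, "gamma"] = 0.04
        eff = sitar.effects_table(modified)
        assert eff.loc[0, "intensity_pct"] == pytest.approx(4.0)

    def test_variance_explained_formula_and_range(self, height_fit, height_table):
        ve = sitar.variance_explained(height_fit, height_table)
        assert 0.0 <= ve <= 100.0
        # the superimposition removes nearly all between-survey variance
        assert ve > 95.0

    def test_adjusted_curves_superimpose_on_mean_curve(self, height_fit, height_table):
        from sitar.scale_selection import backtransform_curve

        adj = sitar.adjusted_curves(height_fit, height_table)
        mean_at = backtransform_curve(height_fit, "mean", adj["adjusted_age"].to_numpy())
        resid = adj["adjusted_value"].to_numpy() - mean_at
        rms = np.sqrt(np.mean(resid**2))
        assert rms == pytest.approx(height_fit.residual_sd, rel=0.5)

    def test_adjusted_curves_identity_when_effects_zero(self, height_fit, height_table):
        nulled = SitarFit.from_dict(height_fit.to_dict())
        nulled.random_effects[["alpha", "beta", "gamma"]] = 0.0
        adj = sitar.adjusted_curves(nulled, height_table)
        np.testing.assert_allclose(adj["adjusted_age"], height_table.data["age"])
        np.testing.assert_allclose(adj["adjusted_value"], height_table.data["value"])

    def test_fit_json_round_trip(self, height_fit, height_table):
        again = SitarFit.from_dict(height_fit.to_dict())
        ages = np.linspace(2.0, 19.0, 7)
        np.testing.assert_allclose(
            again.predict_transformed(ages, "Japan-like 1990"),
            height_fit.predict_transformed(ages, "Japan-like 1990"),
        )
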