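"""Design generation, screening effects, response-surface fit and optimization."""

import numpy as np
import pandas as pd
import pytest

from enzkit import celc307
from enzkit.doe import (
    FactorSpec,
    ResponseSurface,
    box_behnken_design,
    central_composite_design,
    optimize_response,
    pb_effect_screen,
    plackett_burman_design,
    quadratic_model_from_coefficients,
)
from enzkit.exceptions import EnzkitError
from enzkit.synthetic import simulate_doe_response

FACTORS = celc307.RSM_FACTORS


class TestPlackettBurman:
    @pytest.mark.parametrize("n_factors", range(1, 12))
    def test_balance_and_orthogonality(self, n_factors):
        d = plackett_burman_design(n_factors)
        X = d.coded
        assert X.shape == (12, 11)
        assert np.all(np.abs(X.sum(axis=0)) == 0)  # six +1 and six −1 per column
        gram = X.T @ X
        assert np.all(gram[~np.eye(11, dtype=bool)] == 0)

    def test_seven_factors_leave_four_dummies(self):
        d = plackett_burman_design(7)
        assert d.dummy_columns == [7, 8, 9, 10]

    def test_too_many_factors(self):
        with pytest.raises(EnzkitError, match="design too small"):
            plackett_burman_design(12)

    def test_constant_response_gives_zero_effects(self):
        d = plackett_burman_design(7)
        effects = pb_effect_screen(d, np.full(12, 5.0))
        assert all(e.effect == 0.0 for e in effects)

    def test_dominant_factor_ranked_first_and_significant(self):
        d = plackett_burman_design(7)
        rng = np.random.default_rng(1)
        y = 2.0 * d.coded[:, 0] + rng.normal(0, 0.1, 12)
        effects = pb_effect_screen(d, y)
        assert effects[0].column == 0
        assert effects[0].significant
        # effect equals twice the OLS slope on the coded column
        slope = np.linalg.lstsq(
            np.column_stack([np.ones(12), d.coded[:, 0]]), y, rcond=None
        )[0][1]
        assert effects[0].effect == pytest.approx(2 * slope, rel=1e-10)

    def test_lenth_method_available(self):
        d = plackett_burman_design(7)
        rng = np.random.default_rng(2)
        y = 3.0 * d.coded[:, 1] + rng.normal(0, 0.1, 12)
        effects = pb_effect_screen(d, y, method="lenth")
        assert effects[0].column == 1


class TestCentralComposite:
    def test_axial_distance_is_fourth_root_of_eight(self):
        d = central_composite_design(FACTORS, n_center=6, blocks=True)
        assert d.n_runs == 20
        assert np.max(np.abs(d.coded)) == pytest.approx(8**0.25, rel=1e-12)

    def test_reference_natural_axial_levels(self):
        d = central_composite_design(FACTORS, n_center=6, blocks=True)
        nat = d.natural
        assert sorted(np.round(np.unique(nat[:, 0]), 2)) == [3.98, 5.0, 6.5, 8.0, 9.02]
        assert sorted(np.round(np.unique(nat[:, 1]), 2)) == [13.18, 20.0, 30.0, 40.0, 46.82]
        assert sorted(np.round(np.unique(nat[:, 2]), 2)) == [0.06, 0.3, 0.65, 1.0, 1.24]

    def test_coded_columns_centered(self):
        d = central_composite_design(FACTORS, n_center=6)
        assert np.allclose(d.coded.mean(axis=0), 0.0, atol=1e-12)

    def test_rotatability(self):
        # prediction variance on a coded sphere depends only on the radius
        d = central_composite_design(FACTORS, n_center=6)
        from enzkit.doe import _quadratic_columns

        X, _ = _quadratic_columns(d.coded, ["A", "B", "C"])
        X = np.column_stack([np.ones(d.n_runs), X])
        XtXi = np.linalg.inv(X.T @ X)
        rng = np.random.default_rng(0)
        variances = []
        for _ in range(100):
            u = rng.normal(size=3)
            u = 1.3 * u / np.linalg.norm(u)
            x, _ = _quadratic_columns(u[None, :], ["A", "B", "C"])
            x = np.concatenate([[1.0], x.ravel()])
            variances.append(float(x @ XtXi @ x))
        assert np.ptp(variances) < 1e-6


class TestBoxBehnken:
    def test_structure(self):
        d = box_behnken_design(FACTORS, n_center=3)
        assert d.n_runs == 15
        edge = d.coded[:12]
        assert np.all((edge == 0).sum(axis=1) == 1)  # exactly one factor at 0
        assert not np.any(np.all(np.abs(edge) == 1, axis=1))  # no corners
        assert np.allclose(d.coded.sum(axis=0), 0.0)


class TestResponseSurfaceFit:
    def test_noiseless_quadratic_recovered_exactly(self):
        d = central_composite_design(FACTORS, n_center=6)
        truth = dict(celc307.RSM_EQUATION)
        y = simulate_doe_response(d, truth)
        model = ResponseSurface(d, y).fit()
        for name, val in truth.items():
            assert model.coef_natural[name] == pytest.approx(val, rel=1e-6, abs=1e-9)
        assert model.anova.loc["Residual", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_anova_partition_identities(self):
        df = celc307.rsm_dataframe()
        model = ResponseSurface.from_dataframe(df, FACTORS).fit()
        a = model.anova
        ss_parts = a.loc["Block", "SS"] + a.loc["Model", "SS"] + a.loc["Residual", "SS"]
        assert ss_parts == pytest.approx(a.loc["Cor total", "SS"], rel=1e-8)
        assert a.loc["Lack of fit", "SS"] + a.loc["Pure error", "SS"] == pytest.approx(
            a.loc["Residual", "SS"], rel=1e-10
        )
        df_parts = (
            a.loc["Block", "df"] + a.loc["Model", "df"] + a.loc["Residual", "df"]
        )
        assert df_parts == a.loc["Cor total", "df"] == 19

    def test_reference_refit_matches_reported_anova(self):
        df = celc307.rsm_dataframe()
        model = ResponseSurface.from_dataframe(df, FACTORS).fit()
        assert model.model_f == pytest.approx(celc307.RSM_ANOVA_REPORTED["model_F"], rel=0.02)
        assert model.lack_of_fit_f == pytest.approx(
            celc307.RSM_ANOVA_REPORTED["lack_of_fit_F"], rel=0.02
        )
        assert model.anova.loc["Block", "SS"] == pytest.approx(0.6135, abs=0.001)
        assert model.anova.loc["Pure error", "SS"] == pytest.approx(5.07, abs=0.01)
        assert model.coef_natural["C"] == pytest.approx(17.39, abs=0.05)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        df = celc307.rsm_dataframe()
        model = ResponseSurface.from_dataframe(df, FACTORS).fit()
        A, B, C = (df[f.name].to_numpy() for f in FACTORS)
        blk = (df["block"] == 2).astype(float).to_numpy()
        X = sm.add_constant(
            np.column_stack([blk, A, B, C, A * B, A * C, B * C, A**2, B**2, C**2])
        )
        ols = sm.OLS(df["response"].to_numpy(), X).fit()
        names = ["A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2"]
        for i, n in enumerate(names):
            assert model.coef_natural[n] == pytest.approx(ols.params[i + 2], rel=1e-8)

    def test_coefficient_recovery_within_confidence_intervals(self):
        # 95% CIs should cover the generating coefficients ~95% of the time
        d = central_composite_design(FACTORS, n_center=6)
        truth = dict(celc307.RSM_EQUATION)
        names = list(truth)
        cover = {n: 0 for n in names}
        n_seeds = 40
        for seed in range(n_seeds):
            y = simulate_doe_response(d, truth, noise_sd=1.0, seed=seed)
            m = ResponseSurface(d, y).fit()
            for n in names:
                half = 2.262 * m.coef_se_natural[n]  # t(0.975, 9 df)
                if abs(m.coef_natural[n] - truth[n]) <= half:
                    cover[n] += 1
        for n in names:
            assert cover[n] >= 0.90 * n_seeds, f"{n}: {cover[n]}/{n_seeds}"


class TestOptimization:
    def test_interior_concave_optimum_closed_form(self):
        coef = {
            "Intercept": 0.0, "A": 2.0, "B": 4.0, "C": 0.0,
            "AB": 0.0, "AC": 0.0, "BC": 0.0, "A^2": -1.0, "B^2": -2.0, "C^2": -1.0,
        }
        model = quadratic_model_from_coefficients(FACTORS, coef)
        point, value = optimize_response(model, [(-5, 5), (-5, 5), (-5, 5)])
        assert point == pytest.approx([1.0, 1.0, 0.0], abs=1e-9)
        assert value == pytest.approx(3.0, abs=1e-9)

    def test_reference_surface_boundary_optimum(self):
        model = quadratic_model_from_coefficients(FACTORS, celc307.RSM_EQUATION)
        point, value = optimize_response(model, celc307.RSM_BOUNDS)
        # optimum sits on the low-temperature, high-inoculum boundary
        assert point[1] == pytest.approx(20.0, abs=1e-6)
        assert point[2] == pytest.approx(1.0, abs=1e-6)
        assert 55.6 < value < 55.8
        # the reported optimum point evaluates just below the box maximum
        at_reported = model.predict([7.5, 20.0, 1.0])[0]
        assert at_reported == pytest.approx(55.68, abs=0.01)

    def test_linear_model_optimum_at_corner(self):
        coef = {k: 0.0 for k in celc307.RSM_EQUATION}
        coef.update({"Intercept": 1.0, "A": 1.0, "B": -1.0, "C": 2.0})
        model = quadratic_model_from_coefficients(FACTORS, coef)
        point, _ = optimize_response(model, [(0, 1), (0, 1), (0, 1)])
        assert point == pytest.approx([1.0, 0.0, 1.0], abs=1e-9)


class TestSyntheticDOE:
    def test_noise_free_simulation_is_fixed_point(self):
        d = central_composite_design(FACTORS, n_center=6, blocks=True)
        truth = dict(celc307.RSM_EQUATION)
        y = simulate_doe_response(d, truth, block_effects={1: 0.0, 2: 0.5})
        m = ResponseSurface(d, y, include_block=True).fit()
        for name, val in truth.items():
            if name == "Intercept":
                continue
            assert m.coef_natural[name] == pytest.approx(val, rel=1e-6, abs=1e-9)

    def test_pure_error_expectation(self):
        # E[SS_pe] = df_pe · σ²; check the average over seeds
        d = central_composite_design(FACTORS, n_center=6, blocks=True)
        truth = dict(celc307.RSM_EQUATION)
        sses = []
        for seed in range(200):
            y = simulate_doe_response(d, truth, noise_sd=1.0, seed=seed)
            m = ResponseSurface(d, y, include_block=True).fit()
            sses.append(m.anova.loc["Pure error", "SS"])
        df_pe = 4
        mean = np.mean(sses)
        # chi-square mean ± 4 SD band
        sd_of_mean = np.sqrt(2 * df_pe / 200)
        assert abs(mean - df_pe) < 4 * sd_of_mean
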