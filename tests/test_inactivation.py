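"""First-order thermal inactivation: rates, half-lives, D-values, thermodynamics."""

import numpy as np
import pytest

from enzkit.constants import R
from enzkit.exceptions import DegenerateDataError, InsufficientDataError
from enzkit.inactivation import (
    InactivationTimecourse,
    ThermalInactivation,
    fit_inactivation_rate,
    half_life_and_D,
    inactivation_activation_energy,
    inactivation_state_functions,
)
from enzkit.synthetic import simulate_inactivation_panel

T40 = 313.15


class TestRateFit:
    def test_exact_exponential(self):
        t = np.array([0.0, 60.0, 120.0, 240.0, 360.0])
        tc = InactivationTimecourse(T40, t, np.exp(-0.05 * t))
        res = fit_inactivation_rate(tc)
        assert res.k_in == pytest.approx(0.05, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_zero_intercept_closed_form(self):
        rng = np.random.default_rng(3)
        t = np.array([0.0, 30.0, 60.0, 120.0, 180.0, 240.0])
        f = np.exp(-0.01 * t) * np.exp(rng.normal(0, 0.02, t.size))
        res = fit_inactivation_rate(InactivationTimecourse(T40, t, f))
        k_closed = -float(t @ np.log(f)) / float(t @ t)
        assert res.k_in == pytest.approx(k_closed, rel=1e-12)
        # and within 3 SE of the generating constant
        se = 0.02 / np.sqrt(float(t @ t))
        assert abs(res.k_in - 0.01) < 3 * se

    def test_nonpositive_fractions_dropped(self):
        t = np.array([0.0, 60.0, 120.0, 240.0])
        f = np.array([1.0, 0.5, 0.0, 0.1])
        with pytest.warns(UserWarning, match="dropped"):
            res = fit_inactivation_rate(InactivationTimecourse(T40, t, f))
        assert res.n_dropped == 1

    def test_rising_activity_flags_activation(self):
        t = np.array([0.0, 60.0, 120.0, 240.0])
        with pytest.warns(UserWarning, match="activation, not inactivation"):
            res = fit_inactivation_rate(InactivationTimecourse(T40, t, np.exp(0.002 * t)))
        assert res.k_in < 0

    def test_all_dropped_is_error(self):
        t = np.array([0.0, 60.0, 120.0])
        with pytest.warns(UserWarning):
            with pytest.raises(InsufficientDataError, match="no decay data"):
                fit_inactivation_rate(InactivationTimecourse(T40, t, np.array([1.0, -0.1, -0.2])))


class TestHalfLifeAndD:
    def test_identity_k(self):
        th, _ = half_life_and_D(np.log(2))
        assert th == pytest.approx(1.0, rel=1e-12)

    def test_reference_rate(self):
        th, D = half_life_and_D(1.62e-2)
        assert th == pytest.approx(42.787, abs=0.01)
        assert D == pytest.approx(142.13, abs=0.01)

    @pytest.mark.parametrize("k", [1e-4, 0.0162, 0.7, 5.0])
    def test_exact_identities(self, k):
        th, D = half_life_and_D(k)
        assert th * k == pytest.approx(np.log(2), rel=1e-15)
        assert D * k == pytest.approx(np.log(10), rel=1e-15)
        assert D / th == pytest.approx(np.log(10) / np.log(2), rel=1e-15)

    def test_no_decay_rejected(self):
        with pytest.raises(DegenerateDataError, match="no decay"):
            half_life_and_D(0.0)


class TestInactivationEnergy:
    def test_exact_recovery(self):
        T = np.array([313.15, 333.15, 343.15, 353.15, 363.15])
        k = 1e7 * np.exp(-60e3 / (R * T))
        res = inactivation_activation_energy(T, k)
        assert res.Ea == pytest.approx(60.0, rel=1e-9)

    def test_reference_panel_slope(self):
        # OLS on the reference k_in panel (40-90 °C) gives ≈ 68 kJ/mol
        from enzkit.celc307 import inactivation_rates

        T, k = inactivation_rates()
        res = inactivation_activation_energy(T, k)
        assert res.Ea == pytest.approx(67.95, abs=0.05)

    def test_single_temperature_rejected(self):
        with pytest.raises(InsufficientDataError):
            inactivation_activation_energy([313.15], [0.01])


class TestStateFunctions:
    def test_reference_enthalpy(self):
        sf = inactivation_state_functions(1.62e-2, 59.29, T40, "per_minute")
        assert sf.dH == pytest.approx(56.69, abs=0.01)

    def test_reference_gibbs_minute_mode(self):
        sf = inactivation_state_functions(1.62e-2, 59.29, T40, "per_minute")
        assert sf.dG == pytest.approx(87.555, abs=0.01)

    def test_second_mode_shifts_by_rt_ln60(self):
        per_min = inactivation_state_functions(1.62e-2, 59.29, T40, "per_minute")
        per_sec = inactivation_state_functions(1.62e-2, 59.29, T40, "per_second")
        assert per_sec.dG - per_min.dG == pytest.approx(R * T40 * np.log(60) / 1000.0, rel=1e-12)

    def test_identity_point(self):
        from enzkit.constants import H, KB

        sf = inactivation_state_functions(KB * T40 / H, 59.29, T40, "per_minute")
        assert sf.dG == pytest.approx(0.0, abs=1e-9)

    def test_gibbs_helmholtz_identity(self):
        sf = inactivation_state_functions(0.05, 60.0, 343.15, "per_second")
        assert sf.dH - 343.15 * sf.dS / 1000.0 == pytest.approx(sf.dG, rel=1e-14)


class TestPanel:
    def test_noiseless_panel_recovers_parameters(self):
        panel = simulate_inactivation_panel(Ea=60.0, A=1e7)
        res = ThermalInactivation(panel).fit()
        assert res.arrhenius.Ea == pytest.approx(60.0, rel=1e-9)
        assert res.arrhenius.A == pytest.approx(1e7, rel=1e-8)
        # exact identities on every record
        for r in res.rates:
            assert r.t_half * r.k_in == pytest.approx(np.log(2), rel=1e-12)
            assert r.D_value * r.k_in == pytest.approx(np.log(10), rel=1e-12)
        for sf in res.state_functions:
            assert sf.dH == pytest.approx(60.0 - R * sf.temperature_k / 1000.0, rel=1e-12)
            assert sf.dH - sf.temperature_k * sf.dS / 1000.0 == pytest.approx(sf.dG, rel=1e-12)

    def test_monotone_rates_and_half_lives(self):
        panel = simulate_inactivation_panel(Ea=60.0, A=1e7)
        res = ThermalInactivation(panel).fit()
        ks = [r.k_in for r in res.rates]
        ths = [r.t_half for r in res.rates]
        assert np.all(np.diff(ks) > 0)
        assert np.all(np.diff(ths) < 0)

    def test_dg_increases_with_temperature(self):
        # Arrhenius-law inactivation with Ea above RT: ΔG# rises with T
        panel = simulate_inactivation_panel(Ea=60.0, A=1e7)
        res = ThermalInactivation(panel).fit()
        dgs = [sf.dG for sf in res.state_functions]
        assert np.all(np.diff(dgs) > 0)

    def test_unusable_temperature_gives_partial_result(self):
        panel = simulate_inactivation_panel(Ea=60.0, A=1e7)
        bad = InactivationTimecourse(400.0, [0.0, 10.0, 20.0], [1.0, -1.0, -1.0])
        with pytest.warns(UserWarning):
            res = ThermalInactivation(panel + [bad]).fit()
        assert len(res.rates) == len(panel)
        assert any("skipped" in w for w in res.warnings_)
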