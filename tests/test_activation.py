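"""Arrhenius regression and transition-state thermodynamics of catalysis."""

import numpy as np
import pytest

from enzkit.activation import (
    ActivationAnalysis,
    activation_state_functions,
    ascending_limb,
    eyring_free_energy,
    substrate_binding_energies,
)
from enzkit.arrhenius import ArrheniusModel, arrhenius_activation_energy
from enzkit.constants import H, KB, R
from enzkit.exceptions import DegenerateDataError, InsufficientDataError

T40 = 313.15


class TestArrhenius:
    def test_exact_roundtrip(self):
        T = np.array([300.0, 305.0, 310.0, 315.0, 320.0])
        k = 1e8 * np.exp(-50e3 / (R * T))
        res = arrhenius_activation_energy(T, k)
        assert res.Ea == pytest.approx(50.0, rel=1e-9)
        assert res.A == pytest.approx(1e8, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_match_closed_form(self):
        T1, T2, k1, k2 = 300.0, 320.0, 0.01, 0.05
        res = arrhenius_activation_energy([T1, T2], [k1, k2])
        ea_closed = R * np.log(k2 / k1) / (1 / T1 - 1 / T2) / 1000.0
        assert res.Ea == pytest.approx(ea_closed, rel=1e-12)

    def test_zero_rate_rejected(self):
        with pytest.raises(DegenerateDataError, match="log undefined"):
            arrhenius_activation_energy([300.0, 310.0, 320.0], [0.0, 0.1, 0.2])

    def test_single_temperature_rejected(self):
        with pytest.raises(InsufficientDataError):
            ArrheniusModel([300.0], [0.1])


class TestEyring:
    def test_identity_point(self):
        kcat = KB * T40 / H
        k_red, dG = eyring_free_energy(kcat, T40)
        assert k_red == pytest.approx(1.0, rel=1e-12)
        assert dG == pytest.approx(0.0, abs=1e-12)

    def test_reference_kcat_value(self):
        # −RT·ln(kcat·h/(kB·T)) for kcat = 0.10430 s⁻¹ at 40 °C
        _, dG = eyring_free_energy(0.10430, T40)
        assert dG == pytest.approx(82.707, abs=0.01)

    def test_halving_kcat_raises_dg_by_rt_ln2(self):
        _, dg1 = eyring_free_energy(0.2, T40)
        _, dg2 = eyring_free_energy(0.1, T40)
        assert dg2 - dg1 == pytest.approx(R * T40 * np.log(2) / 1000.0, rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DegenerateDataError, match="invalid rate"):
            eyring_free_energy(0.0, T40)


class TestStateFunctions:
    def test_enthalpy_from_reference_ea(self):
        dH, _ = activation_state_functions(25.36, 58.60, T40)
        assert dH == pytest.approx(22.76, abs=0.01)

    def test_entropy_from_reference_values(self):
        _, dS = activation_state_functions(22.75 + R * T40 / 1000.0, 58.60, T40)
        assert dS == pytest.approx(-114.48, abs=0.05)
        assert abs(dS) == pytest.approx(114.51, rel=0.002)

    def test_ea_equal_rt_gives_zero_enthalpy(self):
        dH, _ = activation_state_functions(R * T40 / 1000.0, 10.0, T40)
        assert dH == pytest.approx(0.0, abs=1e-12)

    def test_gibbs_helmholtz_identity_exact(self):
        dH, dS = activation_state_functions(30.0, 55.0, T40)
        assert dH - T40 * dS / 1000.0 == pytest.approx(55.0, rel=1e-14)


class TestBindingEnergies:
    def test_transition_state_energy_from_efficiency(self):
        _, dG_ET, _ = substrate_binding_energies(0.46, 226.73, T40, km_unit_mode="mM")
        assert dG_ET == pytest.approx(-14.12, abs=0.02)

    def test_binding_energy_mm_mode(self):
        dG_ES, _, Ka = substrate_binding_energies(0.46, 226.73, T40, km_unit_mode="mM")
        assert Ka == pytest.approx(2.1739, rel=1e-4)
        assert abs(dG_ES) == pytest.approx(2.02, abs=0.01)

    def test_unit_association_constant_gives_zero(self):
        dG_ES, _, Ka = substrate_binding_energies(1.0, 100.0, T40, km_unit_mode="mM")
        assert Ka == 1.0
        assert dG_ES == pytest.approx(0.0, abs=1e-12)

    def test_et_energy_invariant_under_ratio_preserving_rescale(self):
        _, a, _ = substrate_binding_energies(0.5, 200.0, T40)
        _, b, _ = substrate_binding_energies(5.0, 200.0, T40)  # kcat scaled with Km
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DegenerateDataError, match="log undefined"):
            substrate_binding_energies(-1.0, 10.0, T40)


class TestActivationAnalysis:
    def test_end_to_end_with_profile(self):
        # synthetic activity profile: Arrhenius rise to an optimum, then decline
        T = np.array([293.15, 298.15, 303.15, 308.15, 313.15, 318.15, 323.15])
        rates = 1e6 * np.exp(-40e3 / (R * T))
        act = rates.copy()
        act[T > 313.15] = act[T == 313.15] * 0.5  # inactivation-dominated tail
        res = ActivationAnalysis(
            kcat=0.1, temperature_k=313.15, temperatures_k=T, activities=act,
            Km=0.46, kcat_over_Km=226.73, km_unit_mode="mM",
        ).fit()
        assert res.Ea_act == pytest.approx(40.0, rel=1e-6)  # ascending limb only
        assert res.dH_act == pytest.approx(40.0 - R * 313.15 / 1000.0, rel=1e-9)
        # Gibbs-Helmholtz identity holds exactly
        assert res.dH_act - 313.15 * res.dS_act / 1000.0 == pytest.approx(res.dG_act, rel=1e-12)

    def test_dg_override_feeds_entropy(self):
        res = ActivationAnalysis(kcat=0.10430, temperature_k=T40, Ea=25.36, dG_override=58.60).fit()
        assert abs(res.dS_act) == pytest.approx(114.5, abs=0.1)
        # the Eyring ΔG‡ itself is still reported from kcat
        assert res.dG_act == pytest.approx(82.707, abs=0.01)

    def test_ascending_limb_selection(self):
        T = np.array([1.0, 2.0, 3.0, 4.0])
        a = np.array([1.0, 3.0, 2.0, 1.0])
        Tl, al = ascending_limb(T, a)
        assert Tl.tolist() == [1.0, 2.0]
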