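"""Transition-state thermodynamics of catalysis.

From the Eyring relation k = (kB·T/h)·exp(−ΔG‡/RT) the reduced (transmission)
rate kcat‡ = kcat·h/(kB·T) gives the activation free energy
ΔG‡ = −RT·ln kcat‡.  The Arrhenius activation energy yields the enthalpy
ΔH‡ = Ea‡ − RT, and the entropy follows from ΔS‡ = (ΔH‡ − ΔG‡)/T.  Substrate
binding and transition-state formation energies derive from the Michaelis
constant (ΔG‡(E–S) = −RT·ln(1/Km)) and the catalytic efficiency
(ΔG‡(E–T) = −RT·ln(kcat/Km)).

Unit-mode switches reproduce reported tables that use non-standard unit
conventions: ``km_unit_mode="mM"`` evaluates 1/Km with Km in mM (the
thermodynamically standard choice is molar), and ``rate_unit_mode`` declares
whether a rate constant enters the Eyring expression in s⁻¹ or min⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arrhenius import ArrheniusModel, ArrheniusResults
from .constants import H, KB, R
from .exceptions import DegenerateDataError, EnzkitError

_RATE_TO_PER_SECOND = {"per_second": 1.0, "per_minute": 1.0 / 60.0}


@dataclass(frozen=True)
class ActivationThermo:
    """Consolidated activation (catalysis) thermodynamics at one temperature."""

    temperature_k: float
    Ea_act: float  # kJ/mol, Arrhenius activation energy of catalysis
    arrhenius_slope: float  # K
    preexponential: float
    kcat_transmission: float  # kcat·h/(kB·T), unitless
    dG_act: float  # kJ/mol
    dH_act: float  # kJ/mol
    dS_act: float  # J mol^-1 K^-1, signed
    dS_act_magnitude: float  # |ΔS‡|, for tables that print the magnitude
    dG_ES: float | None = None  # kJ/mol, enzyme-substrate binding
    dG_ET: float | None = None  # kJ/mol, enzyme-transition-state
    Ka: float | None = None  # 1/Km

    def summary(self) -> str:
        rows = [
            ("T (K)", self.temperature_k),
            ("Ea‡ (kJ/mol)", self.Ea_act),
            ("ΔG‡ (kJ/mol)", self.dG_act),
            ("ΔH‡ (kJ/mol)", self.dH_act),
            ("ΔS‡ (J/mol/K)", self.dS_act),
            ("|ΔS‡| (J/mol/K)", self.dS_act_magnitude),
        ]
        if self.dG_ES is not None:
            rows.append(("ΔG‡ E-S (kJ/mol)", self.dG_ES))
        if self.dG_ET is not None:
            rows.append(("ΔG‡ E-T (kJ/mol)", self.dG_ET))
        if self.Ka is not None:
            rows.append(("Ka = 1/Km", self.Ka))
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val:10.4f}" for name, val in rows)


def eyring_free_energy(
    kcat: float, temperature_k: float, rate_unit_mode: str = "per_second"
) -> tuple[float, float]:
    """Reduced Eyring rate and activation free energy.

    Returns (kcat‡, ΔG‡ in kJ/mol).  ``rate_unit_mode`` declares the unit in
    which ``kcat`` enters the expression: "per_second" is standard;
    "per_minute" leaves a min⁻¹ rate unconverted (a convention some tables
    use, shifting ΔG by RT·ln 60).
    """
    if kcat <= 0:
        raise DegenerateDataError("invalid rate: kcat must be positive")
    if temperature_k <= 0:
        raise EnzkitError("temperature must be positive (Kelvin)")
    if rate_unit_mode not in _RATE_TO_PER_SECOND:
        raise ValueError(f"unknown rate_unit_mode {rate_unit_mode!r}")
    # In per_minute mode the numeric value is used as-is against kB·T/h (s⁻¹).
    k_reduced = kcat * H / (KB * temperature_k)
    dG = -R * temperature_k * np.log(k_reduced) / 1000.0
    return float(k_reduced), float(dG)


def activation_state_functions(Ea: float, dG: float, temperature_k: float) -> tuple[float, float]:
    """ΔH‡ = Ea − RT and ΔS‡ = (ΔH‡ − ΔG‡)/T.

    Returns (ΔH‡ kJ/mol, ΔS‡ J mol⁻¹ K⁻¹, signed).
    """
    if temperature_k <= 0:
        raise EnzkitError("temperature must be positive (Kelvin)")
    dH = Ea - R * temperature_k / 1000.0
    dS = (dH - dG) / temperature_k * 1000.0
    return float(dH), float(dS)


def substrate_binding_energies(
    Km: float,
    kcat_over_Km: float,
    temperature_k: float,
    km_unit_mode: str = "M",
) -> tuple[float, float, float]:
    """Free energies of substrate binding and transition-state formation.

    Returns (ΔG‡(E–S), ΔG‡(E–T), Ka) with energies in kJ/mol.  ``Km`` is given
    in mM; ``km_unit_mode`` selects whether 1/Km enters the logarithm on the
    molar scale ("M", standard) or on the mM scale ("mM", the convention that
    reproduces tables quoting Ka = 1/Km with Km in mM).
    """
    if Km <= 0 or kcat_over_Km <= 0:
        raise DegenerateDataError("log undefined: Km and kcat/Km must be positive")
    if km_unit_mode not in ("M", "mM"):
        raise ValueError(f"unknown km_unit_mode {km_unit_mode!r}")
    km_for_log = Km * 1e-3 if km_unit_mode == "M" else Km
    Ka = 1.0 / km_for_log
    RT = R * temperature_k / 1000.0
    dG_ES = -RT * np.log(Ka)
    dG_ET = -RT * np.log(kcat_over_Km)
    return float(dG_ES), float(dG_ET), float(Ka)


def ascending_limb(temperatures_k, activities) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a temperature–activity profile to temperatures ≤ the optimum.

    The Arrhenius law only describes the activation-limited (rising) part of
    the profile; beyond the optimum, inactivation dominates.
    """
    T = np.asarray(temperatures_k, dtype=float)
    a = np.asarray(activities, dtype=float)
    order = np.argsort(T)
    T, a = T[order], a[order]
    i_opt = int(np.argmax(a))
    return T[: i_opt + 1], a[: i_opt + 1]


class ActivationAnalysis:
    """End-to-end activation thermodynamics at a reference temperature.

    Combines an Arrhenius fit on the ascending limb of a temperature–activity
    profile (or accepts a pre-computed Ea‡) with the Eyring decomposition of
    kcat and the binding energies from Km and kcat/Km.

    ``dG_override`` accepts an externally supplied ΔG‡ (kJ/mol) to be used for
    the entropy step in place of the Eyring value — useful when reproducing a
    published table whose ΔG‡ does not derive from its own kcat.
    """

    def __init__(
        self,
        kcat: float,
        temperature_k: float,
        Ea: float | None = None,
        temperatures_k=None,
        activities=None,
        Km: float | None = None,
        kcat_over_Km: float | None = None,
        km_unit_mode: str = "M",
        rate_unit_mode: str = "per_second",
        dG_override: float | None = None,
    ):
        self.kcat = kcat
        self.T = temperature_k
        self.Ea = Ea
        self.profile = (temperatures_k, activities)
        self.Km = Km
        self.kcat_over_Km = kcat_over_Km
        self.km_unit_mode = km_unit_mode
        self.rate_unit_mode = rate_unit_mode
        self.dG_override = dG_override

    def fit(self) -> ActivationThermo:
        Ea = self.Ea
        arr: ArrheniusResults | None = None
        if Ea is None:
            T, a = self.profile
            if T is None or a is None:
                raise EnzkitError("supply either Ea or a temperature-activity profile")
            T_asc, a_asc = ascending_limb(T, a)
            arr = ArrheniusModel(T_asc, a_asc).fit()
            Ea = arr.Ea
        k_red, dG_eyring = eyring_free_energy(self.kcat, self.T, self.rate_unit_mode)
        dG_for_entropy = self.dG_override if self.dG_override is not None else dG_eyring
        dH, dS = activation_state_functions(Ea, dG_for_entropy, self.T)
        dG_ES = dG_ET = Ka = None
        if self.Km is not None and self.kcat_over_Km is not None:
            dG_ES, dG_ET, Ka = substrate_binding_energies(
                self.Km, self.kcat_over_Km, self.T, self.km_unit_mode
            )
        return ActivationThermo(
            temperature_k=self.T,
            Ea_act=Ea,
            arrhenius_slope=arr.slope if arr else -Ea * 1000.0 / R,
            preexponential=arr.A if arr else float("nan"),
            kcat_transmission=k_red,
            dG_act=dG_eyring,
            dH_act=dH,
            dS_act=dS,
            dS_act_magnitude=abs(dS),
            dG_ES=dG_ES,
            dG_ET=dG_ET,
            Ka=Ka,
        )
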