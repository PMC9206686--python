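"""Irreversible thermal inactivation kinetics and thermodynamics.

A first-order inactivation model ln([Act]t/[Act]0) = −k_in·t is fitted per
temperature by zero-intercept least squares (the model forces the log residual
activity to 0 at t = 0).  From k_in follow the half-life t½ = ln2/k_in and the
decimal reduction time D = ln10/k_in, from the panel of k_in(T) an Arrhenius
activation energy Ea#, and per temperature the Eyring state functions
ΔG# = −RT·ln(k_in·h/(kB·T)), ΔH# = Ea# − RT, ΔS# = (ΔH# − ΔG#)/T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .arrhenius import ArrheniusModel, ArrheniusResults
from .constants import H, KB, R
from .exceptions import DegenerateDataError, EnzkitError, InsufficientDataError


@dataclass
class InactivationTimecourse:
    """Residual activity fractions over incubation time at one temperature."""

    temperature_k: float
    times_min: np.ndarray  # includes 0, strictly increasing
    residual_fraction: np.ndarray  # Act_t / Act_0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.residual_fraction = np.asarray(self.residual_fraction, dtype=float)
        if self.times_min.shape != self.residual_fraction.shape:
            raise EnzkitError("times and fractions must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise EnzkitError("times must be strictly increasing")


@dataclass(frozen=True)
class InactivationRate:
    """Zero-intercept first-order decay fit at one temperature."""

    temperature_k: float
    k_in: float  # min^-1
    r_squared: float
    k_in_free_intercept: float  # diagnostic fit with a free intercept
    intercept_free: float  # ln-fraction intercept of the diagnostic fit
    n_used: int
    n_dropped: int

    @property
    def t_half(self) -> float:
        """Half-life, min (ln2/k_in)."""
        return float(np.log(2) / self.k_in)

    @property
    def D_value(self) -> float:
        """Decimal reduction time, min (ln10/k_in)."""
        return float(np.log(10) / self.k_in)


@dataclass(frozen=True)
class InactivationStateFunctions:
    temperature_k: float
    dG: float  # kJ/mol
    dH: float  # kJ/mol
    dS: float  # J mol^-1 K^-1, signed
    dS_magnitude: float


@dataclass
class InactivationResults:
    """Consolidated irreversible-inactivation record across a temperature panel."""

    rates: list[InactivationRate]
    arrhenius: ArrheniusResults | None
    state_functions: list[InactivationStateFunctions]
    rate_unit_mode: str
    warnings_: list[str] = field(default_factory=list)

    @property
    def Ea(self) -> float | None:
        return self.arrhenius.Ea if self.arrhenius else None

    def summary(self) -> str:
        hdr = (
            f"{'T (K)':>8} {'k_in (1/min)':>13} {'t1/2 (min)':>11} {'D (min)':>10} "
            f"{'dG# (kJ/mol)':>13} {'dH# (kJ/mol)':>13} {'dS# (J/mol/K)':>14}"
        )
        lines = ["Irreversible thermal inactivation", "-" * len(hdr), hdr]
        sf = {s.temperature_k: s for s in self.state_functions}
        for r in self.rates:
            s = sf.get(r.temperature_k)
            lines.append(
                f"{r.temperature_k:8.2f} {r.k_in:13.4g} {r.t_half:11.2f} {r.D_value:10.1f} "
                + (f"{s.dG:13.2f} {s.dH:13.2f} {s.dS:14.2f}" if s else " " * 42)
            )
        if self.arrhenius:
            lines.append(f"Ea# = {self.arrhenius.Ea:.4g} kJ/mol (r² = {self.arrhenius.r_squared:.4f})")
        for w in self.warnings_:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def fit_inactivation_rate(tc: InactivationTimecourse) -> InactivationRate:
    """First-order inactivation constant by zero-intercept OLS of ln(fraction) on t.

    Non-positive fractions are dropped with a warning.  A negative k_in
    (activity rising with time) is flagged as activation rather than
    inactivation.  A free-intercept diagnostic fit is reported alongside.
    """
    t = tc.times_min
    f = tc.residual_fraction
    keep = f > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} non-positive fraction(s) dropped from log fit", stacklevel=2)
    t, f = t[keep], f[keep]
    # t = 0 contributes nothing to a zero-intercept fit; require 3 informative points
    informative = t > 0
    if informative.sum() < 2 or t.size < 3:
        raise InsufficientDataError("no decay data: need at least 3 positive-fraction time points")
    y = np.log(f)
    # zero-intercept OLS: k = −Σ t·y / Σ t²
    k_in = float(-(t @ y) / (t @ t))
    yhat = -k_in * t
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    slope_f, icept_f = np.polyfit(t, y, 1)
    if k_in < 0:
        warnings.warn("activation, not inactivation: activity rises with time (k_in < 0)", stacklevel=2)
    return InactivationRate(
        temperature_k=tc.temperature_k,
        k_in=k_in,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        k_in_free_intercept=float(-slope_f),
        intercept_free=float(icept_f),
        n_used=int(t.size),
        n_dropped=n_dropped,
    )


def half_life_and_D(k_in: float) -> tuple[float, float]:
    """Half-life t½ = ln2/k_in and decimal reduction time D = ln10/k_in (min)."""
    if k_in <= 0:
        raise DegenerateDataError("no decay: k_in must be positive")
    return float(np.log(2) / k_in), float(np.log(10) / k_in)


def inactivation_activation_energy(temperatures_k, k_ins) -> ArrheniusResults:
    """Arrhenius activation energy of inactivation from per-temperature k_in."""
    return ArrheniusModel(temperatures_k, k_ins).fit()


def inactivation_state_functions(
    k_in: float,
    Ea: float,
    temperature_k: float,
    rate_unit_mode: str = "per_second",
) -> InactivationStateFunctions:
    """Eyring state functions of inactivation at one temperature.

    ``k_in`` is in min⁻¹.  In "per_second" mode (standard) it is converted to
    s⁻¹ before entering the Eyring expression; "per_minute" uses the min⁻¹
    number directly against kB·T/h, the convention of some published tables
    (it shifts ΔG# by RT·ln 60).
    """
    if k_in <= 0:
        raise DegenerateDataError("invalid rate: k_in must be positive")
    if temperature_k <= 0:
        raise EnzkitError("temperature must be positive (Kelvin)")
    if rate_unit_mode == "per_second":
        k = k_in / 60.0
    elif rate_unit_mode == "per_minute":
        k = k_in
    else:
        raise ValueError(f"unknown rate_unit_mode {rate_unit_mode!r}")
    dG = -R * temperature_k * np.log(k * H / (KB * temperature_k)) / 1000.0
    dH = Ea - R * temperature_k / 1000.0
    dS = (dH - dG) / temperature_k * 1000.0
    return InactivationStateFunctions(
        temperature_k=temperature_k,
        dG=float(dG),
        dH=float(dH),
        dS=float(dS),
        dS_magnitude=abs(float(dS)),
    )


class ThermalInactivation:
    """Model object for a panel of inactivation timecourses across temperatures.

    ``fit()`` runs the full chain: per-temperature k_in → t½ and D →
    Arrhenius Ea# → per-temperature ΔG#, ΔH#, ΔS#.  A temperature whose
    timecourse cannot be fitted is skipped with a recorded warning rather than
    aborting the panel.
    """

    def __init__(self, panel: list[InactivationTimecourse], rate_unit_mode: str = "per_second"):
        if len(panel) < 1:
            raise InsufficientDataError("empty inactivation panel")
        self.panel = panel
        self.rate_unit_mode = rate_unit_mode

    def fit(self) -> InactivationResults:
        rates: list[InactivationRate] = []
        warns: list[str] = []
        for tc in self.panel:
            try:
                rates.append(fit_inactivation_rate(tc))
            except EnzkitError as exc:
                warns.append(f"T={tc.temperature_k:.2f} K skipped: {exc}")
        usable = [r for r in rates if r.k_in > 0]
        arr = None
        if len(usable) >= 3:
            arr = inactivation_activation_energy(
                [r.temperature_k for r in usable], [r.k_in for r in usable]
            )
        elif len(usable) >= 1:
            warns.append("fewer than 3 usable temperatures: Ea# not fitted")
        sfs: list[InactivationStateFunctions] = []
        if arr is not None:
            for r in usable:
                sfs.append(
                    inactivation_state_functions(
                        r.k_in, arr.Ea, r.temperature_k, self.rate_unit_mode
                    )
                )
        return InactivationResults(
            rates=rates,
            arrhenius=arr,
            state_functions=sfs,
            rate_unit_mode=self.rate_unit_mode,
            warnings_=warns,
        )


def inactivation_profile(
    panel: list[InactivationTimecourse], rate_unit_mode: str = "per_second"
) -> InactivationResults:
    """Functional façade over :class:`ThermalInactivation`."""
    return ThermalInactivation(panel, rate_unit_mode=rate_unit_mode).fit()
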