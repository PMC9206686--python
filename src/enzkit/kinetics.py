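"""Michaelis–Menten kinetics: nonlinear fitting and catalytic constants.

The model is v = Vmax·S / (Km + S).  ``MichaelisMenten`` is a small
statsmodels-style model object: construct it from a :class:`KineticDataset`
(or arrays) and call :meth:`MichaelisMenten.fit` to obtain a
:class:`MMKineticsResults` with the estimates, their standard errors and the
derived catalytic constants.  The double-reciprocal (Lineweaver–Burk)
linearization is provided for diagnostic plots and inhibition-mode geometry,
not as the primary estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, InsufficientDataError
from .constants import R  # noqa: F401  (re-exported for convenience)

_MM_MAXITER = 500
_MM_XTOL = 1e-8


def michaelis_menten(S, Km, Vmax):
    """Michaelis–Menten rate law."""
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


@dataclass
class KineticDataset:
    """Substrate concentrations and measured initial velocities.

    Units are carried as tags and never converted implicitly: substrate may be
    mM or mg/ml, velocity U/mg or U/ml.
    """

    substrate_conc: np.ndarray
    velocity: np.ndarray
    substrate_unit: str = "mM"
    velocity_unit: str = "U/mg"
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.substrate_conc.shape != self.velocity.shape:
            raise InsufficientDataError("substrate and velocity must have equal length")
        if np.any(self.substrate_conc <= 0):
            raise FitError("all substrate concentrations must be positive")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.substrate_conc).size)


@dataclass
class MMKineticsResults:
    """Michaelis–Menten fit results and derived catalytic constants.

    Km keeps the unit of the input substrate axis; conversion to molar happens
    only when computing kcat/Km (and requires an mM-tagged Km).  Ka and Ki are
    both defined as 1/Km in the reciprocal substrate unit — the association
    constant of the ES complex under the rapid-equilibrium reading of Km.
    """

    Km: float
    Vmax: float
    Km_se: float
    Vmax_se: float
    rss: float
    substrate_unit: str = "mM"
    velocity_unit: str = "U/mg"
    kcat: float | None = None  # s^-1, supplied or derived
    kcat_over_Km: float | None = None  # M^-1 s^-1
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.Vmax <= 0:
            raise FitError("invalid kinetics: Km and Vmax must be positive")

    @property
    def Ka(self) -> float:
        """Association constant 1/Km (reciprocal substrate unit)."""
        return 1.0 / self.Km

    # The source analysis defines Ki ≡ 1/Km for the binding free-energy step.
    Ki = Ka

    def predict(self, S):
        return michaelis_menten(S, self.Km, self.Vmax)

    def lineweaver_burk_line(self) -> "LBLine":
        """The double-reciprocal line implied by the fitted parameters."""
        return LBLine(slope=self.Km / self.Vmax, intercept=1.0 / self.Vmax)

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit",
            "--------------------",
            f"Km    = {self.Km:.4g} {self.substrate_unit}  (SE {self.Km_se:.2g})",
            f"Vmax  = {self.Vmax:.4g} {self.velocity_unit}  (SE {self.Vmax_se:.2g})",
            f"Ka=1/Km = {self.Ka:.4g} 1/{self.substrate_unit}",
            f"RSS   = {self.rss:.4g}   n = {self.n_obs}",
        ]
        if self.kcat is not None:
            lines.append(f"kcat  = {self.kcat:.4g} 1/s")
        if self.kcat_over_Km is not None:
            lines.append(f"kcat/Km = {self.kcat_over_Km:.4g} 1/(M s)")
        return "\n".join(lines)


@dataclass(frozen=True)
class LBLine:
    """A line in double-reciprocal space: 1/v = slope·(1/S) + intercept."""

    slope: float  # Km/Vmax
    intercept: float  # 1/Vmax

    @property
    def Km(self) -> float:
        return self.slope / self.intercept

    @property
    def Vmax(self) -> float:
        return 1.0 / self.intercept


class MichaelisMenten:
    """Nonlinear least-squares Michaelis–Menten model.

    Parameters
    ----------
    data : KineticDataset
        Positive substrate concentrations with ≥4 distinct levels and
        non-negative velocities.
    weighting : {"uniform", "relative"}
        "uniform" minimizes Σ(v−v̂)²; "relative" weights residuals by 1/v̂
        (useful when error scales with signal).  Default "uniform".
    """

    def __init__(self, data: KineticDataset, weighting: str = "uniform"):
        if data.n_distinct < 4:
            raise InsufficientDataError("need at least 4 distinct substrate concentrations")
        if np.any(data.velocity < 0):
            raise FitError("velocities must be non-negative")
        if weighting not in ("uniform", "relative"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.data = data
        self.weighting = weighting

    @classmethod
    def from_arrays(cls, substrate, velocity, **kwargs):
        ds_kw = {k: kwargs.pop(k) for k in ("substrate_unit", "velocity_unit") if k in kwargs}
        return cls(KineticDataset(substrate, velocity, **ds_kw), **kwargs)

    def _initial_guess(self) -> tuple[float, float]:
        S, v = self.data.substrate_conc, self.data.velocity
        vmax0 = float(v.max())
        # Km0: substrate at half-maximal velocity, linearly interpolated
        order = np.argsort(S)
        Ss, vs = S[order], v[order]
        half = vmax0 / 2.0
        km0 = float(np.interp(half, vs, Ss)) if np.any(vs >= half) else float(np.median(Ss))
        if km0 <= 0:
            km0 = float(np.median(Ss))
        return km0, vmax0

    def fit(self) -> MMKineticsResults:
        S, v = self.data.substrate_conc, self.data.velocity
        p0 = self._initial_guess()
        sigma = None
        if self.weighting == "relative":
            sigma = np.maximum(v, 1e-12 * max(v.max(), 1.0))
        try:
            popt, pcov = curve_fit(
                michaelis_menten,
                S,
                v,
                p0=p0,
                sigma=sigma,
                maxfev=_MM_MAXITER * 10,
                xtol=_MM_XTOL,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            )
        except RuntimeError as exc:  # pragma: no cover - scipy message path
            raise FitError(f"fit failed: {exc}") from exc
        Km, Vmax = float(popt[0]), float(popt[1])
        if not np.isfinite(Km) or not np.isfinite(Vmax) or Km <= 0 or Vmax <= 0:
            raise FitError("invalid kinetics: non-positive parameter at optimum")
        # Degenerate plateau: Km collapses toward zero when v is flat in S.
        # A Km four orders below the smallest tested substrate is unidentifiable.
        if Km < 1e-4 * float(np.min(S)):
            raise FitError("invalid kinetics: Km at zero boundary (velocity flat in substrate)")
        resid = v - michaelis_menten(S, Km, Vmax)
        se = np.sqrt(np.diag(pcov))
        return MMKineticsResults(
            Km=Km,
            Vmax=Vmax,
            Km_se=float(se[0]),
            Vmax_se=float(se[1]),
            rss=float(resid @ resid),
            substrate_unit=self.data.substrate_unit,
            velocity_unit=self.data.velocity_unit,
            n_obs=int(S.size),
        )


def fit_michaelis_menten(data: KineticDataset, weighting: str = "uniform") -> MMKineticsResults:
    """Functional façade over :class:`MichaelisMenten`."""
    return MichaelisMenten(data, weighting=weighting).fit()


_MM_TO_M = {"mM": 1e-3, "M": 1.0, "uM": 1e-6, "µM": 1e-6}


def catalytic_constants(
    fit: MMKineticsResults,
    kcat: float | None = None,
    enzyme_mw_kda: float | None = None,
) -> MMKineticsResults:
    """Attach kcat and the catalytic efficiency kcat/Km to a fit.

    kcat (s⁻¹) is normally supplied directly.  Alternatively it is derived
    from the specific-activity Vmax (U/mg = µmol·min⁻¹·mg⁻¹) and the enzyme
    molecular weight: kcat = Vmax·MW(kDa)/60·10⁻³ s⁻¹.  kcat/Km needs Km in a
    molar-convertible unit; otherwise it is omitted with a warning.
    """
    if kcat is None:
        if enzyme_mw_kda is None:
            raise EnzkitErrorMissing()
        # U/mg = µmol·min⁻¹·mg⁻¹ and 1 kDa = 1 mg/µmol, so
        # Vmax(U/mg) × MW(kDa) = turnovers·min⁻¹; divide by 60 for s⁻¹.
        kcat = fit.Vmax * enzyme_mw_kda / 60.0
    if kcat < 0:
        raise FitError("invalid rate: kcat must be non-negative")
    factor = _MM_TO_M.get(fit.substrate_unit)
    eff = None
    if factor is None:
        warnings.warn(
            f"Km unit {fit.substrate_unit!r} is not molar-convertible; kcat/Km omitted",
            stacklevel=2,
        )
    else:
        km_molar = fit.Km * factor
        eff = kcat / km_molar if kcat > 0 else 0.0
    return replace(fit, kcat=kcat, kcat_over_Km=eff)


class EnzkitErrorMissing(FitError):
    def __init__(self):
        super().__init__("either kcat or the enzyme molecular weight must be supplied")


def lineweaver_burk_transform(data: KineticDataset) -> tuple[LBLine, np.ndarray, np.ndarray]:
    """OLS line through the double-reciprocal transform of the data.

    Zero velocities are excluded with a warning (their reciprocal is
    undefined).  Returns the fitted line plus the transformed points; the
    back-derived Km and Vmax live on the line object.
    """
    S, v = data.substrate_conc, data.velocity
    keep = v > 0
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} zero-velocity point(s) excluded from reciprocal plot", stacklevel=2)
    S, v = S[keep], v[keep]
    if S.size < 2:
        raise InsufficientDataError("need at least 2 positive-velocity points")
    x, y = 1.0 / S, 1.0 / v
    slope, intercept = np.polyfit(x, y, 1)
    return LBLine(slope=float(slope), intercept=float(intercept)), x, y
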