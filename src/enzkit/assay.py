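"""Reducing-sugar assay calibration and enzyme activity units.

A DNS (dinitrosalicylic acid) assay reports hydrolytic activity as absorbance.
A linear standard curve converts absorbance to µmol of reducing sugar, and one
enzyme unit (U) is the amount of enzyme that liberates 1 µmol of reducing
sugar per minute.  Specific activity divides units by enzyme mass (U/mg);
volumetric activity divides by reaction volume (U/ml).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, EnzkitError, InsufficientDataError


@dataclass(frozen=True)
class LinearCalibration:
    """Ordinary least-squares standard curve: absorbance = slope·µmol + intercept."""

    slope: float  # absorbance per µmol reducing sugar
    intercept: float  # absorbance
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DegenerateDataError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise EnzkitError("r_squared must lie in [0, 1]")

    def to_umol(self, absorbance: float) -> float:
        """Invert the standard curve; absorbance below the intercept maps to 0 µmol."""
        umol = (absorbance - self.intercept) / self.slope
        return max(umol, 0.0)


@dataclass(frozen=True)
class ActivityMeasurement:
    """One activity determination expressed in enzyme units."""

    product_formed: float  # µmol reducing sugar
    reaction_time: float  # min
    units_U: float  # µmol/min
    enzyme_mass: float | None = None  # mg
    reaction_volume: float | None = None  # ml
    specific_activity: float | None = None  # U/mg
    volumetric_activity: float | None = None  # U/ml
    clamped: bool = False  # absorbance fell below the calibration intercept


@dataclass
class ActivityProfile:
    """Activity as a function of one assay condition (temperature, pH, ...).

    ``profile_kind`` distinguishes an activity optimum curve from survival
    (pre-incubation then assay at the optimum) and stability (residual
    activity over time) profiles; the normalization is identical.
    """

    conditions: np.ndarray  # °C, pH units, ... strictly increasing
    activities: np.ndarray  # U/mg, U/ml or % of maximum
    profile_kind: str = "activity"  # activity | survival | stability
    stdev: np.ndarray | None = None  # replicate SD carried as metadata
    unit: str = "U/mg"

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.conditions.shape != self.activities.shape:
            raise EnzkitError("conditions and activities must have equal length")
        if np.any(np.diff(self.conditions) <= 0):
            raise EnzkitError("condition values must be strictly increasing")


def average_replicates(
    conditions: np.ndarray, activities: np.ndarray, **profile_kwargs
) -> ActivityProfile:
    """Average replicate activity readings per condition; SD kept as metadata.

    ``conditions`` may contain repeats (one row per replicate).
    """
    conditions = np.asarray(conditions, dtype=float)
    activities = np.asarray(activities, dtype=float)
    levels = np.unique(conditions)
    means = np.array([activities[conditions == c].mean() for c in levels])
    sds = np.array([activities[conditions == c].std(ddof=1) if (conditions == c).sum() > 1 else 0.0 for c in levels])
    return ActivityProfile(levels, means, stdev=sds, **profile_kwargs)


def fit_linear_calibration(concentrations, absorbances) -> LinearCalibration:
    """Fit the standard curve by ordinary least squares.

    Parameters
    ----------
    concentrations : array-like
        Reducing-sugar amounts (µmol) of the standards.
    absorbances : array-like
        Measured absorbances.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("insufficient calibration: need at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("degenerate calibration: zero variance in concentration")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
    return LinearCalibration(slope=float(slope), intercept=float(intercept), r_squared=max(min(r2, 1.0), 0.0))


def activity_units(
    absorbance: float,
    calibration: LinearCalibration,
    time: float,
    enzyme_mass: float | None = None,
    volume: float | None = None,
) -> ActivityMeasurement:
    """Convert one absorbance reading into enzyme units.

    U = µmol reducing sugar / min.  Specific activity (U/mg) requires
    ``enzyme_mass``; volumetric activity (U/ml) requires ``volume``.
    Absorbance below the calibration intercept clamps the product to zero
    (with a warning) rather than reporting negative units.
    """
    if time <= 0:
        raise EnzkitError("invalid duration: reaction time must be positive")
    clamped = absorbance < calibration.intercept
    if clamped:
        warnings.warn("absorbance below calibration intercept; product clamped to 0", stacklevel=2)
    product = calibration.to_umol(absorbance)
    units = product / time
    return ActivityMeasurement(
        product_formed=product,
        reaction_time=time,
        units_U=units,
        enzyme_mass=enzyme_mass,
        reaction_volume=volume,
        specific_activity=units / enzyme_mass if enzyme_mass else None,
        volumetric_activity=units / volume if volume else None,
        clamped=clamped,
    )


def relative_activity_profile(profile: ActivityProfile) -> ActivityProfile:
    """Normalize a profile so its maximum activity is 100%.

    Ties break to the first occurrence of the maximum; order is preserved.
    """
    acts = profile.activities
    if np.all(acts <= 0):
        raise DegenerateDataError("no activity to normalize")
    peak = float(acts.max())
    rel = acts / peak * 100.0
    sd = None if profile.stdev is None else profile.stdev / peak * 100.0
    return ActivityProfile(
        conditions=profile.conditions.copy(),
        activities=rel,
        profile_kind=profile.profile_kind,
        stdev=sd,
        unit="%",
    )
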