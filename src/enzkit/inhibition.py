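"""Inhibition-mode classification from Michaelis–Menten parameter shifts.

For each inhibitor concentration (including the uninhibited control) the
Michaelis–Menten model is fitted independently; the mechanism is then read off
the pattern of apparent-Km and apparent-Vmax shifts relative to the control:

==================  ==========================  =========================
mechanism           apparent Km                 apparent Vmax
==================  ==========================  =========================
competitive         increases                   unchanged
non-competitive     unchanged                   decreases
uncompetitive       decreases proportionally    decreases proportionally
mixed               both shift, non-proportionally
==================  ==========================  =========================

"Unchanged" is judged against a relative tolerance (default 10%) combined
with a significance gate: a shift also has to exceed ``z_crit`` times its
delta-method standard error before it counts as a real change, so a noisy Km
estimate is not mistaken for a mechanistic shift.  Proportional shifts leave
the Lineweaver–Burk slope Km/Vmax constant (parallel reciprocal lines), which
is the uncompetitive signature; parallelism is tested at
max(parallel_tol, z_crit·SE).  The Lineweaver–Burk line geometry (pairwise
intersection points: on the y-axis for competitive, on the x-axis for
non-competitive, parallel for uncompetitive) is reported as corroborating
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EnzkitError, FitError, InsufficientDataError
from .kinetics import KineticDataset, LBLine, MichaelisMenten, MMKineticsResults

MODES = ("competitive", "non-competitive", "uncompetitive", "mixed", "none", "indeterminate")


@dataclass
class InhibitionSeries:
    """One inhibitor: velocity datasets at several inhibitor concentrations.

    ``concentrations_mM`` must include 0 (the uninhibited control).
    """

    inhibitor: str
    concentrations_mM: list[float]
    datasets: list[KineticDataset]

    def __post_init__(self) -> None:
        if len(self.concentrations_mM) != len(self.datasets):
            raise EnzkitError("one dataset per inhibitor concentration required")
        if 0.0 not in self.concentrations_mM:
            raise EnzkitError("control (0 mM inhibitor) dataset required")
        if len([c for c in self.concentrations_mM if c > 0]) < 1:
            raise InsufficientDataError("no inhibitor data: need at least one nonzero level")

    def sorted(self) -> "InhibitionSeries":
        order = np.argsort(self.concentrations_mM)
        return InhibitionSeries(
            self.inhibitor,
            [self.concentrations_mM[i] for i in order],
            [self.datasets[i] for i in order],
        )


@dataclass(frozen=True)
class Intersection:
    """Pairwise Lineweaver–Burk line crossing, classified by location."""

    i: int
    j: int
    x: float | None  # None when parallel
    y: float | None
    location: str  # "y-axis" | "x-axis" | "general" | "parallel"


@dataclass
class InhibitionVerdict:
    """Mechanism call plus the per-concentration fits and LB geometry behind it."""

    inhibitor: str
    mode: str
    concentrations_mM: list[float]
    fits: list[MMKineticsResults]
    lb_lines: list[LBLine]
    intersections: list[Intersection]
    rel_tol: float
    km_shifts: list[float] = field(default_factory=list)
    vmax_shifts: list[float] = field(default_factory=list)
    diagnostics: str = ""

    def summary(self) -> str:
        lines = [
            f"Inhibitor: {self.inhibitor}",
            f"Mode: {self.mode}",
            f"{'[I] (mM)':>9} {'Km':>9} {'Vmax':>9} {'LB slope':>9}",
        ]
        for c, f in zip(self.concentrations_mM, self.fits):
            lines.append(f"{c:9.3g} {f.Km:9.4g} {f.Vmax:9.4g} {f.Km / f.Vmax:9.4g}")
        if self.diagnostics:
            lines.append(f"note: {self.diagnostics}")
        return "\n".join(lines)


def fit_inhibition_series(series: InhibitionSeries) -> list[MMKineticsResults]:
    """Independent Michaelis–Menten fit at each inhibitor level, ordered by [I].

    A failing sub-fit raises :class:`FitError` naming the level; the caller
    (:func:`classify_inhibition_mode` via :class:`InhibitionExperiment`)
    converts that into an "indeterminate" verdict.
    """
    s = series.sorted()
    fits = []
    for conc, ds in zip(s.concentrations_mM, s.datasets):
        try:
            fits.append(MichaelisMenten(ds).fit())
        except EnzkitError as exc:
            raise FitError(f"fit failed at [I] = {conc} mM: {exc}") from exc
    return fits


def lb_lines_and_intersections(
    fits: list[MMKineticsResults], tol: float = 1e-9
) -> tuple[list[LBLine], list[Intersection]]:
    """Closed-form pairwise intersections of the reciprocal-space lines.

    Lines y = (Km/Vmax)·x + 1/Vmax.  An intersection is "on the y-axis" when
    |x*| is small relative to the x-range spanned by the axis crossings, "on
    the x-axis" when |y*| is small likewise, and "parallel" when the slopes
    agree to relative tolerance.
    """
    if len(fits) < 2:
        raise InsufficientDataError("need at least 2 fits for intersections")
    lines = [f.lineweaver_burk_line() for f in fits]
    x_scale = max(abs(-1.0 / f.Km) for f in fits)
    y_scale = max(abs(1.0 / f.Vmax) for f in fits)
    out = []
    rel_tol = max(tol, 1e-9)
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            a, b = lines[i], lines[j]
            dslope = a.slope - b.slope
            scale = max(abs(a.slope), abs(b.slope))
            if abs(dslope) <= rel_tol * scale:
                out.append(Intersection(i, j, None, None, "parallel"))
                continue
            x = (b.intercept - a.intercept) / dslope
            y = a.slope * x + a.intercept
            if abs(x) <= rel_tol * x_scale * 10 or abs(x) < 1e-12:
                loc = "y-axis"
            elif abs(y) <= rel_tol * y_scale * 10 or abs(y) < 1e-12:
                loc = "x-axis"
            else:
                loc = "general"
            out.append(Intersection(i, j, float(x), float(y), loc))
    return lines, out


def _relative_shift(p0, se0, p1, se1) -> tuple[float, float]:
    """Relative shift (p1−p0)/p0 and its delta-method standard error."""
    d = (p1 - p0) / p0
    se = float(np.hypot(se1 / p0, p1 * se0 / p0**2))
    return float(d), se


def classify_inhibition_mode(
    fits: list[MMKineticsResults],
    rel_tol: float = 0.10,
    parallel_tol: float = 0.02,
    z_crit: float = 2.0,
) -> tuple[str, list[float], list[float], str]:
    """Mechanism call from per-level (Km, Vmax) fits (control first).

    Returns (mode, km_shifts, vmax_shifts, diagnostics).  A parameter counts
    as changed when its relative shift at the highest inhibitor level exceeds
    both ``rel_tol`` and ``z_crit`` standard errors; a significant
    opposite-sign shift at an intermediate level makes the series
    non-monotone, hence "indeterminate".
    """
    if len(fits) < 2:
        raise InsufficientDataError("control fit plus at least one inhibited fit required")
    c = fits[0]
    dKs, seKs, dVs, seVs, parallel = [], [], [], [], []
    for f in fits[1:]:
        dK, seK = _relative_shift(c.Km, c.Km_se, f.Km, f.Km_se)
        dV, seV = _relative_shift(c.Vmax, c.Vmax_se, f.Vmax, f.Vmax_se)
        dKs.append(dK)
        seKs.append(seK)
        dVs.append(dV)
        seVs.append(seV)
        sl0, sl1 = c.Km / c.Vmax, f.Km / f.Vmax
        se_sl0 = sl0 * np.hypot(c.Km_se / c.Km, c.Vmax_se / c.Vmax)
        se_sl1 = sl1 * np.hypot(f.Km_se / f.Km, f.Vmax_se / f.Vmax)
        dsl = (sl1 - sl0) / sl0
        se_dsl = float(np.hypot(se_sl1 / sl0, sl1 * se_sl0 / sl0**2))
        parallel.append(abs(dsl) < max(parallel_tol, z_crit * se_dsl))

    def changed(ds, ses):
        d, se = ds[-1], ses[-1]
        if not (abs(d) > rel_tol and abs(d) > z_crit * se):
            return False
        for di, si in zip(ds[:-1], ses[:-1]):
            if np.sign(di) == -np.sign(d) and abs(di) > z_crit * si and abs(di) > rel_tol:
                return None  # significant contradiction across levels
        return True

    k_changed = changed(dKs, seKs)
    v_changed = changed(dVs, seVs)
    if k_changed is None or v_changed is None:
        return "indeterminate", dKs, dVs, "non-monotone parameter shifts across inhibitor levels"
    if not k_changed and not v_changed:
        return "none", dKs, dVs, "neither Km nor Vmax shifted beyond tolerance"
    if k_changed and dKs[-1] > 0 and not v_changed:
        return "competitive", dKs, dVs, "Km increased, Vmax unchanged"
    if v_changed and dVs[-1] < 0 and not k_changed:
        return "non-competitive", dKs, dVs, "Vmax decreased, Km unchanged"
    if k_changed and v_changed and dKs[-1] < 0 and dVs[-1] < 0 and all(parallel):
        return "uncompetitive", dKs, dVs, "Km and Vmax fell proportionally (parallel reciprocal lines)"
    return "mixed", dKs, dVs, "Km and Vmax both shifted non-proportionally"


class InhibitionExperiment:
    """Model object for one inhibitor's full kinetic series.

    ``fit()`` fits every level independently, computes the reciprocal-line
    geometry and returns an :class:`InhibitionVerdict`.  Any sub-fit failure
    yields an "indeterminate" verdict naming the failing level instead of
    raising.
    """

    def __init__(
        self,
        series: InhibitionSeries,
        rel_tol: float = 0.10,
        parallel_tol: float = 0.02,
        z_crit: float = 2.0,
    ):
        self.series = series.sorted()
        self.rel_tol = rel_tol
        self.parallel_tol = parallel_tol
        self.z_crit = z_crit

    def fit(self) -> InhibitionVerdict:
        try:
            fits = fit_inhibition_series(self.series)
        except FitError as exc:
            return InhibitionVerdict(
                inhibitor=self.series.inhibitor,
                mode="indeterminate",
                concentrations_mM=self.series.concentrations_mM,
                fits=[],
                lb_lines=[],
                intersections=[],
                rel_tol=self.rel_tol,
                diagnostics=str(exc),
            )
        lines, inters = lb_lines_and_intersections(fits)
        mode, dKs, dVs, diag = classify_inhibition_mode(
            fits, self.rel_tol, self.parallel_tol, self.z_crit
        )
        return InhibitionVerdict(
            inhibitor=self.series.inhibitor,
            mode=mode,
            concentrations_mM=self.series.concentrations_mM,
            fits=fits,
            lb_lines=lines,
            intersections=inters,
            rel_tol=self.rel_tol,
            km_shifts=dKs,
            vmax_shifts=dVs,
            diagnostics=diag,
        )
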