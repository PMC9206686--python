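"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its parameters and a seed: Michaelis–
Menten velocity data with additive Gaussian noise, inhibitor series under the
four canonical mechanisms, exponential inactivation panels whose rate
constants follow an Arrhenius law, design-of-experiments responses from a
known second-order polynomial, and random protein sequences of a given
composition.  Noiseless output of every generator is an exact fixed point of
the corresponding fitting stage.

Default parameter magnitudes mirror a mesophilic GH5 endoglucanase
characterization (Km ≈ 0.5 mM scale, Vmax ≈ 50–60 U, inactivation Ea ≈ 60
kJ/mol), so synthetic fixtures resemble realistic assay tables.  Velocities
default to means of triplicate readings — matching the common practice of
assaying in triplicate and analyzing the means.
"""

from __future__ import annotations

import numpy as np

from .constants import R
from .exceptions import EnzkitError
from .inactivation import InactivationTimecourse
from .inhibition import InhibitionSeries
from .kinetics import KineticDataset, michaelis_menten

#: Substrate dilution series used by default (two-fold steps, 0.625–20)
DEFAULT_SUBSTRATE_GRID = np.array([0.625, 1.25, 2.5, 5.0, 10.0, 20.0])

INHIBITION_MODES = ("competitive", "non-competitive", "uncompetitive", "mixed", "none")


def simulate_mm_dataset(
    Km: float = 2.0,
    Vmax: float = 50.0,
    substrate=DEFAULT_SUBSTRATE_GRID,
    noise_fraction: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
    substrate_unit: str = "mM",
    velocity_unit: str = "U/mg",
) -> KineticDataset:
    """Michaelis–Menten velocities with additive Gaussian noise.

    ``noise_fraction`` scales the per-replicate noise SD as a fraction of
    Vmax; ``n_replicates`` readings are averaged per substrate level (set to 1
    for single-shot data).  Velocities are truncated at zero.
    """
    if Km <= 0 or Vmax <= 0:
        raise EnzkitError("Km and Vmax must be positive")
    if noise_fraction < 0:
        raise EnzkitError("invalid noise: noise_fraction must be non-negative")
    if n_replicates < 1:
        raise EnzkitError("need at least one replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = np.asarray(substrate, dtype=float)
    if S.size == 0:
        raise EnzkitError("invalid design: empty substrate grid")
    v_true = michaelis_menten(S, Km, Vmax)
    reps = v_true[None, :] + rng.normal(0.0, noise_fraction * Vmax, (n_replicates, S.size))
    v = np.clip(reps, 0.0, None).mean(axis=0)
    return KineticDataset(S, v, substrate_unit=substrate_unit, velocity_unit=velocity_unit)


def apparent_parameters(mode: str, Km: float, Vmax: float, inhibitor_conc: float,
                        Ki: float, alpha: float = 2.0) -> tuple[float, float]:
    """Apparent (Km, Vmax) under a canonical reversible-inhibition mechanism.

    competitive: Km·(1+[I]/Ki), Vmax unchanged.
    non-competitive: Vmax/(1+[I]/Ki), Km unchanged.
    uncompetitive: both divided by (1+[I]/Ki).
    mixed: Km·(1+[I]/Ki)/(1+[I]/(α·Ki)), Vmax/(1+[I]/(α·Ki)).
    """
    I = inhibitor_conc
    if mode == "competitive":
        return Km * (1 + I / Ki), Vmax
    if mode == "non-competitive":
        return Km, Vmax / (1 + I / Ki)
    if mode == "uncompetitive":
        return Km / (1 + I / Ki), Vmax / (1 + I / Ki)
    if mode == "mixed":
        return Km * (1 + I / Ki) / (1 + I / (alpha * Ki)), Vmax / (1 + I / (alpha * Ki))
    if mode == "none":
        return Km, Vmax
    raise EnzkitError(f"invalid mechanism: {mode!r}")


def simulate_inhibition_series(
    mode: str,
    Km: float = 2.0,
    Vmax: float = 50.0,
    Ki: float = 0.5,
    alpha: float = 2.0,
    inhibitor_concs=(0.0, 0.5, 1.0),
    substrate=DEFAULT_SUBSTRATE_GRID,
    noise_fraction: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
    inhibitor: str = "synthetic inhibitor",
) -> InhibitionSeries:
    """Velocity datasets across inhibitor concentrations under a chosen mechanism.

    The per-replicate noise SD is ``noise_fraction`` of the *apparent* Vmax at
    each inhibitor level (measurement error scales with the observed signal).
    """
    if Ki <= 0:
        raise EnzkitError("Ki must be positive")
    if mode not in INHIBITION_MODES:
        raise EnzkitError(f"invalid mechanism: {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    datasets = []
    for I in inhibitor_concs:
        Ka, Va = apparent_parameters(mode, Km, Vmax, I, Ki, alpha)
        datasets.append(
            simulate_mm_dataset(
                Km=Ka, Vmax=Va, substrate=substrate, noise_fraction=noise_fraction,
                n_replicates=n_replicates, seed=rng,
            )
        )
    return InhibitionSeries(inhibitor, list(inhibitor_concs), datasets)


def simulate_inactivation_panel(
    Ea: float = 60.0,
    A: float = 1e7,
    temperatures_c=(40.0, 60.0, 70.0, 80.0, 90.0),
    times_min=(0.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[InactivationTimecourse]:
    """Exponential-decay panels whose k_in(T) follows an Arrhenius law.

    k_in(T) = A·exp(−Ea/(R·T)) in min⁻¹ with Ea in kJ/mol; residual fractions
    exp(−k_in·t) plus Gaussian noise, clipped to (0, 1.05].
    """
    if Ea <= 0 or A <= 0:
        raise EnzkitError("Ea and A must be positive")
    temps = np.asarray(temperatures_c, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if temps.size == 0 or t.size == 0:
        raise EnzkitError("invalid design: empty temperature or time grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel = []
    for Tc in temps:
        Tk = Tc + 273.15
        k_in = A * np.exp(-Ea * 1000.0 / (R * Tk))
        frac = np.exp(-k_in * t)
        if noise_sd > 0:
            frac = frac + rng.normal(0.0, noise_sd, t.size)
            frac[t == 0] = 1.0  # normalization pins the zero-time fraction
        frac = np.clip(frac, 1e-12, 1.05)
        panel.append(InactivationTimecourse(temperature_k=Tk, times_min=t, residual_fraction=frac))
    return panel


def simulate_doe_response(
    design,
    coef_natural: dict[str, float],
    block_effects: dict[int, float] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Responses from a known second-order polynomial over a design matrix.

    ``coef_natural`` maps term names (Intercept, A, B, C, AB, AC, BC, A^2,
    B^2, C^2 — using the factors' symbols) to natural-unit coefficients.
    """
    from .doe import _quadratic_columns  # local import to avoid cycle

    if design.factors is None:
        raise EnzkitError("dimension error: design must carry factor specifications")
    symbols = [f.symbol for f in design.factors]
    cols, names = _quadratic_columns(design.natural, symbols)
    missing = [n for n in names + ["Intercept"] if n not in coef_natural]
    if missing:
        raise EnzkitError(f"dimension error: missing coefficients {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.full(design.n_runs, float(coef_natural["Intercept"]))
    for c, n in zip(cols.T, names):
        y = y + coef_natural[n] * c
    if block_effects:
        if design.blocks is None:
            raise EnzkitError("dimension error: block effects given but design has no blocks")
        y = y + np.array([block_effects.get(int(bl), 0.0) for bl in design.blocks])
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.size)
    return y


def random_protein(
    length: int,
    composition: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> str:
    """Random amino-acid sequence drawn from a composition (default uniform)."""
    if length < 2:
        raise EnzkitError("length must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if composition is None:
        composition = {aa: 1.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    letters = list(composition)
    weights = np.array([composition[aa] for aa in letters], dtype=float)
    if np.all(weights <= 0):
        raise EnzkitError("invalid composition: all weights zero")
    weights = weights / weights.sum()
    return "".join(rng.choice(letters, size=length, p=weights))
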