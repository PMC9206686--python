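"""Diagnostic plots for the fitting stages (matplotlib)."""

from __future__ import annotations

import numpy as np

from .inactivation import InactivationResults
from .kinetics import KineticDataset, MMKineticsResults, michaelis_menten


def plot_mm_fit(data: KineticDataset, fit: MMKineticsResults, ax=None):
    """Velocity data with the fitted Michaelis-Menten curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    S = data.substrate_conc
    ax.plot(S, data.velocity, "o", label="data")
    grid = np.linspace(0, S.max() * 1.1, 200)
    ax.plot(grid, michaelis_menten(grid, fit.Km, fit.Vmax), "-",
            label=f"fit: Km={fit.Km:.3g}, Vmax={fit.Vmax:.3g}")
    ax.set_xlabel(f"substrate ({data.substrate_unit})")
    ax.set_ylabel(f"velocity ({data.velocity_unit})")
    ax.legend()
    return ax


def plot_lineweaver_burk(fits: list[MMKineticsResults], labels=None, ax=None):
    """Double-reciprocal lines of one or more fits (inhibition diagnostics)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x_left = -1.2 * max(1.0 / f.Km for f in fits)
    x_right = abs(x_left)
    grid = np.linspace(x_left, x_right, 100)
    for i, f in enumerate(fits):
        line = f.lineweaver_burk_line()
        lbl = labels[i] if labels else f"Km={f.Km:.3g}, Vmax={f.Vmax:.3g}"
        ax.plot(grid, line.slope * grid + line.intercept, label=lbl)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("1/S")
    ax.set_ylabel("1/v")
    ax.legend()
    return ax


def plot_inactivation_arrhenius(results: InactivationResults, ax=None):
    """Arrhenius plot (ln k_in vs 1/T) with the fitted line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    usable = [r for r in results.rates if r.k_in > 0]
    invT = np.array([1.0 / r.temperature_k for r in usable])
    lnk = np.log([r.k_in for r in usable])
    ax.plot(invT, lnk, "o", label="k_in")
    if results.arrhenius is not None:
        grid = np.linspace(invT.min(), invT.max(), 50)
        ax.plot(grid, results.arrhenius.slope * grid + results.arrhenius.intercept,
                "-", label=f"Ea = {results.arrhenius.Ea:.3g} kJ/mol")
    ax.set_xlabel("1/T (1/K)")
    ax.set_ylabel("ln k_in")
    ax.legend()
    return ax
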