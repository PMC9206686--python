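"""Internal-consistency audit of a reported thermodynamic characterization.

Published enzyme tables sometimes contain values that do not follow from
their own inputs (transcription errors, unit slips, formula typos).  This
module recomputes every derivable quantity of a characterization record from
its stated inputs and flags entries whose reported values disagree beyond a
relative tolerance, without altering either value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import celc307
from .activation import eyring_free_energy
from .arrhenius import arrhenius_activation_energy
from .inactivation import half_life_and_D


@dataclass(frozen=True)
class ConsistencyFlag:
    quantity: str
    reported: float
    recomputed: float
    relation: str
    consistent: bool

    def __str__(self) -> str:
        tag = "OK " if self.consistent else "FLAG"
        return (
            f"[{tag}] {self.quantity}: reported {self.reported:g}, "
            f"recomputed {self.recomputed:g} ({self.relation})"
        )


def _flag(quantity, reported, recomputed, relation, rel_tol) -> ConsistencyFlag:
    ok = abs(recomputed - reported) <= rel_tol * max(abs(reported), 1e-12)
    return ConsistencyFlag(quantity, float(reported), float(recomputed), relation, ok)


def consistency_report(rel_tol: float = 0.02) -> list[ConsistencyFlag]:
    """Audit the CelC307 record: recompute each derivable value from its inputs.

    Checks, at the reported 40 °C reference temperature:

    * ΔG‡ against −RT·ln(kcat·h/(kB·T)) from the reported kcat;
    * per-temperature t½ against ln2/k_in and D against ln10/k_in;
    * the D/t½ ratio against ln10/ln2 (a unit-free identity);
    * Ea# against the Arrhenius regression of the reported k_in values;
    * ΔG# at 40 °C against the minute-scale Eyring value from k_in.
    """
    flags: list[ConsistencyFlag] = []
    T = celc307.T_OPT_K

    _, dG_from_kcat = eyring_free_energy(celc307.KCAT, T, "per_second")
    flags.append(
        _flag("dG_act", celc307.ACTIVATION_TABLE["dG_act"], dG_from_kcat,
              "-RT ln(kcat h/(kB T)) from reported kcat", rel_tol)
    )

    tbl = celc307.INACTIVATION_TABLE
    for _, row in tbl.iterrows():
        th, D = half_life_and_D(row["k_in"])
        label = f"{row['temp_C']:.0f}C"
        flags.append(_flag(f"t_half@{label}", row["t_half"], th, "ln2/k_in", rel_tol))
        flags.append(_flag(f"D@{label}", row["D_value"], D, "ln10/k_in", rel_tol))
        flags.append(
            _flag(
                f"D/t_half@{label}",
                row["D_value"] / row["t_half"],
                np.log(10) / np.log(2),
                "ln10/ln2 identity",
                rel_tol,
            )
        )

    temps_k, kins = celc307.inactivation_rates()
    ea_fit = arrhenius_activation_energy(temps_k, kins).Ea
    flags.append(
        _flag("Ea_inact", celc307.EA_INACT, ea_fit, "Arrhenius OLS on reported k_in", rel_tol)
    )

    from .inactivation import inactivation_state_functions

    sf40 = inactivation_state_functions(tbl["k_in"].iloc[0], celc307.EA_INACT, T, "per_minute")
    flags.append(
        _flag("dG_inact@40C", tbl["dG"].iloc[0], sf40.dG,
              "minute-scale Eyring from reported k_in", rel_tol)
    )
    return flags


def inconsistent_entries(rel_tol: float = 0.02) -> list[ConsistencyFlag]:
    """Only the flags that fail the audit."""
    return [f for f in consistency_report(rel_tol) if not f.consistent]
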