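"""CSV/FASTA/YAML readers and writers shared by the analysis stages.

All CSV dialects are plain headered tables; files are read with
UTF-8-BOM-tolerant decoding, so BOM/CRLF variants parse identically.  Schema
problems name the missing column; parse problems name the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .assay import ActivityProfile, average_replicates
from .doe import FactorSpec
from .exceptions import EnzkitError
from .inactivation import InactivationTimecourse
from .inhibition import InhibitionSeries
from .kinetics import KineticDataset


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8-sig")
    df.columns = [str(c).strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise EnzkitError(f"schema error: missing column {col!r} in {path}")
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise EnzkitError(f"parse error: non-numeric {col!r} at row {bad[0] + 2} of {path}")
        df[col] = converted
    return df


def read_calibration_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Standard-curve table: columns concentration_umol, absorbance."""
    df = _numeric(_read_csv(path, ["concentration_umol", "absorbance"]),
                  ["concentration_umol", "absorbance"], path)
    return df["concentration_umol"].to_numpy(), df["absorbance"].to_numpy()


def read_profile_csv(path, profile_kind: str = "activity") -> ActivityProfile:
    """Condition-activity table: columns condition, activity, optional replicate."""
    df = _numeric(_read_csv(path, ["condition", "activity"]), ["condition", "activity"], path)
    return average_replicates(
        df["condition"].to_numpy(), df["activity"].to_numpy(), profile_kind=profile_kind
    )


def read_kinetics_csv(path, substrate_unit="mM", velocity_unit="U/mg") -> KineticDataset:
    """Velocity table: columns substrate, velocity."""
    df = _numeric(_read_csv(path, ["substrate", "velocity"]), ["substrate", "velocity"], path)
    return KineticDataset(
        df["substrate"].to_numpy(), df["velocity"].to_numpy(),
        substrate_unit=substrate_unit, velocity_unit=velocity_unit,
    )


def read_inhibition_csv(path, inhibitor: str = "inhibitor") -> InhibitionSeries:
    """Inhibition table: columns inhibitor_conc, substrate, velocity."""
    cols = ["inhibitor_conc", "substrate", "velocity"]
    df = _numeric(_read_csv(path, cols), cols, path)
    concs = sorted(df["inhibitor_conc"].unique())
    datasets = []
    for c in concs:
        sub = df[df["inhibitor_conc"] == c]
        datasets.append(KineticDataset(sub["substrate"].to_numpy(), sub["velocity"].to_numpy()))
    return InhibitionSeries(inhibitor, [float(c) for c in concs], datasets)


def read_inactivation_csv(path) -> list[InactivationTimecourse]:
    """Long-format decay table: columns temperature_C, time_min, residual_fraction."""
    cols = ["temperature_C", "time_min", "residual_fraction"]
    df = _numeric(_read_csv(path, cols), cols, path)
    panel = []
    for Tc in sorted(df["temperature_C"].unique()):
        sub = df[df["temperature_C"] == Tc].sort_values("time_min")
        panel.append(
            InactivationTimecourse(
                temperature_k=float(Tc) + 273.15,
                times_min=sub["time_min"].to_numpy(),
                residual_fraction=sub["residual_fraction"].to_numpy(),
            )
        )
    return panel


def read_doe_csv(path, factors: list[FactorSpec]) -> pd.DataFrame:
    """Design+response table: one column per factor, response, optional block."""
    required = [f.name for f in factors] + ["response"]
    df = _read_csv(path, required)
    numeric_cols = required + (["block"] if "block" in df.columns else [])
    return _numeric(df, numeric_cols, path)


def read_factor_specs(path) -> list[FactorSpec]:
    """YAML factor file: a list of {name, symbol, center, half_range}."""
    with open(path, encoding="utf-8-sig") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise EnzkitError("schema error: factor file must be a non-empty list")
    return [FactorSpec(**entry) for entry in raw]


def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA records as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
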