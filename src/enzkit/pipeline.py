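"""End-to-end characterization pipeline assembling all stage outputs.

``run_pipeline`` takes a configuration mapping stage names to their inputs,
runs each requested stage independently (one stage's failure never aborts the
others), and returns a :class:`CharacterizationReport` whose content is plain
JSON-serializable data.  Reports round-trip losslessly through JSON and are
byte-deterministic for identical inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as ezio
from .activation import ActivationAnalysis
from .assay import fit_linear_calibration, relative_activity_profile
from .exceptions import EnzkitError
from .inactivation import ThermalInactivation
from .inhibition import InhibitionExperiment
from .kinetics import MichaelisMenten, catalytic_constants
from .doe import ResponseSurface, optimize_response
from .seqprops import protparam_profile, translate_sequence

__version__ = "0.1.0"


@dataclass
class CharacterizationReport:
    """Consolidated per-stage results with provenance and accumulated warnings."""

    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "warnings": self.warnings, "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CharacterizationReport":
        d = json.loads(text)
        return cls(stages=d["stages"], warnings=d["warnings"], provenance=d["provenance"])


def _jsonable(obj):
    """Convert dataclasses/arrays/numpy scalars to plain JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if hasattr(obj, "to_dict"):  # pandas
        return obj.to_dict()
    return obj


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage_calibration(cfg):
    x, y = ezio.read_calibration_csv(cfg["input"])
    cal = fit_linear_calibration(x, y)
    return _jsonable(cal)


def _stage_profile(cfg):
    prof = ezio.read_profile_csv(cfg["input"], cfg.get("profile_kind", "activity"))
    rel = relative_activity_profile(prof)
    return {
        "conditions": rel.conditions.tolist(),
        "relative_activity_percent": rel.activities.tolist(),
        "profile_kind": rel.profile_kind,
    }


def _stage_mm(cfg):
    data = ezio.read_kinetics_csv(
        cfg["input"],
        substrate_unit=cfg.get("substrate_unit", "mM"),
        velocity_unit=cfg.get("velocity_unit", "U/mg"),
    )
    res = MichaelisMenten(data, weighting=cfg.get("weighting", "uniform")).fit()
    if "kcat" in cfg:
        res = catalytic_constants(res, kcat=cfg["kcat"])
    out = _jsonable(res)
    out["Ka"] = res.Ka
    return out


def _stage_inhibition(cfg):
    series = ezio.read_inhibition_csv(cfg["input"], cfg.get("inhibitor", "inhibitor"))
    verdict = InhibitionExperiment(series, rel_tol=cfg.get("rel_tol", 0.10)).fit()
    return _jsonable(verdict)


def _stage_activation(cfg):
    kwargs = dict(
        kcat=cfg["kcat"],
        temperature_k=cfg["temperature_C"] + 273.15,
        Km=cfg.get("Km"),
        kcat_over_Km=cfg.get("kcat_over_Km"),
        km_unit_mode=cfg.get("km_unit_mode", "M"),
        rate_unit_mode=cfg.get("rate_unit_mode", "per_second"),
        dG_override=cfg.get("dG_override"),
    )
    if "Ea" in cfg:
        kwargs["Ea"] = cfg["Ea"]
    elif "input" in cfg:
        prof = ezio.read_profile_csv(cfg["input"])
        kwargs["temperatures_k"] = prof.conditions + 273.15
        kwargs["activities"] = prof.activities
    return _jsonable(ActivationAnalysis(**kwargs).fit())


def _stage_inactivation(cfg):
    panel = ezio.read_inactivation_csv(cfg["input"])
    res = ThermalInactivation(panel, rate_unit_mode=cfg.get("rate_unit_mode", "per_second")).fit()
    out = _jsonable(res)
    out["Ea"] = res.Ea
    out["t_half"] = [r.t_half for r in res.rates]
    out["D_value"] = [r.D_value for r in res.rates]
    return out


def _stage_doe(cfg):
    factors = ezio.read_factor_specs(cfg["factors"])
    df = ezio.read_doe_csv(cfg["input"], factors)
    model = ResponseSurface.from_dataframe(df, factors).fit()
    out = {
        "coefficients_natural": model.coef_natural,
        "anova": model.anova.reset_index().to_dict(orient="records"),
        "r_squared": model.r_squared,
    }
    if "bounds" in cfg:
        point, value = optimize_response(model, [tuple(b) for b in cfg["bounds"]])
        out["optimum"] = {f.name: float(p) for f, p in zip(factors, point)}
        out["optimum_predicted"] = value
    return _jsonable(out)


def _stage_seqprops(cfg):
    records = ezio.read_fasta(cfg["input"])
    out = []
    for rid, seq in records:
        if cfg.get("nucleotide", False):
            seq = translate_sequence(seq, frame=cfg.get("frame", 1))
        out.append(_jsonable(protparam_profile(seq, seq_id=rid)))
    return out


_STAGES = {
    "calibration": _stage_calibration,
    "profile": _stage_profile,
    "mm": _stage_mm,
    "inhibition": _stage_inhibition,
    "activation": _stage_activation,
    "inactivation": _stage_inactivation,
    "doe": _stage_doe,
    "seqprops": _stage_seqprops,
}


def run_pipeline(config: dict) -> CharacterizationReport:
    """Run every stage named in ``config``; collect results, warnings, provenance.

    ``config`` maps stage names (see keys of the internal registry) to their
    stage configuration; unknown stages and failing stages are recorded as
    warnings, not errors.
    """
    if not config:
        raise EnzkitError("nothing to do: empty pipeline configuration")
    report = CharacterizationReport(provenance={"software": f"enzkit {__version__}", "inputs": {}})
    import warnings as _w

    for name, cfg in config.items():
        runner = _STAGES.get(name)
        if runner is None:
            report.warnings.append(f"unknown stage {name!r} skipped")
            continue
        for key in ("input", "factors"):
            if isinstance(cfg, dict) and key in cfg and Path(str(cfg[key])).exists():
                report.provenance["inputs"][f"{name}.{key}"] = _digest(cfg[key])
        try:
            with _w.catch_warnings(record=True) as caught:
                _w.simplefilter("always")
                report.stages[name] = runner(cfg)
            for w in caught:
                report.warnings.append(f"{name}: {w.message}")
        except Exception as exc:  # stage isolation is the contract
            report.warnings.append(f"stage {name!r} failed: {exc}")
    return report
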