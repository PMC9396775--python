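"""Serialization: run reports (JSON), angle/coordinate tables (CSV),
minimal CA-trace PDB export, and YAML run configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import yaml

from .hybrid import HybridConfig, RunResult
from .model import ABSequence, ValidationError, build_coordinates
from .pso import PSOConfig
from .tabu import TabuConfig

__all__ = [
    "write_angles_csv",
    "read_angles_csv",
    "write_coordinates_csv",
    "write_pdb",
    "write_run_report",
    "read_run_report",
    "config_to_dict",
    "load_config",
]

_REPORT_REQUIRED = (
    "method", "sequence_id", "sequence", "seed", "best_energy",
    "best_angles", "trace",
)


def write_angles_csv(angles, path: Union[str, Path]) -> None:
    lines = ["index,angle_rad"]
    for i, a in enumerate(np.asarray(angles, float)):
        lines.append(f"{i},{float(a)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_angles_csv(path: Union[str, Path]) -> np.ndarray:
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0].strip() != "index,angle_rad":
        raise ValidationError("angles CSV must have header 'index,angle_rad'")
    return np.array([float(line.split(",")[1]) for line in lines[1:]])


def write_coordinates_csv(sequence: ABSequence, angles,
                          path: Union[str, Path]) -> None:
    points = build_coordinates(np.asarray(angles, float)).points
    lines = ["index,residue,x,y"]
    for i, (res, (x, y)) in enumerate(zip(sequence.residues, points)):
        lines.append(f"{i},{res},{float(x)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pdb(sequence: ABSequence, angles, path: Union[str, Path],
              scale: float = 1.0) -> None:
    """Minimal CA-only pseudo-chain: one ATOM record per residue, chain A,
    z = 0, coordinates multiplied by ``scale``."""
    points = build_coordinates(np.asarray(angles, float)).points * scale
    lines = []
    for i, (res, (x, y)) in enumerate(zip(sequence.residues, points), start=1):
        resname = "ALA" if res == "A" else "GLY"
        lines.append(
            f"ATOM  {i:5d}  CA  {resname} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_run_report(result: RunResult, path: Union[str, Path],
                     config: Optional[HybridConfig] = None) -> None:
    """JSON report: lossless for all RunResult fields, config echoed,
    byte-reproducible (sorted keys, no timestamps)."""
    payload = {
        "method": result.method,
        "sequence_id": result.sequence_id,
        "sequence": result.sequence,
        "seed": result.seed,
        "best_energy": result.best_energy,
        "best_angles": list(result.best_angles),
        "trace": list(result.trace),
        "phase_boundary": result.phase_boundary,
        "config": config_to_dict(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_run_report(path: Union[str, Path]) -> Tuple[RunResult, Optional[dict]]:
    data = json.loads(Path(path).read_text())
    missing = [k for k in _REPORT_REQUIRED if k not in data]
    if missing:
        raise ValidationError(f"run report missing required fields: {missing}")
    result = RunResult(
        method=data["method"],
        sequence_id=data["sequence_id"],
        sequence=data["sequence"],
        best_energy=float(data["best_energy"]),
        best_angles=tuple(data["best_angles"]),
        trace=tuple(data["trace"]),
        seed=data["seed"],
        phase_boundary=data.get("phase_boundary"),
    )
    return result, data.get("config")


def config_to_dict(config: HybridConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> HybridConfig:
    """Inverse of :func:`config_to_dict`; used to replay a run from its
    report's echoed configuration."""
    data = dict(data)
    pso = _build(PSOConfig, data.pop("pso", {}) or {}, "pso")
    tabu = _build(TabuConfig, data.pop("tabu", {}) or {}, "tabu")
    top_known = {f.name for f in dataclasses.fields(HybridConfig)} - {"pso", "tabu"}
    unknown = set(data) - top_known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return HybridConfig(pso=pso, tabu=tabu, **data)


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValidationError(f"unknown {name} config keys: {sorted(unknown)}")
    return cls(**section)


def load_config(path: Union[str, Path]) -> HybridConfig:
    """Load a YAML run configuration; unknown keys are rejected and any
    omitted value falls back to the benchmark defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    return config_from_dict(raw)
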