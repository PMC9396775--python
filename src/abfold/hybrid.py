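"""Hybrid driver: PSO global search seeding tabu refinement, plus the two
single-method baselines and run summarization."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .model import ABSequence, ValidationError, build_coordinates, fitness
from .pso import PSOConfig, run_pso
from .tabu import TabuConfig, run_tabu

__all__ = [
    "HybridConfig",
    "RunResult",
    "run_hybrid",
    "run_baseline",
    "improvement_percent",
    "summarize_runs",
]


@dataclass
class HybridConfig:
    """Orchestration parameters.

    The total iteration budget (default 800) is shared between phases:
    PSO may use up to ``pso_share`` of it but hands off as soon as its
    best energy stalls for ``window`` iterations; tabu search receives
    every remaining iteration, seeded with the PSO global best.  The
    default share of 1.0 lets PSO keep searching while it is still
    improving, so tabu takes over exactly when the global phase has
    genuinely converged (an earlier fixed cut starves whichever phase is
    doing the real work on this landscape).
    """

    total_iterations: int = 800
    pso: PSOConfig = field(default_factory=PSOConfig)
    tabu: TabuConfig = field(default_factory=TabuConfig)
    pso_share: float = 1.0
    window: int = 150
    tolerance: float = 1e-4
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 < self.pso_share <= 1.0:
            raise ValidationError("pso_share must lie in (0, 1]")
        if self.total_iterations < 2:
            raise ValidationError("total_iterations must be >= 2")


@dataclass
class RunResult:
    """Outcome of one optimization run (any method)."""

    method: str
    sequence_id: str
    sequence: str
    best_energy: float
    best_angles: Tuple[float, ...]
    trace: Tuple[float, ...]
    seed: Optional[int]
    phase_boundary: Optional[int] = None

    @property
    def best_coordinates(self) -> np.ndarray:
        return build_coordinates(np.asarray(self.best_angles)).points


def _phase_rngs(seed: Optional[int]) -> Tuple[np.random.Generator, np.random.Generator]:
    """Deterministic per-phase generators from one master seed.

    The PSO phase uses the plain ``default_rng(seed)`` stream — the same
    one the standalone PSO baseline uses, so for a given seed the hybrid's
    global phase follows the baseline trajectory until handoff — and the
    tabu phase gets an independent child stream.
    """
    tabu_ss = np.random.SeedSequence(seed).spawn(1)[0]
    return np.random.default_rng(seed), np.random.default_rng(tabu_ss)


def run_hybrid(sequence: ABSequence, config: Optional[HybridConfig] = None, *,
               seed: Optional[int] = None) -> RunResult:
    """PSO until convergence (or its budget share), then tabu refinement
    from the PSO global best; traces are concatenated."""
    config = config or HybridConfig()
    master_seed = seed if seed is not None else config.seed
    pso_rng, tabu_rng = _phase_rngs(master_seed)

    pso_budget = max(1, int(round(config.total_iterations * config.pso_share)))
    pso_cfg = dataclasses.replace(config.pso, iterations=pso_budget)
    pso_result = run_pso(sequence, pso_cfg, rng=pso_rng, early_stop=True,
                         window=config.window, tolerance=config.tolerance)

    tabu_budget = config.total_iterations - len(pso_result.trace)
    best_angles, best_energy = pso_result.best_position, pso_result.best_energy
    trace = pso_result.trace
    if tabu_budget > 0:
        tabu_cfg = dataclasses.replace(config.tabu, iterations=tabu_budget)
        tabu_result = run_tabu(sequence, pso_result.best_position, tabu_cfg,
                               rng=tabu_rng)
        trace = trace + tabu_result.trace
        if tabu_result.best_energy <= best_energy:
            best_angles, best_energy = tabu_result.best_position, tabu_result.best_energy
    return RunResult(
        method="hybrid",
        sequence_id=sequence.name or sequence.residues,
        sequence=sequence.residues,
        best_energy=float(best_energy),
        best_angles=tuple(float(a) for a in best_angles),
        trace=trace,
        seed=master_seed,
        phase_boundary=len(pso_result.trace),
    )


def run_baseline(sequence: ABSequence, method: str,
                 config: Optional[HybridConfig] = None, *,
                 seed: Optional[int] = None) -> RunResult:
    """Run a single method with the full iteration budget.

    ``pso`` delegates to :func:`run_pso`; ``tabu`` starts from a seeded
    uniform-random conformation.
    """
    config = config or HybridConfig()
    master_seed = seed if seed is not None else config.seed
    if method == "pso":
        cfg = dataclasses.replace(config.pso, iterations=config.total_iterations)
        rng = np.random.default_rng(master_seed)
        res = run_pso(sequence, cfg, rng=rng)
        best_angles, best_energy, trace = res.best_position, res.best_energy, res.trace
    elif method == "tabu":
        rng = np.random.default_rng(master_seed)
        initial = rng.uniform(-math.pi, math.pi, size=sequence.n - 2)
        cfg = dataclasses.replace(config.tabu, iterations=config.total_iterations)
        res = run_tabu(sequence, initial, cfg, rng=rng)
        best_angles, best_energy, trace = res.best_position, res.best_energy, res.trace
    else:
        raise ValidationError(f"unknown method {method!r}; expected 'pso' or 'tabu'")
    return RunResult(
        method=method,
        sequence_id=sequence.name or sequence.residues,
        sequence=sequence.residues,
        best_energy=float(best_energy),
        best_angles=tuple(float(a) for a in best_angles),
        trace=tuple(trace),
        seed=master_seed,
    )


def improvement_percent(e_new: float, e_ref: float) -> float:
    """Relative improvement in minimum energy, on absolute values:
    (|e_new| - |e_ref|) / |e_ref| * 100."""
    if e_ref == 0:
        raise ValidationError("reference energy must be nonzero")
    return (abs(e_new) - abs(e_ref)) / abs(e_ref) * 100.0


def _as_record(item) -> dict:
    if isinstance(item, RunResult):
        return {"sequence": item.sequence_id, "method": item.method,
                "energy": item.best_energy}
    if isinstance(item, dict):
        return {"sequence": item["sequence"], "method": item["method"],
                "energy": float(item["energy"])}
    raise ValidationError(f"cannot summarize {type(item).__name__}")


def summarize_runs(results: Iterable[Union[RunResult, dict]]) -> pd.DataFrame:
    """Per (sequence, method) summary of best energies over runs.

    Columns: n_runs, min, median, mean, plus — on hybrid rows for which
    the matching baseline is present — improvement_vs_tabu_pct and
    improvement_vs_pso_pct computed on the per-group minima.
    """
    records = [_as_record(r) for r in results]
    if not records:
        raise ValidationError("no results to summarize")
    df = pd.DataFrame.from_records(records)
    summary = (
        df.groupby(["sequence", "method"])["energy"]
        .agg(n_runs="size", min="min", median="median", mean="mean")
        .reset_index()
    )
    for base in ("tabu", "pso"):
        col = f"improvement_vs_{base}_pct"
        summary[col] = np.nan
        for seq_id, group in summary.groupby("sequence"):
            methods = group.set_index("method")["min"]
            if "hybrid" in methods.index and base in methods.index:
                pct = improvement_percent(methods["hybrid"], methods[base])
                summary.loc[
                    (summary["sequence"] == seq_id) & (summary["method"] == "hybrid"),
                    col,
                ] = pct
    return summary
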