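"""Tabu search refinement over conformation space.

Neighborhood moves are single-coordinate perturbations

    x_j' = wrap(x_j + f(q) * pi * Q * K),   f(q) = +1 if q < 0.5 else -1

with q, Q fresh uniform(0, 1) draws and K a fixed scale factor.  Of the L
neighbors generated each iteration, the L_C lowest-energy ones form the
candidate set; a candidate is tabu when some recently accepted solution y
satisfies both |E(y) - E(z)| <= E_0 and ||y - z|| <= r_0 (Euclidean), unless
it beats the incumbent best (aspiration).  The tabu list is FIFO with
capacity and tenure L_T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import ABSequence, ValidationError, batch_total_energy, fitness, wrap_angle

__all__ = [
    "TabuConfig",
    "TabuEntry",
    "TabuList",
    "CandidateSet",
    "TabuResult",
    "sign_factor",
    "perturb",
    "generate_neighbors",
    "select_candidates",
    "is_tabu",
    "aspiration_overrides",
    "update_tabu_list",
    "tabu_step",
    "run_tabu",
]


@dataclass
class TabuConfig:
    """Tabu parameters; defaults follow the benchmark setup
    (L = 40 neighbors, L_C = 6 candidates, K = 0.93, L_T = 8,
    E_0 = 0.10, r_0 = 0.005)."""

    L: int = 40
    Lc: int = 6
    K: float = 0.93
    Lt: int = 8
    E0: float = 0.10
    r0: float = 0.005
    iterations: int = 800
    k_power_mode: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if not 1 <= self.Lc <= self.L:
            raise ValidationError("need 1 <= Lc <= L")
        if self.K <= 0:
            raise ValidationError("K must be positive")
        if self.E0 <= 0 or self.r0 <= 0:
            raise ValidationError("E0 and r0 must be positive")
        if self.Lt < 1:
            raise ValidationError("Lt must be >= 1")


@dataclass
class TabuEntry:
    solution: np.ndarray
    energy: float
    tenure: int


@dataclass
class TabuList:
    """FIFO short-term memory of recently accepted solutions."""

    capacity: int
    entries: List[TabuEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CandidateSet:
    """Lowest-energy neighbors, ascending; ties keep generation order."""

    solutions: List[np.ndarray]
    energies: List[float]


@dataclass
class TabuResult:
    best_position: np.ndarray
    best_energy: float
    trace: Tuple[float, ...]


def sign_factor(q: float) -> int:
    """Perturbation sign: +1 when q < 0.5, otherwise -1."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError("q must lie in [0, 1]")
    return 1 if q < 0.5 else -1


def perturb(solution: np.ndarray, coordinate_index: int, q: float, Q: float,
            K: float) -> np.ndarray:
    """Single-coordinate neighborhood move of magnitude pi * Q * K."""
    x = np.array(solution, dtype=float)
    if not 0 <= coordinate_index < x.size:
        raise ValidationError(f"coordinate index {coordinate_index} out of range")
    if not 0.0 <= Q <= 1.0:
        raise ValidationError("Q must lie in [0, 1]")
    x[coordinate_index] = wrap_angle(
        x[coordinate_index] + sign_factor(q) * math.pi * Q * K
    )
    return x


def generate_neighbors(solution: np.ndarray, L: int,
                       rng: np.random.Generator, K: float = 0.93,
                       k_power_mode: bool = False) -> List[np.ndarray]:
    """Generate L neighbors, each differing from the input in exactly one
    coordinate.  With ``k_power_mode`` the scale decays as K**i across the
    generation index i (alternative reading of the neighborhood rule)."""
    if L < 1:
        raise ValidationError("L must be >= 1")
    x = np.asarray(solution, dtype=float)
    neighbors = []
    for i in range(L):
        j = int(rng.integers(x.size))
        q = float(rng.uniform())
        Q = float(rng.uniform())
        scale = K ** i if k_power_mode else K
        neighbors.append(perturb(x, j, q, Q, scale))
    return neighbors


def select_candidates(neighbors: Sequence[np.ndarray],
                      energies: Sequence[float], Lc: int) -> CandidateSet:
    """The min(Lc, L) lowest-energy neighbors; stable sort keeps the
    earlier-generated neighbor first on ties."""
    order = np.argsort(np.asarray(energies, dtype=float), kind="stable")[:Lc]
    return CandidateSet(
        solutions=[np.asarray(neighbors[k], float) for k in order],
        energies=[float(energies[k]) for k in order],
    )


def is_tabu(candidate: np.ndarray, candidate_energy: float,
            tabu_list: TabuList, E0: float, r0: float) -> bool:
    """True iff some listed solution is within E0 in energy AND r0 in
    Euclidean distance of the candidate."""
    z = np.asarray(candidate, dtype=float)
    for entry in tabu_list.entries:
        if abs(entry.energy - candidate_energy) <= E0 \
                and np.linalg.norm(entry.solution - z) <= r0:
            return True
    return False


def aspiration_overrides(candidate_energy: float, best_so_far_energy: float) -> bool:
    """Aspiration rule: a strictly better-than-incumbent candidate is
    accepted even if tabu."""
    return candidate_energy < best_so_far_energy


def update_tabu_list(tabu_list: TabuList, accepted_solution: np.ndarray,
                     energy: float) -> TabuList:
    """Decrement all tenures, expire entries reaching 0, append the newly
    accepted solution with full tenure, and evict FIFO past capacity."""
    kept = []
    for entry in tabu_list.entries:
        entry.tenure -= 1
        if entry.tenure > 0:
            kept.append(entry)
    kept.append(TabuEntry(np.array(accepted_solution, float), float(energy),
                          tenure=tabu_list.capacity))
    while len(kept) > tabu_list.capacity:
        kept.pop(0)
    return TabuList(capacity=tabu_list.capacity, entries=kept)


def tabu_step(current: np.ndarray, best_so_far: Tuple[np.ndarray, float],
              tabu_list: TabuList, sequence: ABSequence, config: TabuConfig,
              rng: np.random.Generator):
    """One tabu iteration.

    Returns ``(new_current, new_current_energy, new_best, new_list)``
    where ``new_best`` is an (angles, energy) pair.  The move taken is the
    lowest-energy candidate that is non-tabu or aspirated; when every
    candidate is tabu and none aspirates, the lowest-energy one is taken
    anyway to avoid deadlock.
    """
    best_position, best_energy = best_so_far
    neighbors = generate_neighbors(current, config.L, rng, K=config.K,
                                   k_power_mode=config.k_power_mode)
    energies = batch_total_energy(sequence, np.vstack(neighbors))
    candidates = select_candidates(neighbors, energies, config.Lc)

    chosen, chosen_energy = None, math.inf
    for z, ez in zip(candidates.solutions, candidates.energies):
        if not math.isfinite(ez):
            continue
        if aspiration_overrides(ez, best_energy) or \
                not is_tabu(z, ez, tabu_list, config.E0, config.r0):
            chosen, chosen_energy = z, ez
            break
    if chosen is None:
        for z, ez in zip(candidates.solutions, candidates.energies):
            if math.isfinite(ez):
                chosen, chosen_energy = z, ez
                break
    if chosen is None:  # every neighbor diverged; stay put
        chosen, chosen_energy = np.array(current, float), fitness(sequence, current)

    tabu_list = update_tabu_list(tabu_list, chosen, chosen_energy)
    if chosen_energy < best_energy:
        best_position, best_energy = chosen.copy(), chosen_energy
    return chosen, chosen_energy, (best_position, best_energy), tabu_list


def run_tabu(sequence: ABSequence, initial_solution: np.ndarray,
             config: TabuConfig, *,
             rng: Optional[np.random.Generator] = None) -> TabuResult:
    """Run tabu search from an initial conformation.  The best-so-far
    trace is monotone non-increasing and starts at the initial energy."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    current = np.asarray(initial_solution, dtype=float)
    if current.size != sequence.n - 2:
        raise ValidationError(
            f"initial solution has dimension {current.size}, expected {sequence.n - 2}"
        )
    best = (current.copy(), fitness(sequence, current))
    tabu_list = TabuList(capacity=config.Lt)
    trace: List[float] = []
    for _ in range(config.iterations):
        current, _, best, tabu_list = tabu_step(
            current, best, tabu_list, sequence, config, rng
        )
        trace.append(best[1])
    return TabuResult(best_position=best[0], best_energy=float(best[1]),
                      trace=tuple(trace))
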