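"""Particle swarm optimization over conformation space.

Velocity update per particle and dimension:

    v' = inertia * v + lambda1 * r1 * (p_personal - x) + lambda2 * r2 * (p_global - x)

with r1, r2 fresh uniform(0, 1) draws, followed by component-wise clamping
to [-v_max, v_max]; positions advance by x' = wrap(x + v').  The inertia
weight decays linearly over the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import ABSequence, ValidationError, batch_total_energy, wrap_angle

__all__ = [
    "PSOConfig",
    "Particle",
    "SwarmState",
    "PSOResult",
    "update_velocity",
    "update_position",
    "inertia_at",
    "init_swarm",
    "pso_step",
    "run_pso",
    "has_converged",
]


@dataclass
class PSOConfig:
    """Swarm parameters; defaults follow the benchmark setup
    (260 particles, 800 iterations, learning factors 2.0)."""

    swarm_size: int = 260
    iterations: int = 800
    lambda1: float = 2.0
    lambda2: float = 2.0
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    v_max: float = math.pi
    per_dimension_rand: bool = True
    #: Positions are angles, so the attraction displacements (p - x) are
    #: taken along the shortest arc by default; disable for the plain
    #: Euclidean difference.
    wrap_attraction: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValidationError("swarm_size must be >= 2")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("learning factors must be >= 0")
        for w in (self.inertia_start, self.inertia_end):
            if not 0.0 < w <= 1.0:
                raise ValidationError("inertia weights must lie in (0, 1]")
        if self.v_max <= 0:
            raise ValidationError("v_max must be positive")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


@dataclass
class Particle:
    """Single-particle view: position, velocity and personal best."""

    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_energy: float


@dataclass
class SwarmState:
    """Whole-swarm state stored as (swarm_size, n-2) arrays."""

    positions: np.ndarray
    velocities: np.ndarray
    best_positions: np.ndarray
    best_energies: np.ndarray
    global_best_position: np.ndarray
    global_best_energy: float
    iteration: int = 0

    @property
    def particles(self) -> List[Particle]:
        return [
            Particle(self.positions[i].copy(), self.velocities[i].copy(),
                     self.best_positions[i].copy(), float(self.best_energies[i]))
            for i in range(self.positions.shape[0])
        ]


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_energy: float
    trace: Tuple[float, ...]

    @property
    def iterations_run(self) -> int:
        return len(self.trace)


def update_velocity(particle: Particle, global_best_position: np.ndarray,
                    inertia: float, lambda1: float, lambda2: float,
                    random_pair, v_max: float = math.pi,
                    wrap_attraction: bool = True) -> np.ndarray:
    """One velocity update for a single particle (clamped to +-v_max).

    With ``wrap_attraction`` the personal/global-best displacements are
    measured along the shortest arc of the angle circle, which avoids
    spurious near-2*pi pulls across the +-pi seam.
    """
    gbest = np.asarray(global_best_position, dtype=float)
    if gbest.shape != particle.position.shape:
        raise ValidationError("global best dimension mismatch")
    r1, r2 = random_pair
    d_personal = particle.best_position - particle.position
    d_global = gbest - particle.position
    if wrap_attraction:
        d_personal = np.asarray(wrap_angle(d_personal))
        d_global = np.asarray(wrap_angle(d_global))
    v = (inertia * particle.velocity
         + lambda1 * np.asarray(r1) * d_personal
         + lambda2 * np.asarray(r2) * d_global)
    return np.clip(v, -v_max, v_max)


def update_position(particle: Particle) -> np.ndarray:
    """Advance a particle by its (already updated) velocity, wrapping each
    angle into [-pi, pi)."""
    return np.asarray(wrap_angle(particle.position + particle.velocity))


def inertia_at(iteration: int, config: PSOConfig) -> float:
    """Linearly interpolated inertia weight at a given iteration."""
    cap = max(config.iterations, 1)
    frac = min(max(iteration, 0), cap) / cap
    return config.inertia_start + frac * (config.inertia_end - config.inertia_start)


def init_swarm(sequence: ABSequence, config: PSOConfig,
               rng: np.random.Generator) -> SwarmState:
    """Seeded swarm: positions uniform on [-pi, pi)^(n-2), velocities
    uniform on [-v_max/2, v_max/2]."""
    d = sequence.n - 2
    if d < 1:
        raise ValidationError("sequence must have at least 3 residues")
    m = config.swarm_size
    positions = rng.uniform(-math.pi, math.pi, size=(m, d))
    velocities = rng.uniform(-config.v_max / 2, config.v_max / 2, size=(m, d))
    energies = batch_total_energy(sequence, positions)
    gbest = int(np.argmin(energies))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        best_positions=positions.copy(),
        best_energies=energies.copy(),
        global_best_position=positions[gbest].copy(),
        global_best_energy=float(energies[gbest]),
    )


def pso_step(swarm: SwarmState, sequence: ABSequence, config: PSOConfig,
             rng: np.random.Generator) -> SwarmState:
    """Advance the whole swarm one iteration in place and return it."""
    m, d = swarm.positions.shape
    inertia = inertia_at(swarm.iteration, config)
    shape = (m, d) if config.per_dimension_rand else (m, 1)
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    d_personal = swarm.best_positions - swarm.positions
    d_global = swarm.global_best_position - swarm.positions
    if config.wrap_attraction:
        d_personal = np.asarray(wrap_angle(d_personal))
        d_global = np.asarray(wrap_angle(d_global))
    v = (inertia * swarm.velocities
         + config.lambda1 * r1 * d_personal
         + config.lambda2 * r2 * d_global)
    np.clip(v, -config.v_max, config.v_max, out=v)
    x = np.asarray(wrap_angle(swarm.positions + v))
    energies = batch_total_energy(sequence, x)

    # Diverging conformations: resample the particle within bounds once.
    bad = ~np.isfinite(energies)
    if np.any(bad):
        x[bad] = rng.uniform(-math.pi, math.pi, size=(int(bad.sum()), d))
        v[bad] = 0.0
        energies[bad] = batch_total_energy(sequence, x[bad])

    swarm.positions = x
    swarm.velocities = v
    improved = energies < swarm.best_energies
    swarm.best_positions[improved] = x[improved]
    swarm.best_energies[improved] = energies[improved]
    gbest = int(np.argmin(swarm.best_energies))
    if swarm.best_energies[gbest] < swarm.global_best_energy:
        swarm.global_best_energy = float(swarm.best_energies[gbest])
        swarm.global_best_position = swarm.best_positions[gbest].copy()
    swarm.iteration += 1
    return swarm


def has_converged(trace: Sequence[float], window: int, tolerance: float) -> bool:
    """True when the best energy improved by less than ``tolerance`` over
    the last ``window`` iterations (requires a trace at least that long)."""
    if not len(trace):
        raise ValidationError("trace must be non-empty")
    if len(trace) < window:
        return False
    return (trace[-window] - trace[-1]) < tolerance


def run_pso(sequence: ABSequence, config: PSOConfig, *,
            rng: Optional[np.random.Generator] = None,
            early_stop: bool = False, window: int = 50,
            tolerance: float = 1e-4) -> PSOResult:
    """Run PSO to the iteration cap (or, with ``early_stop``, until the
    convergence window shows no further improvement).  Deterministic for a
    given seed / generator."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    swarm = init_swarm(sequence, config, rng)
    trace: List[float] = []
    for _ in range(config.iterations):
        pso_step(swarm, sequence, config, rng)
        trace.append(swarm.global_best_energy)
        if early_stop and has_converged(trace, window, tolerance):
            break
    return PSOResult(
        best_position=swarm.global_best_position.copy(),
        best_energy=swarm.global_best_energy,
        trace=tuple(trace),
    )
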