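"""Core 2D AB off-lattice chain model.

Sequences over the two-letter alphabet {A, B} (A hydrophobic, B hydrophilic)
are folded on a continuous plane as chains of unit-length bonds.  A
conformation is the vector of signed bend angles at the n-2 interior
residues; the potential energy is the sum of a backbone bending term and a
Lennard-Jones-like non-bonded term over all residue pairs separated by at
least two bonds along the chain:

    E = sum_i E1(alpha_i) + sum_{j >= i+2} E2(r_ij, eta_i, eta_j)

with the Stillinger-type forms

    E1(alpha)          = (1/4) (1 - cos alpha)
    E2(r, eta_i, eta_j) = 4 (r^-12 - C(eta_i, eta_j) r^-6)
    C(eta_i, eta_j)    = (1 + eta_i + eta_j + 5 eta_i eta_j) / 8

so that C is 1 for AA pairs, 1/2 for BB pairs and -1/2 for mixed pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "ValidationError",
    "EnergyDomainError",
    "ABSequence",
    "Conformation",
    "Coordinates2D",
    "EnergyBreakdown",
    "wrap_angle",
    "eta_of",
    "pair_coefficient",
    "build_coordinates",
    "backbone_energy",
    "nonbonded_energy",
    "total_energy",
    "batch_total_energy",
    "fitness",
    "MIN_PAIR_DISTANCE",
]

TWO_PI = 2.0 * math.pi

#: Pair distances below this are treated as a domain error (effectively
#: infinite repulsion); optimizers map the error to +inf fitness.
MIN_PAIR_DISTANCE = 1e-6


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class EnergyDomainError(ValueError):
    """Raised when a conformation brings two residues closer than
    :data:`MIN_PAIR_DISTANCE`, where the pair potential diverges."""


def wrap_angle(x):
    """Wrap an angle (scalar or array) into ``[-pi, pi)``.

    The result is congruent to ``x`` modulo ``2*pi`` and the map is
    idempotent.  NaN or infinite input is rejected.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("wrap_angle requires finite input")
    wrapped = arr - TWO_PI * np.floor((arr + math.pi) / TWO_PI)
    # floor rounding can land exactly on +pi; fold it back.
    wrapped = np.where(wrapped >= math.pi, wrapped - TWO_PI, wrapped)
    if np.isscalar(x) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


class ABSequence:
    """An AB sequence: residue labels over {A, B} with polarity values.

    Parameters
    ----------
    residues:
        String over the alphabet {A, B}; lowercase is accepted and
        normalized to uppercase.
    name:
        Optional record identifier (used for FASTA round-trips).
    """

    def __init__(self, residues: str, name: str = ""):
        residues = str(residues).upper()
        for pos, ch in enumerate(residues):
            if ch not in "AB":
                raise ValidationError(
                    f"invalid residue {ch!r} at position {pos} "
                    f"(0-based); only A and B are allowed"
                )
        self.residues = residues
        self.name = name
        self._pair_cache = None

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def eta(self) -> np.ndarray:
        """Polarity vector: +1 at A (hydrophobic), -1 at B (hydrophilic)."""
        return np.where(np.frombuffer(self.residues.encode(), dtype=np.uint8)
                        == ord("A"), 1.0, -1.0)

    def _pair_terms(self):
        """Index arrays (i, j) with j >= i+2 and the matching C coefficients."""
        if self._pair_cache is None:
            n = self.n
            ii, jj = np.triu_indices(n, k=2)
            eta = self.eta
            ei, ej = eta[ii], eta[jj]
            coeff = (1.0 + ei + ej + 5.0 * ei * ej) / 8.0
            self._pair_cache = (ii, jj, coeff)
        return self._pair_cache

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, ABSequence) and self.residues == other.residues

    def __hash__(self) -> int:
        return hash(self.residues)

    def __repr__(self) -> str:
        return f"ABSequence({self.residues!r})"


def _as_sequence(seq: Union[str, ABSequence]) -> ABSequence:
    return seq if isinstance(seq, ABSequence) else ABSequence(seq)


@dataclass
class Conformation:
    """Bend-angle vector (radians) for the n-2 interior residues."""

    angles: np.ndarray

    def __post_init__(self):
        arr = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if arr.size == 0:
            raise ValidationError("conformation needs at least one bend angle")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("bend angles must be finite")
        if np.any(np.abs(arr) > math.pi):
            raise ValidationError("bend angles must lie in [-pi, pi]")
        self.angles = arr

    @property
    def n(self) -> int:
        """Number of residues in the chain this conformation folds."""
        return self.angles.size + 2


@dataclass
class Coordinates2D:
    """Planar realization of a chain: n points, unit bonds, p1 at the
    origin and p2 at (1, 0)."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must have shape (n, 2)")


@dataclass
class EnergyBreakdown:
    backbone: float
    nonbonded: float

    @property
    def total(self) -> float:
        return self.backbone + self.nonbonded


def eta_of(sequence: Union[str, ABSequence]) -> np.ndarray:
    """Polarity vector of a sequence: +1 per A, -1 per B."""
    return _as_sequence(sequence).eta


def pair_coefficient(eta_i: float, eta_j: float) -> float:
    """Mixing coefficient C of the non-bonded term.

    Returns 1 for two hydrophobic residues, 1/2 for two hydrophilic, and
    -1/2 for a mixed pair; symmetric in its arguments.
    """
    if eta_i not in (1, -1, 1.0, -1.0) or eta_j not in (1, -1, 1.0, -1.0):
        raise ValidationError("polarity values must be +1 or -1")
    return (1.0 + eta_i + eta_j + 5.0 * eta_i * eta_j) / 8.0


def _coerce_angles(conformation) -> np.ndarray:
    if isinstance(conformation, Conformation):
        return conformation.angles
    return Conformation(np.asarray(conformation, dtype=float)).angles


def build_coordinates(conformation) -> Coordinates2D:
    """Realize the planar chain geometry of a conformation.

    The first bond points along +x from the origin; each subsequent bond
    direction is the previous one rotated by the bend angle at the shared
    residue (positive = counter-clockwise).  All bonds have length 1.
    """
    angles = _coerce_angles(conformation)
    directions = np.concatenate([[0.0], np.cumsum(angles)])
    steps = np.column_stack([np.cos(directions), np.sin(directions)])
    points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Coordinates2D(points)


def backbone_energy(conformation) -> float:
    """Bending energy: sum of (1/4)(1 - cos alpha) over the bend angles."""
    angles = _coerce_angles(conformation)
    return float(np.sum(0.25 * (1.0 - np.cos(angles))))


def nonbonded_energy(sequence, coordinates: Coordinates2D) -> float:
    """Pair energy over residues at chain separation >= 2.

    Raises :class:`EnergyDomainError` when any such pair is closer than
    :data:`MIN_PAIR_DISTANCE`.
    """
    seq = _as_sequence(sequence)
    pts = coordinates.points if isinstance(coordinates, Coordinates2D) else np.asarray(coordinates, float)
    if pts.shape[0] != seq.n:
        raise ValidationError(
            f"coordinates have {pts.shape[0]} points but sequence has {seq.n} residues"
        )
    if seq.n < 3:
        raise ValidationError("non-bonded energy needs at least 3 residues")
    ii, jj, coeff = seq._pair_terms()
    diff = pts[jj] - pts[ii]
    r = np.hypot(diff[:, 0], diff[:, 1])
    if np.any(r < MIN_PAIR_DISTANCE):
        k = int(np.argmin(r))
        raise EnergyDomainError(
            f"residues {ii[k]} and {jj[k]} coincide (r = {r[k]:.3e})"
        )
    inv6 = r ** -6
    return float(np.sum(4.0 * (inv6 * inv6 - coeff * inv6)))


def total_energy(sequence, conformation) -> EnergyBreakdown:
    """Full potential energy of (sequence, conformation).

    Pure function of its inputs; ``total = backbone + nonbonded``.
    """
    seq = _as_sequence(sequence)
    angles = _coerce_angles(conformation)
    if angles.size != seq.n - 2:
        raise ValidationError(
            f"sequence of {seq.n} residues needs {seq.n - 2} bend angles, "
            f"got {angles.size}"
        )
    coords = build_coordinates(angles)
    return EnergyBreakdown(
        backbone=backbone_energy(angles),
        nonbonded=nonbonded_energy(seq, coords),
    )


def batch_total_energy(sequence, angle_matrix: np.ndarray) -> np.ndarray:
    """Vectorized total energy for a batch of conformations.

    ``angle_matrix`` has shape (m, n-2); returns an array of m energies.
    Conformations with a diverging pair distance get +inf instead of an
    exception, which is the fitness convention the optimizers rely on.
    """
    seq = _as_sequence(sequence)
    angles = np.atleast_2d(np.asarray(angle_matrix, dtype=float))
    m, d = angles.shape
    if d != seq.n - 2:
        raise ValidationError(
            f"angle matrix has dimension {d}, expected {seq.n - 2}"
        )
    directions = np.concatenate([np.zeros((m, 1)), np.cumsum(angles, axis=1)], axis=1)
    x = np.concatenate([np.zeros((m, 1)), np.cumsum(np.cos(directions), axis=1)], axis=1)
    y = np.concatenate([np.zeros((m, 1)), np.cumsum(np.sin(directions), axis=1)], axis=1)
    ii, jj, coeff = seq._pair_terms()
    r = np.hypot(x[:, jj] - x[:, ii], y[:, jj] - y[:, ii])
    bad = np.any(r < MIN_PAIR_DISTANCE, axis=1)
    r = np.where(r < MIN_PAIR_DISTANCE, 1.0, r)  # placeholder, masked below
    inv6 = r ** -6
    nonbonded = np.sum(4.0 * (inv6 * inv6 - coeff * inv6), axis=1)
    backbone = np.sum(0.25 * (1.0 - np.cos(angles)), axis=1)
    out = backbone + nonbonded
    out[bad] = np.inf
    return out


def fitness(sequence, angles: np.ndarray) -> float:
    """Scalar total energy with +inf (not an exception) on domain errors."""
    return float(batch_total_energy(sequence, np.asarray(angles, float)[None, :])[0])
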