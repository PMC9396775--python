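"""Independent brute-force reference implementations.

Deliberately shares no code with :mod:`abfold.model`: the energy here is a
literal transcription using plain Python loops and :mod:`math`, used by the
test suite to cross-validate the vectorized production implementation, and
the grid minimizer provides an exhaustive baseline on tiny chains.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Sequence, Tuple

__all__ = ["naive_energy", "grid_minimize"]


def _eta(label: str) -> int:
    if label == "A":
        return 1
    if label == "B":
        return -1
    raise ValueError(f"invalid residue {label!r}")


def naive_energy(sequence: str, angles: Sequence[float]) -> float:
    """Total energy by direct double loop; no vectorization, no caching."""
    seq = str(sequence).upper()
    n = len(seq)
    if n < 3:
        raise ValueError("need at least 3 residues")
    if len(angles) != n - 2:
        raise ValueError(f"expected {n - 2} angles, got {len(angles)}")

    # chain geometry: unit bonds, first bond along +x
    xs = [0.0, 1.0]
    ys = [0.0, 0.0]
    direction = 0.0
    for k in range(n - 2):
        direction = direction + angles[k]
        xs.append(xs[-1] + math.cos(direction))
        ys.append(ys[-1] + math.sin(direction))

    energy = 0.0
    for k in range(n - 2):
        energy += 0.25 * (1.0 - math.cos(angles[k]))
    for i in range(n - 2):
        for j in range(i + 2, n):
            r = math.hypot(xs[j] - xs[i], ys[j] - ys[i])
            if r < 1e-6:
                raise ValueError(f"residues {i} and {j} coincide")
            ei, ej = _eta(seq[i]), _eta(seq[j])
            coeff = (1.0 + ei + ej + 5.0 * ei * ej) / 8.0
            energy += 4.0 * (r ** -12 - coeff * r ** -6)
    return energy


def grid_minimize(sequence: str, step: float) -> Tuple[float, List[float]]:
    """Exhaustive minimum over the grid {-pi, -pi+step, ...}^(n-2).

    Refuses chains longer than 6 residues (dimension > 4) to bound cost.
    The grid covers [-pi, pi): both -pi and the last point below +pi are
    included, +pi itself is not (it aliases -pi).
    """
    seq = str(sequence).upper()
    n = len(seq)
    if n > 6:
        raise ValueError(
            f"grid_minimize is limited to n <= 6 residues (got {n}); "
            "the grid grows exponentially in n"
        )
    if n < 3:
        raise ValueError("need at least 3 residues")
    if step <= 0:
        raise ValueError("step must be positive")

    axis = []
    k = 0
    while -math.pi + k * step < math.pi:
        axis.append(-math.pi + k * step)
        k += 1

    best_energy = math.inf
    best_angles: List[float] = []
    for point in itertools.product(axis, repeat=n - 2):
        try:
            e = naive_energy(seq, point)
        except ValueError:
            continue
        if e < best_energy:
            best_energy = e
            best_angles = list(point)
    return best_energy, best_angles
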