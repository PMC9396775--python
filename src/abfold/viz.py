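"""Optional conformation plotting (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from .model import ABSequence, build_coordinates


def plot_conformation(sequence: ABSequence, angles, path: Union[str, Path, None] = None,
                      ax=None, title: Optional[str] = None):
    """Draw the folded chain: backbone line plus residue markers
    (filled = A/hydrophobic, open = B/hydrophilic).  Returns the axes."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = build_coordinates(np.asarray(angles, float)).points
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(pts[:, 0], pts[:, 1], "-", color="0.6", lw=1.5, zorder=1)
    is_a = np.array([r == "A" for r in sequence.residues])
    ax.scatter(pts[is_a, 0], pts[is_a, 1], s=60, c="black", zorder=2, label="A")
    ax.scatter(pts[~is_a, 0], pts[~is_a, 1], s=60, facecolors="white",
               edgecolors="black", zorder=2, label="B")
    ax.set_aspect("equal")
    ax.legend(loc="best", frameon=False)
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
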