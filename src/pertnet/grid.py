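"""Discrete edge-strength grid shared by inference and decimation.

Edge strengths w_ij are restricted to a symmetric 11-value grid
{-1, -0.8, ..., 0.8, 1} with uniform spacing 0.2, including 0 (no edge).
"""

from __future__ import annotations

import numpy as np

#: Ordered edge-value grid. Index 5 is w = 0.
EDGE_GRID: np.ndarray = np.round(np.linspace(-1.0, 1.0, 11), 10)
EDGE_GRID.setflags(write=False)

GRID_SIZE: int = EDGE_GRID.size
ZERO_INDEX: int = int(np.argmin(np.abs(EDGE_GRID)))

#: Indicator delta(w) = 1 iff w != 0 (the L0 complexity term).
NONZERO_MASK: np.ndarray = (EDGE_GRID != 0.0)
NONZERO_MASK.setflags(write=False)


def snap_to_grid(w: float, atol: float = 1e-9) -> float:
    """Return the grid value equal to ``w`` (within ``atol``).

    Raises ValueError if ``w`` is not on the grid.
    """
    idx = int(np.argmin(np.abs(EDGE_GRID - w)))
    if abs(EDGE_GRID[idx] - w) > atol:
        raise ValueError(f"value {w!r} is not on the edge grid")
    return float(EDGE_GRID[idx])


def grid_index(w: float) -> int:
    """Index of grid value ``w`` (must lie on the grid)."""
    snapped = snap_to_grid(w)
    return int(np.argmin(np.abs(EDGE_GRID - snapped)))
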