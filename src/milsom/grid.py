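"""Map lattices: rectangular and hexagonal unit grids.

Units live on a 2-D lattice. Rectangular grids place unit (r, c) at (c, r);
hexagonal grids use the offset-row convention — odd rows shifted half a unit
right, rows compressed by sqrt(3)/2 — so that each interior unit has six
neighbors all at lattice distance exactly 1. Grid-space distances between
unit positions drive the neighborhood kernel and the topographic-error
adjacency test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError

__all__ = ["SOMGrid", "TOPOLOGIES"]

TOPOLOGIES = ("rectangular", "hexagonal")

# adjacency threshold: neighbors sit at grid distance 1 in both topologies;
# 1.01 excludes rectangular diagonals (sqrt 2) while tolerating float error
_ADJACENCY_EPS = 1.01


@dataclass(frozen=True)
class SOMGrid:
    rows: int
    cols: int
    topology: str = "hexagonal"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise InputError("grid must have at least one row and one column")
        if self.topology not in TOPOLOGIES:
            raise InputError(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_index(self, row: int, col: int) -> int:
        return row * self.cols + col

    def unit_coords(self, index: int) -> tuple[int, int]:
        return divmod(index, self.cols)

    @property
    def unit_positions(self) -> np.ndarray:
        """(n_units, 2) grid-space (x, y) positions in row-major unit order."""
        return self._positions()

    def _positions(self) -> np.ndarray:
        cached = getattr(self, "_pos_cache", None)
        if cached is not None:
            return cached
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        x = cc.astype(float)
        y = rr.astype(float)
        if self.topology == "hexagonal":
            x = x + 0.5 * (rr % 2)
            y = y * (np.sqrt(3.0) / 2.0)
        pos = np.column_stack([x.ravel(), y.ravel()])
        object.__setattr__(self, "_pos_cache", pos)
        return pos

    def pairwise_distances(self) -> np.ndarray:
        cached = getattr(self, "_dist_cache", None)
        if cached is None:
            cached = cdist(self._positions(), self._positions())
            object.__setattr__(self, "_dist_cache", cached)
        return cached

    def adjacency(self) -> np.ndarray:
        """Boolean neighbor matrix (grid distance <= ~1), diagonal False."""
        dist = self.pairwise_distances()
        adj = dist <= _ADJACENCY_EPS
        np.fill_diagonal(adj, False)
        return adj

    def neighbor_pairs(self) -> list[tuple[int, int]]:
        """Sorted list of adjacent unit-index pairs (a < b)."""
        adj = self.adjacency()
        a, b = np.nonzero(np.triu(adj, k=1))
        return list(zip(a.tolist(), b.tolist()))
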