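"""Map-quality assessment: quantization error, topographic error, U-matrix.

Quantization error (Qe) — mean Euclidean distance from each record to its
best matching unit — measures mapping precision; the mean (rather than the
sum) makes values comparable across dataset sizes. Topographic error (Te) —
the fraction of records whose first and second BMUs are not grid
neighbors — measures how well the map preserves topology. The U-matrix
lays the inter-unit weight distances out on an expanded lattice so cluster
boundaries show up as ridges of large distance (conventionally rendered
dark) between valleys of similar units (light).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import Codebook
from .dataset import Dataset
from .errors import InputError

__all__ = [
    "QualityReport",
    "quantization_error",
    "topographic_error",
    "u_matrix",
    "component_planes",
    "evaluate_map",
]


def quantization_error(data: Dataset, codebook: Codebook) -> float:
    """Mean distance from each record to its BMU; 0 iff every record sits on a unit."""
    X = data.values
    if X.shape[1] != codebook.d:
        raise InputError("dataset and codebook dimensions differ")
    dist = cdist(X, codebook.weights)
    return float(dist.min(axis=1).mean())


def topographic_error(data: Dataset, codebook: Codebook) -> float:
    """Fraction of records whose two best matching units are not adjacent.

    Ties for either rank resolve to the lowest unit index (stable sort).
    Requires at least two units.
    """
    if codebook.n_units < 2:
        raise InputError("topographic error needs at least two units")
    X = data.values
    if X.shape[1] != codebook.d:
        raise InputError("dataset and codebook dimensions differ")
    dist = cdist(X, codebook.weights)
    order = np.argsort(dist, axis=1, kind="stable")
    first, second = order[:, 0], order[:, 1]
    adj = codebook.grid.adjacency()
    return float(np.mean(~adj[first, second]))


def u_matrix(codebook: Codebook) -> np.ndarray:
    """Unified distance matrix on the expanded (2r-1) x (2c-1) lattice.

    Cells between adjacent units hold the Euclidean distance between their
    weight vectors; unit cells hold the mean of the surrounding between-cells
    (cells with no adjacent between-cell, e.g. a 1x1 map, read 0).
    """
    grid = codebook.grid
    rows, cols = grid.rows, grid.cols
    U = np.full((2 * rows - 1, 2 * cols - 1), np.nan)
    W = codebook.weights
    for a, b in grid.neighbor_pairs():
        ra, ca = grid.unit_coords(a)
        rb, cb = grid.unit_coords(b)
        U[ra + rb, ca + cb] = float(np.linalg.norm(W[a] - W[b]))
    between = ~np.isnan(U)
    # fill unit cells and any holes with the mean of surrounding between-cells
    filled = U.copy()
    for i in range(U.shape[0]):
        for j in range(U.shape[1]):
            if between[i, j]:
                continue
            i0, i1 = max(i - 1, 0), min(i + 2, U.shape[0])
            j0, j1 = max(j - 1, 0), min(j + 2, U.shape[1])
            vals = U[i0:i1, j0:j1][between[i0:i1, j0:j1]]
            filled[i, j] = float(vals.mean()) if vals.size else 0.0
    return filled


def component_planes(codebook: Codebook) -> list[np.ndarray]:
    """One (rows x cols) plane per dimension; stacking them rebuilds the codebook."""
    grid = codebook.grid
    return [
        codebook.weights[:, j].reshape(grid.rows, grid.cols)
        for j in range(codebook.d)
    ]


@dataclass
class QualityReport:
    quantization_error: float
    topographic_error: float
    u_matrix: np.ndarray
    n_records: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.topographic_error <= 1.0:
            raise InputError("topographic error must lie in [0, 1]")
        if np.any(self.u_matrix < 0):
            raise InputError("U-matrix entries must be nonnegative")


def evaluate_map(data: Dataset, codebook: Codebook) -> QualityReport:
    """Bundle Qe, Te and the U-matrix for one dataset/codebook pair."""
    return QualityReport(
        quantization_error=quantization_error(data, codebook),
        topographic_error=topographic_error(data, codebook),
        u_matrix=u_matrix(codebook),
        n_records=data.n,
    )
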