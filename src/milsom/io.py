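"""File I/O for codebooks and derived artifacts (CSV, GeoJSON)."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .core import Codebook
from .dataset import Dataset
from .errors import InputError
from .grid import SOMGrid

__all__ = [
    "write_codebook_csv",
    "read_codebook_csv",
    "write_u_matrix_csv",
    "records_to_geojson",
]


def write_codebook_csv(codebook: Codebook, path, column_names=None) -> None:
    """Write unit_row, unit_col plus one column per dimension.

    Floats are serialized with ``repr`` (shortest round-trip form), so a
    read-back reproduces the weights to full float64 precision.
    """
    grid = codebook.grid
    if column_names is None:
        column_names = [f"w{j + 1}" for j in range(codebook.d)]
    if len(column_names) != codebook.d:
        raise InputError("one column name per dimension required")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["unit_row", "unit_col", "topology", *column_names]
        )
        for idx in range(codebook.n_units):
            r, c = grid.unit_coords(idx)
            writer.writerow(
                [r, c, grid.topology, *[repr(float(v)) for v in codebook.weights[idx]]]
            )


def read_codebook_csv(path) -> Codebook:
    """Inverse of :func:`write_codebook_csv`; exact float64 round trip."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:3] != ["unit_row", "unit_col", "topology"]:
            raise InputError(f"{path}: not a codebook CSV (unexpected header)")
        rows = list(reader)
    if not rows:
        raise InputError(f"{path}: empty codebook")
    coords = np.array([[int(r[0]), int(r[1])] for r in rows])
    topology = rows[0][2]
    grid = SOMGrid(int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1, topology)
    weights = np.empty((grid.n_units, len(header) - 3))
    for r in rows:
        idx = grid.unit_index(int(r[0]), int(r[1]))
        weights[idx] = [float(v) for v in r[3:]]
    return Codebook(weights, grid)


def write_u_matrix_csv(u: np.ndarray, path) -> None:
    np.savetxt(path, u, delimiter=",", fmt="%.17g")


def records_to_geojson(
    data: Dataset, record_labels: np.ndarray, path=None
) -> dict:
    """Point FeatureCollection with a ``cluster`` property per record.

    Requires the dataset to have spatial columns flagged. Non-spatial
    columns are carried along as additional properties.
    """
    if data.spatial_columns is None:
        raise InputError("GeoJSON export needs spatial_columns flagged on the dataset")
    xi, yi = data.spatial_columns
    record_labels = np.asarray(record_labels)
    if record_labels.shape[0] != data.n:
        raise InputError("one label per record required")
    other = [j for j in range(data.d) if j not in (xi, yi)]
    features = []
    for i in range(data.n):
        props = {"cluster": int(record_labels[i])}
        for j in other:
            props[data.column_names[j]] = float(data.values[i, j])
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(data.values[i, xi]), float(data.values[i, yi])],
                },
                "properties": props,
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection
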