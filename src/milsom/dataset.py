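"""Tabular numeric datasets: the n-records x d-dimensions input to SOM training.

A :class:`Dataset` wraps an ``(n, d)`` float matrix with column names and an
optional pair of columns flagged as planar (x, y) coordinates — the layout of
point-referenced epidemiological tables (coordinates, a case/control
indicator, continuous exposure attributes). Mixed-unit columns (meters vs
percentiles) make per-column z-scoring the default preprocessing for
training; :meth:`Dataset.zscore` returns the scaled view together with the
:class:`Scaler` needed to map codebook weights back to original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["Dataset", "Scaler", "read_csv"]


@dataclass(frozen=True)
class Scaler:
    """Per-column affine transform ``(values - mean) / scale``."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.scale

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scale + self.mean


@dataclass
class Dataset:
    """An ``(n, d)`` matrix of finite reals with named columns.

    Parameters
    ----------
    values
        Record-major numeric matrix; coerced to float64.
    column_names
        One label per dimension. Auto-generated ``v1..vd`` when omitted.
    spatial_columns
        Optional ``(x_index, y_index)`` pair flagging planar coordinates,
        used for GeoJSON export of cluster labels.
    """

    values: np.ndarray
    column_names: list[str] = field(default_factory=list)
    spatial_columns: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise InputError("dataset values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise InputError("dataset must contain at least one record and one dimension")
        if not np.all(np.isfinite(self.values)):
            raise InputError("dataset contains non-finite entries (NaN or inf)")
        if not self.column_names:
            self.column_names = [f"v{j + 1}" for j in range(d)]
        if len(self.column_names) != d:
            raise InputError(
                f"{len(self.column_names)} column names for {d} dimensions"
            )
        if self.spatial_columns is not None:
            i, j = self.spatial_columns
            if i == j or not (0 <= i < d and 0 <= j < d):
                raise InputError("spatial_columns must be two distinct valid column indices")
            self.spatial_columns = (int(i), int(j))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def zscore(self) -> tuple["Dataset", Scaler]:
        """Return a per-column standardized copy and the scaler that produced it.

        Constant columns get unit scale so they map to zero rather than NaN.
        """
        mean = self.values.mean(axis=0)
        scale = self.values.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        scaler = Scaler(mean=mean, scale=scale)
        scaled = Dataset(
            values=scaler.transform(self.values),
            column_names=list(self.column_names),
            spatial_columns=self.spatial_columns,
        )
        return scaled, scaler

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def read_csv(
    path,
    delimiter: str = ",",
    spatial_columns: tuple[str, str] | tuple[int, int] | None = None,
) -> Dataset:
    """Load a header-rowed CSV into a :class:`Dataset`.

    Every column must be numeric; a non-numeric column raises
    :class:`InputError` naming the offending column. ``spatial_columns`` may
    be given as column names or integer indices.
    """
    frame = pd.read_csv(path, sep=delimiter)
    if frame.shape[0] < 1:
        raise InputError(f"{path}: no data rows")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any() and not frame[col].isna().any():
            raise InputError(f"column '{col}' is non-numeric; only numeric columns are accepted")
        if frame[col].isna().any():
            raise InputError(f"column '{col}' contains missing values")
        frame[col] = coerced
    idx: tuple[int, int] | None = None
    if spatial_columns is not None:
        resolved = []
        for c in spatial_columns:
            if isinstance(c, str):
                if c not in frame.columns:
                    raise InputError(f"spatial column '{c}' not found in header")
                resolved.append(frame.columns.get_loc(c))
            else:
                resolved.append(int(c))
        idx = (resolved[0], resolved[1])
    return Dataset(
        values=frame.to_numpy(dtype=float),
        column_names=[str(c) for c in frame.columns],
        spatial_columns=idx,
    )
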