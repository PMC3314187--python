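"""Synthetic point-referenced health datasets.

Real clinically acquired geographic tables of the kind this package targets
(e.g. geocoded asthma cases) carry X/Y coordinates, a case-control
indicator, and continuous distance-to-exposure attributes; spatially they
look like a handful of dense clusters over diffuse background. The
generator here emulates exactly that structure so every pipeline stage is
testable end to end with known ground truth: Gaussian spatial clusters
around uniform centers, a case probability elevated inside clusters,
distance-like attributes measured to cluster-specific anchor points, and a
uniform background ("noise") fraction labelled 0.

A second generator produces i.i.d. uniform [0,1]^d records — a dataset with
no organized spatial pattern, the standard null for quantization-error
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset
from .errors import InputError

__all__ = ["MixtureSpec", "generate_spatial_mixture", "generate_noisy_uniform"]

# case probability multiplier for background records relative to cluster members
_BACKGROUND_CASE_FACTOR = 0.2


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of a spatial cluster mixture.

    Defaults describe a city-scale scene: a 1000 x 1000 extent (arbitrary
    planar units, think hundreds of meters per unit), compact clusters
    (spread 30), three distance-like exposure attributes, 70% case
    probability inside clusters, and 10% diffuse background.
    """

    n: int = 2000
    n_clusters: int = 3
    spatial_extent: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    cluster_spread: float = 30.0
    attribute_dims: int = 3
    case_fraction: float = 0.7
    noise_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.n_clusters or self.n_clusters < 1:
            raise InputError("need n >= n_clusters >= 1")
        if not (0.0 <= self.case_fraction <= 1.0 and 0.0 <= self.noise_fraction <= 1.0):
            raise InputError("case_fraction and noise_fraction must lie in [0, 1]")
        if self.cluster_spread <= 0:
            raise InputError("cluster_spread must be positive")
        if self.attribute_dims < 0:
            raise InputError("attribute_dims must be nonnegative")
        x0, y0, x1, y1 = self.spatial_extent
        if x1 <= x0 or y1 <= y0:
            raise InputError("spatial extent must have positive area")


def generate_spatial_mixture(spec: MixtureSpec) -> tuple[Dataset, np.ndarray]:
    """Draw the mixture; returns (dataset, ground-truth labels).

    Labels are 1..n_clusters for cluster members and 0 for background.
    Columns: x, y, case_control, dist_1..dist_attribute_dims; the (x, y)
    pair is flagged as spatial. Deterministic per seed; record order is
    shuffled so cluster membership is not positional.
    """
    rng = np.random.default_rng(spec.seed)
    x0, y0, x1, y1 = spec.spatial_extent
    k = spec.n_clusters

    n_noise = int(round(spec.noise_fraction * spec.n))
    n_members = spec.n - n_noise
    if n_members < k and spec.noise_fraction < 1.0:
        n_noise = spec.n - k
        n_members = k
    per_cluster = np.full(k, n_members // k)
    per_cluster[: n_members % k] += 1

    centers = np.column_stack(
        [rng.uniform(x0, x1, size=k), rng.uniform(y0, y1, size=k)]
    )
    # one anchor per (cluster-or-background, attribute): the exposure source
    # a record's distance attribute is measured to
    anchors = np.stack(
        [
            np.column_stack(
                [
                    rng.uniform(x0, x1, size=spec.attribute_dims),
                    rng.uniform(y0, y1, size=spec.attribute_dims),
                ]
            )
            for _ in range(k + 1)
        ]
    )  # (k+1, attribute_dims, 2); index 0 = background

    labels = np.concatenate(
        [np.full(c, j + 1) for j, c in enumerate(per_cluster)]
        + [np.zeros(n_noise, dtype=int)]
    ).astype(int)
    pos = np.empty((spec.n, 2))
    member_mask = labels > 0
    if member_mask.any():
        pos[member_mask] = centers[labels[member_mask] - 1] + rng.normal(
            0.0, spec.cluster_spread, size=(int(member_mask.sum()), 2)
        )
    if n_noise:
        pos[~member_mask] = np.column_stack(
            [rng.uniform(x0, x1, size=n_noise), rng.uniform(y0, y1, size=n_noise)]
        )

    p_case = np.where(
        member_mask, spec.case_fraction, _BACKGROUND_CASE_FACTOR * spec.case_fraction
    )
    case = (rng.random(spec.n) < p_case).astype(float)

    attrs = np.empty((spec.n, spec.attribute_dims))
    attr_noise_sd = spec.cluster_spread / 2.0
    for j in range(spec.attribute_dims):
        anchor_xy = anchors[labels, j]  # label 0 -> background anchors
        attrs[:, j] = np.linalg.norm(pos - anchor_xy, axis=1) + rng.normal(
            0.0, attr_noise_sd, size=spec.n
        )
    attrs = np.abs(attrs)  # distances are nonnegative

    values = np.column_stack([pos, case, attrs])
    order = rng.permutation(spec.n)
    names = ["x", "y", "case_control"] + [
        f"dist_{j + 1}" for j in range(spec.attribute_dims)
    ]
    dataset = Dataset(values[order], column_names=names, spatial_columns=(0, 1))
    return dataset, labels[order]


def generate_noisy_uniform(n: int, d: int, seed: int = 0) -> Dataset:
    """i.i.d. uniform [0, 1]^d records with no organized spatial pattern."""
    if n < 1 or d < 1:
        raise InputError("need n >= 1 and d >= 1")
    rng = np.random.default_rng(seed)
    return Dataset(rng.random((n, d)), column_names=[f"v{j + 1}" for j in range(d)])
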