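"""Standard Kohonen SOM primitives.

The codebook, winner (BMU) search, neighborhood kernels, the linear decay
schedule for learning rate and radius, and the classical proportional
update

    w_i(t+1) = w_i(t) + alpha(t) h_ci(t) [x_k(t) - w_i(t)]

which the PID-controlled variant both extends and must reduce to when its
extra gains are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset, Scaler
from .errors import InputError
from .grid import SOMGrid

__all__ = [
    "Codebook",
    "Phase",
    "TrainingSchedule",
    "TrainedModel",
    "EpochRecord",
    "decay",
    "default_schedule",
    "init_codebook",
    "find_bmu",
    "neighborhood_weights",
    "kohonen_update",
    "train_standard_som",
]

KERNELS = ("gaussian", "bubble")


@dataclass
class Codebook:
    """Weight vectors of all map units, row-major in unit order."""

    weights: np.ndarray  # (n_units, d)
    grid: SOMGrid

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.weights.shape[0] != self.grid.n_units:
            raise InputError(
                f"codebook has {self.weights.shape[0]} weight vectors "
                f"for a grid of {self.grid.n_units} units"
            )
        if not np.all(np.isfinite(self.weights)):
            raise InputError("codebook contains non-finite weights")

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "Codebook":
        return Codebook(self.weights.copy(), self.grid)


@dataclass(frozen=True)
class Phase:
    """One training phase: epoch count plus linear alpha/radius ramps."""

    epochs: int
    alpha_start: float
    alpha_end: float
    radius_start: float
    radius_end: float

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InputError("phase must run at least one epoch")
        for a in (self.alpha_start, self.alpha_end):
            if not 0.0 <= a <= 1.0:
                raise InputError("learning rates must lie in [0, 1]")
        if self.alpha_start < self.alpha_end:
            raise InputError("alpha must not increase within a phase")
        if self.radius_start < 0 or self.radius_end < 0:
            raise InputError("radii must be nonnegative")
        if self.radius_start < self.radius_end:
            raise InputError("radius must not increase within a phase")


@dataclass(frozen=True)
class TrainingSchedule:
    phases: tuple[Phase, ...]
    kernel: str = "gaussian"
    radius_floor: float = 1.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise InputError("schedule needs at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))
        if self.kernel not in KERNELS:
            raise InputError(f"kernel must be one of {KERNELS}")
        if self.radius_floor < 0:
            raise InputError("radius_floor must be nonnegative")

    @property
    def total_epochs(self) -> int:
        return sum(p.epochs for p in self.phases)


def default_schedule(
    grid: SOMGrid,
    rough_epochs: int = 10,
    fine_epochs: int = 20,
    kernel: str = "gaussian",
) -> TrainingSchedule:
    """Two-phase rough/fine schedule derived from the map size.

    The rough phase starts at learning rate 0.5 with radius max(rows, cols)/4;
    the fine phase starts at 0.05 with a quarter of the rough radius. Both
    ramps decay linearly, the radius is clamped at the floor of 1 during
    training. For a 20x20 map this yields rough radius 5 and fine radius 1.25.
    """
    rough_radius = max(max(grid.rows, grid.cols) / 4.0, 1.0)
    fine_radius = max(rough_radius / 4.0, 1.0)
    return TrainingSchedule(
        phases=(
            Phase(rough_epochs, 0.5, 0.05, rough_radius, fine_radius),
            Phase(fine_epochs, 0.05, 0.0, fine_radius, 1.0),
        ),
        kernel=kernel,
        radius_floor=1.0,
    )


def decay(step: int, total_steps: int, start: float, end: float) -> float:
    """Linear ramp from ``start`` (step 0) to ``end`` (step == total_steps)."""
    if total_steps < 1:
        raise InputError("total_steps must be >= 1")
    if not 0 <= step <= total_steps:
        raise InputError(f"step {step} outside [0, {total_steps}]")
    f = step / total_steps
    return start * (1.0 - f) + end * f  # endpoint-exact linear interpolation


def init_codebook(
    data: Dataset,
    grid: SOMGrid,
    method: str = "random_sample",
    seed: int = 0,
) -> Codebook:
    """Seed-deterministic codebook initialization inside the data envelope.

    ``random_sample`` draws unit weights from the data records (with
    replacement); ``uniform_span`` draws each coordinate uniformly within its
    column's [min, max] range.
    """
    rng = np.random.default_rng(seed)
    return Codebook(_init_weights(data.values, grid, method, rng), grid)


def _init_weights(X: np.ndarray, grid: SOMGrid, method: str, rng: np.random.Generator) -> np.ndarray:
    if X.shape[0] < 1:
        raise InputError("cannot initialize from an empty dataset")
    if method == "random_sample":
        idx = rng.integers(0, X.shape[0], size=grid.n_units)
        return X[idx].copy()
    if method == "uniform_span":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        return rng.uniform(lo, hi, size=(grid.n_units, X.shape[1]))
    raise InputError(f"unknown init method {method!r}")


def find_bmu(x: np.ndarray, codebook: Codebook) -> tuple[int, float]:
    """Best matching unit: argmin over units of ||x - w_i||, lowest index on ties."""
    x = np.asarray(x, dtype=float)
    if x.shape != (codebook.d,):
        raise InputError(f"input has shape {x.shape}, codebook dimension is {codebook.d}")
    diff = codebook.weights - x
    sq = np.einsum("ij,ij->i", diff, diff)
    bmu = int(np.argmin(sq))  # np.argmin returns the first (lowest) index on ties
    return bmu, float(np.sqrt(sq[bmu]))


def neighborhood_weights(
    grid: SOMGrid, bmu: int, radius: float, kernel: str = "gaussian"
) -> np.ndarray:
    """Per-unit kernel weights h_ci in [0, 1] centered at the BMU.

    gaussian: exp(-g^2 / (2 radius^2)); bubble: indicator of g <= radius,
    with g the grid-space distance from the BMU.
    """
    if radius <= 0:
        raise InputError("radius must be positive")
    if kernel not in KERNELS:
        raise InputError(f"kernel must be one of {KERNELS}")
    g = grid.pairwise_distances()[bmu]
    if kernel == "gaussian":
        return np.exp(-(g**2) / (2.0 * radius**2))
    return (g <= radius).astype(float)


def kohonen_update(
    codebook: Codebook,
    x: np.ndarray,
    bmu: int,
    alpha: float,
    h: np.ndarray,
) -> Codebook:
    """Classical proportional update, in place; units with h == 0 untouched."""
    x = np.asarray(x, dtype=float)
    if x.shape != (codebook.d,):
        raise InputError("input dimension mismatch")
    if not 0.0 <= alpha <= 1.0:
        raise InputError("alpha must lie in [0, 1]")
    h = np.asarray(h, dtype=float)
    if h.shape != (codebook.n_units,):
        raise InputError("kernel weight vector length mismatch")
    active = h > 0
    W = codebook.weights
    W[active] += (alpha * h[active])[:, None] * (x - W[active])
    return codebook


@dataclass
class EpochRecord:
    epoch: int
    qe: float
    alpha: float
    radius: float
    a1_eff: float = 0.0
    a2_eff: float = 0.0


@dataclass
class TrainedModel:
    """A trained map plus the provenance needed to reproduce and interpret it.

    ``codebook`` lives in the (optionally z-scored) training space; when
    ``scaler`` is set, :meth:`codebook_original_units` maps weights back.
    """

    codebook: Codebook
    schedule: TrainingSchedule
    history: list[EpochRecord]
    seed: int
    algorithm: str
    scaler: Scaler | None = None
    gains: "object | None" = None  # PIDGains for algorithm == "milsom"

    def __post_init__(self) -> None:
        if len(self.history) != self.schedule.total_epochs:
            raise InputError("history length must equal total epochs trained")
        if any(rec.qe < 0 for rec in self.history):
            raise InputError("quantization errors must be nonnegative")

    @property
    def final_qe(self) -> float:
        return self.history[-1].qe

    def qe_history(self) -> np.ndarray:
        return np.array([rec.qe for rec in self.history])

    def codebook_original_units(self) -> Codebook:
        if self.scaler is None:
            return self.codebook.copy()
        return Codebook(self.scaler.inverse(self.codebook.weights), self.codebook.grid)


def train_standard_som(
    data: Dataset,
    grid: SOMGrid,
    schedule: TrainingSchedule,
    seed: int = 0,
    normalize: bool = True,
    init: str = "random_sample",
) -> TrainedModel:
    """Online Kohonen training: seeded per-epoch shuffles, linear per-step decay.

    See :func:`milsom.training.run_training` for the loop shared with the
    PID-controlled variant.
    """
    from .training import run_training

    return run_training(
        data, grid, schedule, seed, gains=None, normalize=normalize, init=init
    )
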