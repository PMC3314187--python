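"""The online training loop shared by the standard SOM and MIL-SOM.

One loop serves both algorithms so the zero-gain reduction (a1 = a2 = 0
reproduces Kohonen training exactly) holds by construction: record order,
schedules, initialization and winner search are literally the same code,
and only the per-presentation update differs.

Per presentation: alpha and radius follow a linear ramp over the phase's
step count (epochs x records), the radius clamped at the schedule's floor;
records are visited in a fresh seeded shuffle each epoch; the update
touches only units inside the radius-defined neighborhood set N_c(t) (the
update rule's explicit second branch), with the kernel shaping weights
within it; per-epoch quantization error is appended to the history.
Controller state (MIL-SOM only) is reset at phase boundaries.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    Codebook,
    EpochRecord,
    TrainedModel,
    TrainingSchedule,
    _init_weights,
    decay,
)
from .dataset import Dataset
from .grid import SOMGrid
from .pid import PIDGains, PIDState, default_windup_cap, milsom_update

__all__ = ["run_training"]


def run_training(
    data: Dataset,
    grid: SOMGrid,
    schedule: TrainingSchedule,
    seed: int = 0,
    gains: PIDGains | None = None,
    windup_cap=None,
    normalize: bool = True,
    init: str = "random_sample",
) -> TrainedModel:
    """Train a map; ``gains=None`` selects the classical proportional update.

    Returns a :class:`TrainedModel` whose codebook lives in the (optionally
    z-scored) training space, with the scaler recorded for mapping back.
    Deterministic given (data, grid, schedule, seed, gains).
    """
    scaler = None
    if normalize:
        scaled, scaler = data.zscore()
        X = scaled.values
    else:
        X = data.values
    n, d = X.shape
    if grid.n_units > 4 * n:
        warnings.warn(
            f"grid of {grid.n_units} units is large for {n} records; "
            "many units will interpolate rather than quantize",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    codebook = Codebook(_init_weights(X, grid, init, rng), grid)
    grid_dist = grid.pairwise_distances()
    gaussian = schedule.kernel == "gaussian"

    state = None
    if gains is not None:
        if windup_cap is None:
            windup_cap = default_windup_cap(X)
        state = PIDState(grid.n_units, d, windup_cap=windup_cap)

    history: list[EpochRecord] = []
    W = codebook.weights
    step = 0
    epoch_index = 0
    for phase in schedule.phases:
        if state is not None:
            state.reset(start_step=step)  # alpha/radius change regime at phase boundaries
        total = phase.epochs * n
        s = 0
        for _ in range(phase.epochs):
            order = rng.permutation(n)
            alpha = radius = 0.0
            for k in order:
                alpha = decay(s, total, phase.alpha_start, phase.alpha_end)
                radius = decay(s, total, phase.radius_start, phase.radius_end)
                if schedule.radius_floor > 0:
                    radius = max(radius, schedule.radius_floor)
                x = X[k]
                diff = W - x
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                g = grid_dist[bmu]
                # the update rule's two branches: units outside the
                # radius-defined neighborhood set N_c(t) are not updated
                members = g <= radius
                if gaussian:
                    h = np.where(members, np.exp(-(g**2) / (2.0 * radius**2)), 0.0)
                else:
                    h = members.astype(float)
                if state is None:
                    active = h > 0
                    W[active] += (alpha * h[active])[:, None] * (x - W[active])
                else:
                    milsom_update(codebook, state, x, bmu, step, alpha, h, gains)
                s += 1
                step += 1
            history.append(
                EpochRecord(
                    epoch=epoch_index,
                    qe=_qe(X, W),
                    alpha=alpha,
                    radius=radius,
                    a1_eff=alpha * gains.a1 if gains is not None else 0.0,
                    a2_eff=alpha * gains.a2 if gains is not None else 0.0,
                )
            )
            epoch_index += 1

    return TrainedModel(
        codebook=codebook,
        schedule=schedule,
        history=history,
        seed=seed,
        algorithm="standard" if gains is None else "milsom",
        scaler=scaler,
        gains=gains,
    )


def _qe(X: np.ndarray, W: np.ndarray) -> float:
    """Mean distance to the nearest unit, blocked to bound memory."""
    total = 0.0
    block = max(1, int(2_000_000 // max(W.shape[0], 1)))
    for start in range(0, X.shape[0], block):
        xb = X[start : start + block]
        sq = (
            np.einsum("ij,ij->i", xb, xb)[:, None]
            - 2.0 * xb @ W.T
            + np.einsum("ij,ij->i", W, W)[None, :]
        )
        total += np.sqrt(np.maximum(sq.min(axis=1), 0.0)).sum()
    return float(total / X.shape[0])
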