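"""PID-controlled weight updates: the MIL-SOM learning rule.

Kohonen's update corrects each in-neighborhood unit by the proportional
error e_i(t) = x_k(t) - w_i(t) alone. Here the correction is a full
proportional-integral-derivative control signal

    u_i(t) = e_i(t) + a1 * de_i(t)/dt + a2 * Int e_i(t) dt
    w_i(t+1) = w_i(t) + alpha(t) h_ci(t) u_i(t)

equivalently w_i += h_ci [alpha e_i + alpha1 de_i/dt + alpha2 Int e_i] with
alpha1 = alpha * a1 and alpha2 = alpha * a2. The derivative term damps
oscillation of the weight trajectory; the integral term folds the unit's
accumulated error history into the step, accelerating convergence early in
training. Both gains nonnegative; a1 = a2 = 0 recovers the standard SOM
update exactly.

Discretization: the derivative is a backward difference against the unit's
error at its previous update, divided by the elapsed step count (zero when
the unit has no history); the integral is taken over the single window
between the unit's consecutive updates — rectangle rule, e * elapsed-steps
(elapsed 1 on a unit's first update) — element-wise clamped to +-windup_cap
when a cap is set, which bounds the catch-up kick a long-idle unit receives
(anti-windup). Both terms vanish as the error does, matching the controller
rationale: the derivative damps oscillation of the weight trajectory, and
the integral lets rarely-updated units make up the corrections the decayed
learning rate would otherwise forfeit. State is keyed per unit and advances
only when the unit falls inside the update neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Codebook, TrainedModel, TrainingSchedule
from .dataset import Dataset
from .errors import InputError, StateError
from .grid import SOMGrid

__all__ = [
    "PIDGains",
    "PIDState",
    "compute_error",
    "pid_signal",
    "milsom_update",
    "train_milsom",
    "default_windup_cap",
]


@dataclass(frozen=True)
class PIDGains:
    """Derivative gain a1 and integral gain a2 (proportional gain is alpha)."""

    a1: float = 0.2
    a2: float = 0.05

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise InputError("PID gains must be nonnegative")


class PIDState:
    """Per-unit controller memory: previous error, last integral term, timing.

    ``windup_cap`` may be a positive scalar or a per-dimension array; the
    integral term is clamped element-wise to [-cap, +cap].
    """

    def __init__(self, n_units: int, d: int, windup_cap=None):
        if windup_cap is not None:
            cap = np.asarray(windup_cap, dtype=float)
            if np.any(cap <= 0):
                raise InputError("windup_cap must be positive")
            windup_cap = cap
        self.n_units = n_units
        self.d = d
        self.windup_cap = windup_cap
        self.reset()

    def reset(self, start_step: int = 0) -> None:
        """Wipe controller memory; the controller re-engages at ``start_step``.

        A unit's first integral window after a reset spans back to the
        engagement point (clamped by the windup cap), so units the shrinking
        neighborhood reaches late receive a bounded catch-up correction.
        """
        self.prev_error = np.zeros((self.n_units, self.d))
        self.integral = np.zeros((self.n_units, self.d))
        self.last_control = np.zeros((self.n_units, self.d))
        self.last_step = np.full(self.n_units, int(start_step) - 1, dtype=np.int64)
        self.has_history = np.zeros(self.n_units, dtype=bool)

    def signal(
        self, e: np.ndarray, units: np.ndarray, step: int, gains: PIDGains
    ) -> np.ndarray:
        """Control signals for several units at once; advances their state.

        ``e`` is (len(units), d): each unit's current error. Requires
        ``step`` strictly after each unit's last update.
        """
        units = np.asarray(units, dtype=int)
        e = np.atleast_2d(np.asarray(e, dtype=float))
        if e.shape != (units.size, self.d):
            raise InputError("error block shape does not match unit list / dimension")
        hist = self.has_history[units]
        if np.any(self.last_step[units][hist] >= step):
            raise StateError("step must be strictly greater than each unit's last update step")
        elapsed = (step - self.last_step[units]).astype(float)
        deriv = np.zeros_like(e)
        if np.any(hist):
            deriv[hist] = (e[hist] - self.prev_error[units][hist]) / elapsed[hist, None]
        integ = e * elapsed[:, None]  # rectangle rule over the inter-update window
        if self.windup_cap is not None:
            integ = np.clip(integ, -self.windup_cap, self.windup_cap)
        u = e + gains.a1 * deriv + gains.a2 * integ
        self.prev_error[units] = e
        self.integral[units] = integ
        self.last_step[units] = step
        self.last_control[units] = u
        self.has_history[units] = True
        return u


def compute_error(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Tracking error e = x - w, element-wise."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise InputError(f"shape mismatch: {x.shape} vs {w.shape}")
    return x - w


def pid_signal(
    e: np.ndarray, unit: int, step: int, state: PIDState, gains: PIDGains
) -> np.ndarray:
    """Single-unit control signal u = e + a1 de/dt + a2 Int e; advances state."""
    return state.signal(np.asarray(e, dtype=float)[None, :], np.array([unit]), step, gains)[0]


def milsom_update(
    codebook: Codebook,
    state: PIDState,
    x: np.ndarray,
    bmu: int,
    step: int,
    alpha: float,
    h: np.ndarray,
    gains: PIDGains,
) -> Codebook:
    """One PID-controlled presentation, in place.

    Every unit with h_i > 0 computes its own error against x, obtains its
    control signal, and moves by alpha * h_i * u_i. Units outside the
    neighborhood (h_i == 0) are untouched and their controller state does
    not advance.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (codebook.d,):
        raise InputError("input dimension mismatch")
    if not 0.0 <= alpha <= 1.0:
        raise InputError("alpha must lie in [0, 1]")
    h = np.asarray(h, dtype=float)
    if h.shape != (codebook.n_units,):
        raise InputError("kernel weight vector length mismatch")
    active = np.nonzero(h > 0)[0]
    if active.size == 0:
        return codebook
    W = codebook.weights
    e = x - W[active]
    u = state.signal(e, active, step, gains)
    W[active] += (alpha * h[active])[:, None] * u
    return codebook


def default_windup_cap(X: np.ndarray) -> np.ndarray:
    """Anti-windup clamp: 10x the per-column data range (floored at 1)."""
    span = X.max(axis=0) - X.min(axis=0)
    return 10.0 * np.maximum(span, 0.1)


def train_milsom(
    data: Dataset,
    grid: SOMGrid,
    schedule: TrainingSchedule,
    gains: PIDGains | None = None,
    seed: int = 0,
    normalize: bool = True,
    windup_cap=None,
    init: str = "random_sample",
) -> TrainedModel:
    """PID-controlled training with the same loop structure as the standard SOM.

    Effective derivative/integral rates decay proportionally with alpha(t)
    (alpha1 = alpha * a1, alpha2 = alpha * a2); controller state is reset at
    phase boundaries, where alpha and radius change regime discontinuously.
    With gains (0, 0) the result is element-wise identical to
    :func:`milsom.core.train_standard_som`.
    """
    from .training import run_training

    if gains is None:
        gains = PIDGains()
    return run_training(
        data,
        grid,
        schedule,
        seed,
        gains=gains,
        windup_cap=windup_cap,
        normalize=normalize,
        init=init,
    )
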