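import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milsom import (
    Dataset,
    InputError,
    PIDGains,
    PIDState,
    Phase,
    SOMGrid,
    StateError,
    TrainingSchedule,
    compute_error,
    kohonen_update,
    milsom_update,
    pid_signal,
    train_milsom,
    train_standard_som,
)

from conftest import make_codebook


class TestComputeError:
    def test_zero_at_convergence(self):
        w = np.array([1.0, 2.0])
        assert np.array_equal(compute_error(w, w), np.zeros(2))

    def test_subtraction(self):
        assert np.array_equal(
            compute_error(np.array([1.0, 2.0]), np.array([0.0, 1.0])), np.array([1.0, 1.0])
        )

    def test_matches_scalar_loop(self, rng):
        x, w = rng.normal(size=5), rng.normal(size=5)
        expected = np.array([x[j] - w[j] for j in range(5)])
        assert np.array_equal(compute_error(x, w), expected)

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            compute_error(np.zeros(2), np.zeros(3))


class TestPidSignal:
    def test_zero_gains_pass_error_through(self, rng):
        state = PIDState(4, 3)
        e = rng.normal(size=3)
        u = pid_signal(e, unit=2, step=5, state=state, gains=PIDGains(0.0, 0.0))
        assert np.array_equal(u, e)

    def test_first_update_has_zero_derivative(self):
        state = PIDState(2, 1)
        e = np.array([3.0])
        u = pid_signal(e, 0, step=0, state=state, gains=PIDGains(a1=10.0, a2=0.0))
        assert np.array_equal(u, e)  # derivative term absent without history

    def test_hand_unrolled_three_step_recurrence(self):
        # consecutive updates of one unit; derivative = backward difference,
        # integral = error x elapsed inter-update window (here 1 step)
        a1, a2 = 1.0, 1.0
        state = PIDState(1, 1)
        gains = PIDGains(a1, a2)
        errors = [2.0, 3.0, -1.0]
        expected = [
            2.0 + 0.0 + a2 * 2.0,                    # no history yet
            3.0 + a1 * (3.0 - 2.0) + a2 * 3.0,
            -1.0 + a1 * (-1.0 - 3.0) + a2 * -1.0,
        ]
        for t, (e, want) in enumerate(zip(errors, expected)):
            u = pid_signal(np.array([e]), 0, step=t, state=state, gains=gains)
            assert u[0] == pytest.approx(want)

    def test_idle_gap_stretches_window_and_divides_difference(self):
        state = PIDState(1, 1)
        gains = PIDGains(1.0, 1.0)
        pid_signal(np.array([2.0]), 0, step=0, state=state, gains=gains)
        u = pid_signal(np.array([4.0]), 0, step=5, state=state, gains=gains)
        # derivative (4-2)/5, integral 4*5
        assert u[0] == pytest.approx(4.0 + (4.0 - 2.0) / 5.0 + 4.0 * 5.0)

    def test_windup_cap_clamps_integral_term(self):
        state = PIDState(1, 1, windup_cap=3.0)
        gains = PIDGains(0.0, 1.0)
        pid_signal(np.array([1.0]), 0, step=0, state=state, gains=gains)
        u = pid_signal(np.array([2.0]), 0, step=10, state=state, gains=gains)
        assert u[0] == pytest.approx(2.0 + 3.0)  # 2*10 clamped to cap

    def test_non_monotone_step_rejected(self):
        state = PIDState(1, 2)
        gains = PIDGains()
        pid_signal(np.zeros(2), 0, step=4, state=state, gains=gains)
        with pytest.raises(StateError):
            pid_signal(np.zeros(2), 0, step=4, state=state, gains=gains)

    def test_untouched_units_keep_empty_state(self):
        state = PIDState(3, 2)
        pid_signal(np.ones(2), 1, step=0, state=state, gains=PIDGains())
        assert not state.has_history[0] and not state.has_history[2]
        assert np.array_equal(state.integral[0], np.zeros(2))


class TestMilsomUpdate:
    def test_zero_gains_reduce_to_kohonen(self, rng):
        cb_a = make_codebook(rng.normal(size=(6, 2)), 2, 3)
        cb_b = make_codebook(cb_a.weights.copy(), 2, 3)
        x = rng.normal(size=2)
        h = rng.random(6)
        kohonen_update(cb_a, x, 0, 0.4, h)
        milsom_update(cb_b, PIDState(6, 2), x, 0, 0, 0.4, h, PIDGains(0.0, 0.0))
        assert np.array_equal(cb_a.weights, cb_b.weights)

    def test_zero_alpha_freezes_weights_but_advances_history(self, rng):
        cb = make_codebook(rng.normal(size=(4, 2)), 2, 2)
        before = cb.weights.copy()
        state = PIDState(4, 2)
        h = np.array([1.0, 0.5, 0.0, 0.0])
        milsom_update(cb, state, rng.normal(size=2), 0, 0, 0.0, h, PIDGains())
        assert np.array_equal(cb.weights, before)
        assert state.has_history[0] and state.has_history[1]
        assert not state.has_history[2] and not state.has_history[3]

    def test_single_unit_scripted_trajectory(self):
        # hand-computed recurrence for one 1-d unit, h = 1, alpha fixed
        alpha, a1, a2 = 0.5, 0.3, 0.1
        xs = [1.0, 0.2, -0.4]
        w = 0.0
        prev_e = None
        expected = []
        for x in xs:
            e = x - w
            deriv = 0.0 if prev_e is None else e - prev_e
            u = e + a1 * deriv + a2 * e
            w = w + alpha * u
            prev_e = e
            expected.append(w)
        cb = make_codebook([[0.0]], 1, 1)
        state = PIDState(1, 1)
        for t, x in enumerate(xs):
            milsom_update(cb, state, np.array([x]), 0, t, alpha, np.ones(1), PIDGains(a1, a2))
            assert cb.weights[0, 0] == pytest.approx(expected[t], rel=1e-12)


def _schedule(epochs=(2, 2)):
    return TrainingSchedule(
        phases=(
            Phase(epochs[0], 0.5, 0.1, 2.5, 1.0),
            Phase(epochs[1], 0.1, 0.0, 1.0, 1.0),
        ),
    )


class TestTrainMilsom:
    def test_zero_gain_training_equals_standard(self, small_dataset):
        grid = SOMGrid(3, 3)
        std = train_standard_som(small_dataset, grid, _schedule(), seed=5)
        mil = train_milsom(small_dataset, grid, _schedule(), gains=PIDGains(0.0, 0.0), seed=5)
        assert np.array_equal(std.codebook.weights, mil.codebook.weights)
        assert std.qe_history().tolist() == mil.qe_history().tolist()

    def test_deterministic(self, small_dataset):
        grid = SOMGrid(2, 4)
        a = train_milsom(small_dataset, grid, _schedule(), gains=PIDGains(), seed=8)
        b = train_milsom(small_dataset, grid, _schedule(), gains=PIDGains(), seed=8)
        assert np.array_equal(a.codebook.weights, b.codebook.weights)

    def test_history_records_effective_gains_decaying_with_alpha(self, small_dataset):
        grid = SOMGrid(2, 2)
        model = train_milsom(small_dataset, grid, _schedule(), gains=PIDGains(0.2, 0.05), seed=0)
        recs = model.history
        assert all(r.a1_eff == pytest.approx(r.alpha * 0.2) for r in recs)
        assert all(r.a2_eff == pytest.approx(r.alpha * 0.05) for r in recs)
        assert recs[-1].a1_eff <= recs[0].a1_eff

    def test_negative_gains_rejected(self):
        with pytest.raises(InputError):
            PIDGains(-0.1, 0.0)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_reduction_property_random_instances(seed):
    """Zero gains make every MIL-SOM run equal its standard counterpart."""
    rng = np.random.default_rng(seed)
    data = Dataset(rng.normal(size=(int(rng.integers(5, 20)), int(rng.integers(1, 4)))))
    grid = SOMGrid(int(rng.integers(1, 4)), int(rng.integers(1, 4)))
    kernel = "gaussian" if rng.random() < 0.5 else "bubble"
    sched = TrainingSchedule(
        phases=(Phase(int(rng.integers(1, 3)), 0.6, 0.1, 2.0, 1.0),), kernel=kernel
    )
    run_seed = int(rng.integers(0, 2**31))
    std = train_standard_som(data, grid, sched, seed=run_seed, normalize=False)
    mil = train_milsom(
        data, grid, sched, gains=PIDGains(0.0, 0.0), seed=run_seed, normalize=False
    )
    assert np.array_equal(std.codebook.weights, mil.codebook.weights)
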