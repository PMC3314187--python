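import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milsom import (
    Dataset,
    InputError,
    Phase,
    SOMGrid,
    TrainingSchedule,
    decay,
    default_schedule,
    find_bmu,
    init_codebook,
    kohonen_update,
    neighborhood_weights,
    train_standard_som,
)
from milsom.synthetic import MixtureSpec, generate_spatial_mixture

from conftest import make_codebook


class TestInitCodebook:
    def test_single_record_sampling_replicates_it(self):
        record = np.array([[2.0, -1.0, 0.5]])
        cb = init_codebook(Dataset(record), SOMGrid(2, 2), "random_sample", seed=0)
        assert np.array_equal(cb.weights, np.repeat(record, 4, axis=0))

    def test_deterministic_per_seed(self, small_dataset):
        a = init_codebook(small_dataset, SOMGrid(3, 3), "uniform_span", seed=7)
        b = init_codebook(small_dataset, SOMGrid(3, 3), "uniform_span", seed=7)
        assert np.array_equal(a.weights, b.weights)

    @pytest.mark.parametrize("method", ["random_sample", "uniform_span"])
    def test_weights_inside_data_envelope(self, rng, method):
        data = Dataset(rng.normal(size=(100, 4)))
        cb = init_codebook(data, SOMGrid(3, 3), method, seed=3)
        lo, hi = data.values.min(axis=0), data.values.max(axis=0)
        # envelope check per coordinate, by scan
        for w in cb.weights:
            assert np.all(w >= lo) and np.all(w <= hi)


class TestFindBmu:
    def test_nearest_by_inspection(self):
        cb = make_codebook([[0.0, 0.0], [1.0, 1.0]], 1, 2)
        idx, dist = find_bmu(np.array([0.1, 0.0]), cb)
        assert idx == 0
        assert dist == pytest.approx(0.1)

    def test_tie_broken_by_lowest_index(self):
        cb = make_codebook([[0.0], [1.0]], 1, 2)
        assert find_bmu(np.array([0.5]), cb)[0] == 0

    def test_dimension_mismatch(self, random_codebook):
        with pytest.raises(InputError):
            find_bmu(np.zeros(5), random_codebook)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        units = int(rng.integers(2, 50))
        rows = 1 if units < 4 else int(rng.integers(1, units // 2))
        while units % rows:
            rows -= 1
        cb = make_codebook(rng.normal(size=(units, 3)), rows, units // rows)
        x = rng.normal(size=3)
        best, best_d = 0, np.inf
        for i in range(units):
            d = float(np.sqrt(((x - cb.weights[i]) ** 2).sum()))
            if d < best_d:
                best, best_d = i, d
        idx, dist = find_bmu(x, cb)
        assert idx == best
        assert dist == pytest.approx(best_d, rel=1e-10)


class TestNeighborhoodWeights:
    def test_bubble_tiny_radius_hits_bmu_only(self):
        grid = SOMGrid(3, 3, "rectangular")
        h = neighborhood_weights(grid, 4, radius=0.5, kernel="bubble")
        expected = np.zeros(9)
        expected[4] = 1.0
        assert np.array_equal(h, expected)

    def test_gaussian_closed_form(self):
        grid = SOMGrid(1, 3, "rectangular")
        radius = 2.0 / np.sqrt(2.0)  # unit at grid distance 2 sits at radius*sqrt(2)
        h = neighborhood_weights(grid, 0, radius=radius, kernel="gaussian")
        assert h[0] == 1.0
        assert h[2] == pytest.approx(np.exp(-1.0))

    def test_bubble_support_matches_exhaustive_distance_scan(self):
        grid = SOMGrid(4, 4, "rectangular")
        h = neighborhood_weights(grid, 5, radius=1.5, kernel="bubble")
        dist = grid.pairwise_distances()[5]
        for i in range(16):
            assert (h[i] > 0) == (dist[i] <= 1.5)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(InputError):
            neighborhood_weights(SOMGrid(2, 2), 0, radius=0.0)

    def test_weights_bounded(self, rng):
        grid = SOMGrid(5, 5, "hexagonal")
        h = neighborhood_weights(grid, 12, radius=2.3, kernel="gaussian")
        assert np.all((h >= 0) & (h <= 1))


class TestDecay:
    def test_boundaries_and_midpoint(self):
        assert decay(0, 10, 0.5, 0.05) == 0.5
        assert decay(10, 10, 0.5, 0.05) == 0.05
        assert decay(5, 10, 0.5, 0.05) == pytest.approx(0.275)

    def test_step_out_of_range(self):
        with pytest.raises(InputError):
            decay(11, 10, 1.0, 0.0)


class TestKohonenUpdate:
    def test_zero_alpha_is_identity(self, random_codebook):
        before = random_codebook.weights.copy()
        kohonen_update(random_codebook, np.ones(3), 0, 0.0, np.ones(12))
        assert np.array_equal(random_codebook.weights, before)

    def test_full_step_lands_on_input(self, random_codebook):
        x = np.array([5.0, -2.0, 1.0])
        h = np.zeros(12)
        h[3] = 1.0
        kohonen_update(random_codebook, x, 3, 1.0, h)
        assert np.array_equal(random_codebook.weights[3], x)

    def test_matches_scalar_loop(self, rng):
        cb = make_codebook(rng.normal(size=(6, 2)), 2, 3)
        expected = cb.weights.copy()
        x = rng.normal(size=2)
        h = rng.random(6)
        alpha = 0.3
        for i in range(6):
            for j in range(2):
                expected[i, j] += alpha * h[i] * (x[j] - expected[i, j])
        kohonen_update(cb, x, 0, alpha, h)
        assert np.allclose(cb.weights, expected, rtol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_update_stays_in_per_coordinate_hull(self, seed):
        rng = np.random.default_rng(seed)
        cb = make_codebook(rng.normal(size=(4, 3)), 2, 2)
        old = cb.weights.copy()
        x = rng.normal(size=3)
        h = rng.random(4)
        alpha = float(rng.random())
        kohonen_update(cb, x, 0, alpha, h)
        lo = np.minimum(old, x)
        hi = np.maximum(old, x)
        assert np.all(cb.weights >= lo - 1e-12) and np.all(cb.weights <= hi + 1e-12)


def _tiny_schedule(epochs=2, alpha=(0.5, 0.1), radius=(2.0, 1.0)):
    return TrainingSchedule(
        phases=(Phase(epochs, alpha[0], alpha[1], radius[0], radius[1]),),
        kernel="gaussian",
    )


class TestTrainStandardSom:
    def test_single_record_single_unit_fixed_point(self):
        data = Dataset(np.array([[3.0, -1.0]]))
        sched = TrainingSchedule(
            phases=(Phase(1, 1.0, 1.0, 1.0, 1.0),), radius_floor=1.0
        )
        model = train_standard_som(data, SOMGrid(1, 1), sched, seed=0, normalize=False)
        assert np.allclose(model.codebook.weights[0], [3.0, -1.0])

    def test_bitwise_reproducible(self, small_dataset):
        kw = dict(grid=SOMGrid(3, 3), schedule=_tiny_schedule(), seed=11)
        a = train_standard_som(small_dataset, **kw)
        b = train_standard_som(small_dataset, **kw)
        assert np.array_equal(a.codebook.weights, b.codebook.weights)
        assert a.qe_history().tolist() == b.qe_history().tolist()

    def test_qe_improves_on_cluster_mixture(self):
        data, _ = generate_spatial_mixture(MixtureSpec(n=300, seed=4))
        grid = SOMGrid(5, 5)
        model = train_standard_som(data, grid, default_schedule(grid, 3, 5), seed=4)
        qe = model.qe_history()
        assert qe[-1] < qe[0]
        assert len(model.history) == model.schedule.total_epochs

    def test_frozen_alpha_keeps_qe_constant(self, small_dataset):
        sched = TrainingSchedule(phases=(Phase(3, 0.0, 0.0, 2.0, 1.0),))
        model = train_standard_som(small_dataset, SOMGrid(3, 3), sched, seed=2)
        qe = model.qe_history()
        assert np.allclose(qe, qe[0])

    def test_oversized_grid_warns_but_trains(self):
        data = Dataset(np.arange(8.0).reshape(4, 2))
        with pytest.warns(UserWarning, match="large"):
            train_standard_som(data, SOMGrid(10, 10), _tiny_schedule(1), seed=0)


class TestDefaultSchedule:
    def test_twenty_by_twenty_derivations(self):
        sched = default_schedule(SOMGrid(20, 20))
        rough, fine = sched.phases
        assert rough.radius_start == 5.0
        assert fine.radius_start == 1.25
        assert sched.radius_floor == 1.0
        assert rough.alpha_start == 0.5
        assert fine.alpha_start == 0.05

    def test_small_map_radius_never_below_floor(self):
        sched = default_schedule(SOMGrid(3, 3))
        assert all(p.radius_start >= 1.0 and p.radius_end >= 1.0 for p in sched.phases)
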