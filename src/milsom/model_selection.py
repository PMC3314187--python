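"""Model selection: the J-metric run selector and annealed unit-count choice.

Repeated SOM runs from different starts land in different local optima; the
J-metric

    J_som = sum_k sum_i || X_k - w_i ||

(the literal double sum over every data-point / unit pair) scores one run,
and the best of N restarts is the one with the smallest J. Choosing how
many units the map should have is cast as minimizing the slope dJ/d(nodes)
subject to bound constraints — past the elbow of the J-vs-nodes curve each
extra unit buys only a marginal reduction — and, because the node count is
an integer, the search uses simulated annealing with a discrete proposal
step rather than a gradient method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import RunConfig
from .core import Codebook, TrainedModel, default_schedule
from .dataset import Dataset
from .errors import InputError
from .pid import train_milsom

__all__ = [
    "SAParams",
    "SelectionConfig",
    "j_metric",
    "best_of_runs",
    "anneal_node_count",
    "most_square_factorization",
]


@dataclass(frozen=True)
class SAParams:
    initial_temperature: float | None = None  # None -> |objective at start|
    cooling_factor: float = 0.95
    steps: int = 50
    proposal_halfwidth: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise InputError("cooling_factor must lie in (0, 1)")
        if self.steps < 1 or self.proposal_halfwidth < 1:
            raise InputError("steps and proposal_halfwidth must be positive")


@dataclass(frozen=True)
class SelectionConfig:
    n_runs: int = 50
    nodes_low: int = 4
    nodes_high: int = 400
    sa_params: SAParams = field(default_factory=SAParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise InputError("n_runs must be positive")
        if self.nodes_low > self.nodes_high:
            raise InputError("nodes_low must not exceed nodes_high")


def j_metric(data: Dataset, codebook: Codebook, mode: str = "all_pairs") -> float:
    """Summed node-to-data distance for one trained map.

    ``all_pairs`` (default) is the literal double sum over every
    (record, unit) pair; ``bmu`` sums only each record's distance to its
    best matching unit (total quantization error), a common tightening of
    the same idea.
    """
    if data.d != codebook.d:
        raise InputError("dataset and codebook dimensions differ")
    dist = cdist(data.values, codebook.weights)
    if mode == "all_pairs":
        return float(dist.sum())
    if mode == "bmu":
        return float(dist.min(axis=1).sum())
    raise InputError("mode must be 'all_pairs' or 'bmu'")


def _derive_seed(master: int, *salt: int) -> int:
    """Deterministic child seed < 2**31 from a master seed plus salt ints."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def best_of_runs(
    data: Dataset,
    config: RunConfig,
    selection: SelectionConfig,
    j_mode: str = "all_pairs",
) -> tuple[TrainedModel, list[float]]:
    """Train ``selection.n_runs`` restarts and keep the smallest-J map.

    Each restart gets a distinct seed derived from the master seed; J is
    computed in the model's own training space (z-scored when the config
    normalizes). Ties resolve to the lowest run index.
    """
    models: list[TrainedModel] = []
    j_values: list[float] = []
    grid = config.grid()
    schedule = config.schedule()
    for run in range(selection.n_runs):
        run_seed = _derive_seed(selection.seed, 1, run)
        model = train_milsom(
            data,
            grid,
            schedule,
            gains=config.gains(),
            seed=run_seed,
            normalize=config.normalize,
            windup_cap=config.windup_cap,
            init=config.init,
        )
        space = data if model.scaler is None else data.zscore()[0]
        models.append(model)
        j_values.append(j_metric(space, model.codebook, mode=j_mode))
    best = int(np.argmin(j_values))
    return models[best], j_values


def most_square_factorization(nodes: int) -> tuple[int, int]:
    """Factor a unit count into the most-square rows x cols pair (rows <= cols)."""
    if nodes < 1:
        raise InputError("node count must be positive")
    for rows in range(int(math.isqrt(nodes)), 0, -1):
        if nodes % rows == 0:
            return rows, nodes // rows
    return 1, nodes


def anneal_node_count(
    data: Dataset,
    selection: SelectionConfig,
    config_template: RunConfig | None = None,
    j_mode: str = "bmu",
) -> tuple[int, list[tuple[int, float]]]:
    """Simulated annealing over integer node counts in [nodes_low, nodes_high].

    The objective at a candidate count is the finite-difference slope
    |J(nodes) - J(nodes - 1)| estimated from short training runs (the
    template's epoch budget, one fixed derived seed per node count, J values
    memoized). J defaults to the summed record-to-BMU distance, whose
    steep-then-flat profile versus node count is what the near-zero-slope
    stopping idea presumes; the literal all-pairs sum grows with every
    added unit and has no elbow. Proposals step by a uniform integer in
    [1, proposal_halfwidth] either way, clipped to the bounds; acceptance is
    Metropolis with geometric cooling; the best count seen is returned along
    with the memoized (nodes, J) curve sorted by node count.
    """
    if selection.nodes_low < 2:
        raise InputError("nodes_low must be at least 2")
    if selection.nodes_high <= selection.nodes_low:
        raise InputError("nodes_high must exceed nodes_low")
    if config_template is None:
        config_template = RunConfig(rough_epochs=2, fine_epochs=4)
    sa = selection.sa_params
    memo: dict[int, float] = {}

    def j_of(nodes: int) -> float:
        if nodes not in memo:
            rows, cols = most_square_factorization(nodes)
            cfg = config_template.model_copy(
                update={"map_rows": rows, "map_cols": cols, "phases": None}
            )
            model = train_milsom(
                data,
                cfg.grid(),
                default_schedule(
                    cfg.grid(), cfg.rough_epochs, cfg.fine_epochs, kernel=cfg.kernel
                ),
                gains=cfg.gains(),
                seed=_derive_seed(selection.seed, 2, nodes),
                normalize=cfg.normalize,
                windup_cap=cfg.windup_cap,
                init=cfg.init,
            )
            space = data if model.scaler is None else data.zscore()[0]
            memo[nodes] = j_metric(space, model.codebook, mode=j_mode)
        return memo[nodes]

    def objective(nodes: int) -> float:
        return abs(j_of(nodes) - j_of(nodes - 1))

    rng = np.random.default_rng(_derive_seed(selection.seed, 3))
    low, high = selection.nodes_low, selection.nodes_high
    current = int(rng.integers(low, high + 1))
    current_obj = objective(current)
    best, best_obj = current, current_obj
    temperature = (
        sa.initial_temperature
        if sa.initial_temperature is not None
        else max(abs(current_obj), 1e-12)
    )
    for _ in range(sa.steps):
        sign = 1 if rng.random() < 0.5 else -1
        proposal = current + sign * int(rng.integers(1, sa.proposal_halfwidth + 1))
        proposal = min(max(proposal, low), high)
        if proposal != current:
            prop_obj = objective(proposal)
            delta = prop_obj - current_obj
            if delta <= 0 or rng.random() < math.exp(-delta / max(temperature, 1e-300)):
                current, current_obj = proposal, prop_obj
            if prop_obj < best_obj:
                best, best_obj = proposal, prop_obj
        temperature *= sa.cooling_factor
    curve = sorted(memo.items())
    return best, curve
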