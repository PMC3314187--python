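# Methods

## Model

A self-organizing map places `rows × cols` units on a 2-D lattice
(hexagonal by default — each interior unit has six neighbors at lattice
distance 1 under the offset-row embedding — or rectangular with
4-neighborhoods). Each unit i carries a weight vector w_i in data space.
Online training presents one record x_k at a time, elects the best
matching unit (BMU) c = argmin_i ‖x_k − w_i‖ by Euclidean distance (ties
to the lowest unit index), and corrects all units in the neighborhood set
N_c(t) = {i : lattice distance(c, i) ≤ r(t)}, weighted by the kernel
h_ci(t) (Gaussian `exp(−g²/2r²)` or bubble `1[g ≤ r]`). Units outside
N_c(t) are untouched — the update rule's explicit second branch. With the
Gaussian kernel alone every unit would be a member at every step; the
radius-defined membership set is what localizes learning (and, for the
PID variant, what keeps each unit's controller state fed only by samples
the unit is actually responsible for).

### The PID-controlled correction

The classical correction is proportional-only: Δw_i = α h_ci e_i with
e_i = x_k − w_i. The MIL-SOM correction is a discrete PID control signal

    u_i = e_i + a1 · de_i/dt + a2 · ∫ e_i dt,     Δw_i = α h_ci u_i

with both gains nonnegative and the exact classical update recovered at
a1 = a2 = 0 (the implementation shares one training loop between the two
algorithms, so the reduction holds bitwise, not merely approximately).
Effective derivative/integral rates decay with the learning rate:
α1 = α·a1, α2 = α·a2.

Discretization, per unit and per update:

- derivative: backward difference against the unit's error at its previous
  update, divided by the elapsed step count; zero when the unit has no
  history. It damps oscillation of the weight trajectory near convergence.
- integral: the single-window integral over the elapsed inter-update
  interval, rectangle rule: e_i × Δt, where Δt counts global steps since
  the unit's last update (first update after a controller reset spans back
  to the reset point). The term is clamped element-wise to ±windup_cap
  (anti-windup). Because errors multiply the elapsed window, a unit the
  shrinking neighborhood rarely reaches receives a bounded catch-up
  correction — the mechanism behind the variant's faster convergence at a
  fixed budget — while the term vanishes as e_i does, keeping late
  training stable. A running accumulator was considered and rejected: it
  converges to a persistent elastic tension rather than zero and was
  measured to drag the map toward the data mean (final quantization error
  ~5× worse than the classical update under the same schedule).
- controller state is keyed by unit, advances only when the unit is inside
  N_c(t), and is reset at phase boundaries, where the learning rate and
  radius change regime discontinuously.

### Parameters

| parameter | default | meaning |
|---|---|---|
| a1 (derivative gain) | 0.2 | dimensionless multiple of the error difference |
| a2 (integral gain) | 0.05 | dimensionless multiple of the windowed integral |
| windup_cap | 10 × per-column data range | element-wise clamp on the integral term |
| rough phase | 10 epochs, α 0.5 → 0.05, radius max(rows, cols)/4 → that/4 | global ordering |
| fine phase | 20 epochs, α 0.05 → 0, radius down to 1 | local refinement |
| radius floor | 1 | minimum neighborhood radius at any instant |
| kernel | gaussian (within N_c) | bubble available |
| topology | hexagonal | rectangular available |
| normalization | per-column z-score, on | constant columns map to 0 |

For a 20×20 map the schedule derives rough radius 5 and fine radius 1.25.
Per-column z-scoring is on by default because the target tables mix units
(meters, indicator variables, percentiles); codebooks and quality metrics
live in the scaled space, and the recorded scaler maps weights back.
Schedules decay linearly per phase over the phase's step count
(epochs × records); records are presented in a fresh seeded shuffle each
epoch. Everything is deterministic given (data, configuration, seed).

## Model selection

- Best-of-N restarts: each restart trains from a seed derived from the
  master seed; the kept map minimizes J = Σ_k Σ_i ‖X_k − w_i‖, the literal
  sum over every record/unit pair (a `bmu` mode summing only BMU distances
  is available). Default N = 50.
- Unit count: simulated annealing over integer node counts in
  [nodes_low, nodes_high]; the objective is the finite-difference slope
  |J(nodes) − J(nodes−1)| from short training runs, memoized, one fixed
  derived seed per count. The slope objective uses the `bmu` J mode: the
  record-to-BMU sum is steep then flat in the node count, which is what a
  near-zero-slope stopping criterion presumes, whereas the all-pairs sum
  grows with every added unit and has no elbow. Proposals are ± uniform
  integers in [1, 3], Metropolis acceptance, geometric cooling (factor
  0.95, 50 steps), best-seen returned. The chosen count is factored into
  the most-square rows × cols pair. Annealing selects the map-size scale;
  it is a heuristic on a noisy objective and is not guaranteed to find the
  global slope minimum.

## Quality metrics

- Quantization error: mean record-to-BMU distance (the mean, not the sum,
  so values are comparable across dataset sizes).
- Topographic error: fraction of records whose first and second BMUs are
  not lattice neighbors (ties to the lowest unit index; adjacency is
  lattice distance ≤ 1.01, i.e. 6-neighborhood on hexagonal and
  4-neighborhood on rectangular maps).
- U-matrix: expanded (2·rows−1) × (2·cols−1) lattice; cells between
  adjacent units hold inter-unit weight distances, unit cells the mean of
  their surrounding between-cells; remaining holes (rectangular diagonals)
  the mean of their assigned neighbors. In renderings, low values (close
  neighbors) map to light, high values to dark.
- Component planes: per-dimension slices of the codebook on the grid.

## Post-clustering

k-means (Lloyd's iterations, seeded random initialization, best of 10
restarts by within-cluster sum of squares, empty clusters repaired by
re-seeding the farthest point; WCSS is asserted non-increasing across
iterations) partitions codebook vectors; the Davies–Bouldin index —
mean over clusters of the worst (scatter_i + scatter_j)/separation_ij
ratio — selects k over a sweep (default 2 … √units, ties to the smallest
k). The data-aware entry point `cluster_map` excludes units with zero BMU
hits from the sweep and the index: interpolating units sit between data
clusters by construction and otherwise masquerade as "bridge" clusters;
the excluded units then inherit the nearest centroid's label so the whole
map stays labelled. Records inherit their BMU's cluster. Cluster ids are
1-based.

## Synthetic data

`generate_spatial_mixture` emulates point-referenced case-control tables:
cluster centers uniform in a planar extent (default 1000 × 1000 units),
members isotropic Gaussian around them (spread 30), a binary case–control
column (case probability 0.7 for members, one-fifth of that for
background), `attribute_dims` distance-to-anchor exposure columns with
Gaussian noise (sd = spread/2, magnitudes taken so distances stay
nonnegative), and a uniform background fraction (default 10%) labelled 0.
Rows are shuffled; everything is reproducible from the seed.
`generate_noisy_uniform` yields i.i.d. uniform [0,1]^d records.

What the generator does *not* emulate: census-geometry aggregation,
spatially autocorrelated background risk, anisotropic or irregularly
shaped clusters, missing data, and duplicated records. Passing tests on
these scenes therefore demonstrate correctness of the machinery and the
direction of the PID effect under clean conditions, not performance on
real registries.

A note on binary attributes: a case–control column with within-cluster
probability strictly between 0 and 1 carries unit variance after
z-scoring and genuinely splits each spatial cluster in two in attribute
space. Scenes meant to contain exactly k spatial clusters (the recovery
experiment) therefore use pure case clusters (member case probability 1),
and draw candidate scenes until the z-scored separation index (minimum
between-centroid distance over maximum within-cluster scatter) is at
least 5 — otherwise the scene would not satisfy its own premise of
well-separated clusters.

## Study conditions for the shipped experiments

- Directional benchmark: the fixed scene n = 2000, d = 6 (x, y, case,
  three distance attributes), 3 clusters, 10% background; 10 × 10 map,
  rough 3 + fine 7 epochs, equal budget for both algorithms, 10 paired
  training seeds; compared by medians of final quantization error and of
  epochs-to-threshold (threshold = the paired standard run's final Qe).
- Recovery: n = 600, 3 pure-case clusters (spread 60, separation index
  ≥ 5), 8 × 8 map, Davies–Bouldin sweep k = 2 … 6, Rand index against
  ground truth.
- Uniform-random quantization: n = 2000, d = 7, 20 × 20 map, unscaled
  data, rough 3 + fine 7 epochs.
- Stability: 10⁵ PID updates on a heavy-tailed (Cauchy) mixed-scale
  stream, 3 × 3 map, default gains and cap.

## Numerical choices and degenerate inputs

- BMU and second-BMU ties break to the lowest unit index (stable sort).
- Linear decay is endpoint-exact (`start·(1−f) + end·f`).
- z-scoring guards constant columns with unit scale.
- Squared-distance computations clamp small negative values before the
  square root.
- Codebook CSVs serialize floats via `repr` (shortest round-trip), so
  write/read is exact to full float64 precision.
- A grid much larger than the dataset (over 4 units per record) warns but
  trains.
- Davies–Bouldin raises on coincident centroids (undefined ratio); a
  single-unit map has no topographic error (second BMU undefined).

## Known limitations

- The PID advantage is a small, seed-noisy margin on well-conditioned
  scenes (a few percent of Qe in the median, larger early in training);
  it is not the dramatic wall-clock factor sometimes associated with the
  approach, which depends on how far from convergence the baseline is
  stopped.
- Online (sequential) training only; no batch mode, no growing
  architectures, no GPU path.
- Gains are fixed per run (modulo the α(t) proportionality); there is no
  online gain adaptation.
- The simulated-annealing size search evaluates short proxy runs; its
  choice should be read as a scale, not an exact optimum.
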