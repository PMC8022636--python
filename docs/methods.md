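# Methods

## Problem and model

`mowoats` clusters gene-expression matrices: n genes (rows) described by f
numeric features (time points or conditions), assumed complete and already
normalized (e.g. log2 ratios).  A clustering is encoded as k centroid
vectors in raw expression space; genes are hard-assigned to their nearest
centroid under a single configurable metric.  Because no single validity
index captures both cohesion and separation reliably, the search is
multi-objective over three indices computed from each point's nearest
(d1) and second-nearest (d2) centroid distances:

* **Xie–Beni (XB, minimize)** — `sum_i d1(i)^2 / (n * min_{k≠l} D(C_k,C_l)^2)`:
  total within-cluster scatter over the worst centroid separation.
* **Overall deviation (Dev, minimize)** — `sum_i d1(i)`: aggregate
  compactness.
* **Simple Silhouette (SSI, maximize)** — `mean_i (1 − d1(i)/d2(i))`: a
  centroid-only silhouette surrogate.  Unlike the full Silhouette it needs
  no point–point distances, so it decomposes over row partitions.  A point
  with `d2 = 0` (coincident with two centroids) scores 0, a neutral value
  that avoids division by zero.

No scalarization is applied: candidate solutions are compared by Pareto
dominance (`xb ≤, dev ≤, ssi ≥`, strict somewhere), and the non-dominated
set is maintained in a bounded **elite list**.

## Distance metrics and rank preprocessing

Two metrics are supported and fixed for a whole run (objectives and
validation always share the metric):

* `euclidean` — L2 on raw profiles.
* `spearman` — `1 − r_s` with `r_s = 1 − 6·Σd_i²/(f(f²−1))` evaluated on
  **minimum-order ranks** (tied values all take the smallest rank of the
  tied group, i.e. `rank(v) = 1 + #{values < v}`, 1-based).  The closed
  form is used exactly as stated, without a tie correction; with ties it
  can leave [−1, 1] slightly and is deliberately not clamped — the
  distance stays monotone in disagreement, which is all the optimizer
  needs.  Centroids live in raw expression space under both metrics and
  are rank-transformed on the fly before comparison; the data's rank
  matrix is computed once per run.  Because `1 − r_s` is an affine
  function of the squared Euclidean distance between rank vectors, the
  metric vectorizes through `cdist`.

The default metric is `euclidean`; `spearman` is the appropriate choice
when profiles from different scales or platforms are mixed.

## Partitioned objective evaluation

Objective evaluation follows a map/reduce contract modelled on distributed
execution: rows are split into contiguous partitions; each partition
independently computes `(row index, i_min, d1, d2)` records; the
coordinator concatenates them by key and applies the three formulas.  The
result is independent of the partition count and boundaries up to
floating-point summation order (tested at 1e−9 relative).  Returning d2
alongside d1 is required for SSI; it adds one scalar per row to the
reduction payload.  Backends: `SerialBackend` (default),
`ProcessPoolBackend` (joblib), and the abstract `EvaluationBackend` base
for adapters to distributed engines.  All backends must produce identical
assignments.

## The optimizer

Each whale is a flattened k×f centroid matrix.  Per iteration t, each
whale draws coefficients: `a = 2(1 − t/max_it)` (linear 2→0 decay);
per-dimension `A = 2a·r − a` and `C = 2r′` with r, r′ uniform in [0, 1];
`l` uniform in [−1, 1]; `p`, `θ` uniform in [0, 1].  Moves:

* `p > p_threshold` and mean|A| < 1 — **encircle** a uniformly random
  elite-list member: `new_j = g_j − A_j·|C_j·g_j − x_j|`.
* `p > p_threshold` and mean|A| ≥ 1 — encircle a uniformly random swarm
  member (exploration).
* `p ≤ p_threshold` (default 0.2) — **bubble-net spiral** around a random
  elite-list member: `new_j = |g_j − x_j|·e^{b·l}·cos(2πl) + g_j`, b = 1.
  A config flag (`exploit_move="encircle"`) substitutes encircling here
  for users who prefer a purely contractive exploitation move.

Because A and C are drawn per dimension, the intensify/explore branch
needs a scalar summary of |A|; the mean absolute value is used, whose
expectation a/2 follows the same decaying schedule as the scalar-A
formulation, so exploration dominates early iterations and exploitation
late ones.  Per-dimension coefficients make the moves anisotropic, which
empirically helps centroid-encoded solutions where dimensions are
heterogeneous features.

New positions are clamped per coordinate to the data's per-feature
[min, max] (centroids outside the data envelope are never useful), then
evaluated and offered to the elite list.  A whale's new position always
replaces the old one; selection pressure acts only through the archive.
Solutions whose centroids coincide exactly (XB undefined) remain in the
swarm but are never archived.

**Stagnation and crossover.** An iteration "improves" when any elite-list
offer changes the membership.  After `max_non_improve` (default 2)
consecutive non-improving iterations, a crossover phase runs: q whales
(q uniform in [1, ⌊Np/2⌋]) are each recombined by replacing a random
non-empty proper subset of centroid slots with the partner's slots at the
same indices — with a random elite member when θ < 0.5 (intensification),
with a different random whale otherwise (diversification).  Offspring
replace their parents, are re-evaluated and offered to the archive, and
the stagnation counter resets (on either an elite change or a completed
phase).

**Elite list.** Capacity `max_el` (default 50).  A candidate is rejected
if dominated by a member or if its exact objective vector is already
present (duplicates waste capacity); otherwise dominated members are
removed and the candidate inserted.  On overflow the member with the
smallest NSGA-II-style crowding distance is evicted; per-objective
extremes have infinite crowding distance and are never evicted, which
preserves the spread of the stored front.  `update` reports a change only
when the membership actually differs — in particular, an insertion
immediately undone by crowding eviction counts as no change.  Note the
bounded archive is exact (equal to the brute-force non-dominated filter
of all offers) whenever the true front fits within capacity; beyond
capacity it is a crowding-pruned non-dominated subset, and a solution
whose dominator was evicted earlier can in principle linger — an inherent
property of bounded Pareto archives.

**Defaults** (also the study conditions of the test suite): `max_it` 50,
`n_whales` 15, `max_el` 50, `max_non_improve` 2, `p_threshold` 0.2,
`spiral_b` 1.  All randomness flows from one `numpy` generator seeded by
`config.seed`, so a seed fixes the entire run bit for bit.

## Selecting and validating the final clustering

The returned elite list is a front, not a single answer.
`select_best_solution` labels the data by nearest centroid for every
member, computes the full Silhouette `S = mean_i (b_i − a_i)/max(a_i, b_i)`
(a_i mean same-cluster distance, b_i best mean other-cluster distance,
singletons score 0; mean over all n points), skips members that collapse
to one non-empty cluster, and returns the member with the highest S (ties
to the earlier member, so selection is order-invariant whenever scores
are distinct).  The report adds:

* **Davies–Bouldin** `1/m · Σ_i max_{j≠i} (S_i + S_j)/M_ij`.  By default
  the scatter S_k is measured against the *solution's* centroids so
  validation matches the optimized representation; `centroids=None`
  recomputes cluster means (this mode matches scikit-learn's
  `davies_bouldin_score` and is what the `validate` CLI command uses,
  since it sees only labels).
* **Dunn** — minimum single-linkage between-cluster distance over maximum
  within-cluster diameter.
* **F-measure** (when generating/true labels are supplied) — class-size-
  weighted best-match harmonic precision/recall over the contingency
  table; invariant to relabeling of cluster ids.

## Synthetic data

`SyntheticSpec`/`generate_dataset` emulate the shape of real inputs
(hundreds of genes, ≤ 20 features, a handful of co-expression groups):

* **blob** — k centroids rejection-sampled (≤ 1000 attempts) from an
  isotropic Gaussian until all pairwise distances reach
  `separation × noise_sigma`; points are centroid + N(0, noise_sigma²).
  Defaults (n = 400, f = 10, k = 4, separation = 10σ) give a strongly
  separated recovery problem where a correct method should reach
  F-measure ≈ 1 — at 10σ spacing the Gaussian misassignment probability
  is negligible.
* **timecourse** — z-scored smooth templates (rising, falling, peaked,
  sinusoidal, then phase-shifted sinusoids for k > 4) scaled so group
  spread matches the blob convention, plus noise.  These mimic normalized
  log-ratio trajectories, making rank/Spearman tests sensitive to curve
  shape rather than magnitude.

`tie_fraction` quantizes that share of entries to two decimals; if the
quantization happens to produce no within-row collision, the two closest
entries of the first row are set to a common rounded value so the
minimum-order tie path is always exercised.  Group sizes are multinomial
in `group_weights`.

What the generator does **not** emulate: probe-level noise models,
missing values, heavy-tailed or correlated noise, batch effects, or
cluster overlap structure of real microarray compendia.  Passing the
recovery tests therefore demonstrates correctness of the machinery on
well-posed instances, not expected index values on real data.

## Numerical choices and edge cases

* Nearest-centroid ties break to the lowest centroid index (argmin).
* Degenerate solutions: coincident centroids raise a
  `DegenerateSolutionError` from XB/DBI rather than returning ±inf.
* `simple_silhouette` with d2 = 0 scores that point 0.
* Silhouette singletons score 0; two singleton clusters give S = 0.
* I/O round trip uses 17-significant-digit formatting, so write-then-read
  reproduces doubles bit for bit.
* Heatmap export is a stable sort by cluster label: clusters ascending,
  input order preserved within clusters; the export is a row permutation.
* `woa_update_params` draws A, C per flattened dimension; reproducibility
  depends only on the seed and the (k, f) shape.

## Problem sizes in the test suite

Unit and property tests run on instances up to n = 500, f = 20, k = 8;
the recovery study uses 10 independent seeds of the default blob spec with
the default optimizer parameters, chosen as a realistic desk-scale
instance of the study conditions.  `scripts/acceptance.py` re-runs that
study from scratch plus a closed-form 1-D fixture (points {0, 2, 10, 12},
centroids {1, 11}: XB = 0.01, Dev = 4, SSI = (10/11 + 8/9 + 8/9 + 10/11)/4)
and a 50-instance partition-invariance sweep.

## Known limitations

* The bounded archive's exactness guarantee holds only while the true
  non-dominated set fits within capacity (see above).
* The Spearman closed form is not tie-corrected (by design, see above);
  heavy tying compresses the distance range.
* k is a per-run input; model selection across k is the CLI sweep
  (`--k 4,5,6`) ranked by full Silhouette, not an internal criterion.
* With k larger than the number of well-separated groups, nearest-centroid
  labelings often leave clusters empty; such solutions are skipped at
  selection time, which is why a k = 5 run may legitimately return a
  4-cluster labeling.
* The process-pool backend pays serialization overhead per solution; it
  only helps when n·f is large relative to Np·max_it.
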