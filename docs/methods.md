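# Methods

## Input model

The universal input is a score matrix: *n* subjects × *m* stressor
attributes, every entry on a closed working scale, by default [0, 10].
Raw questionnaire totals are mapped onto the scale by a **per-attribute
affine min–max rescaling** (column minimum → lower bound, maximum → upper
bound). Per-attribute — rather than global — rescaling was chosen because
the fuzzy similarity construction also normalizes per attribute; the two
stages then agree on what "full range" means. The map preserves
within-column order, is idempotent, and rejects constant columns: a
stressor on which every subject scores identically carries no clustering
information, and its zero range would otherwise divide by zero in the
similarity step. Missing entries are a load error, not an imputation
problem; psychometric missing-data handling is out of scope.

## Fuzzy equivalence-relation clustering

Similarity is one minus the root-mean-square of range-normalized attribute
distances, so s(i,j) ∈ [0, 1] with s = 1 exactly for identical profiles.
The similarity relation is reflexive and symmetric but not min-transitive;
its **max–min transitive closure** is computed by repeated squaring
(R ← R∘R under max–min composition) until a fixed point, which takes at
most ⌈log₂(n−1)⌉ + 1 squarings. Because max–min composition only ever
*selects* values already present in the matrix (no new floats are
created), the fixed-point test is exact equality — no tolerance is needed,
and results are bit-reproducible across platforms.

The **λ-cut** joins subjects with closure entry ≥ λ (closed threshold, so
pairs sitting exactly at λ share a cluster) and is implemented as
connected components of the thresholded relation; min-transitivity
guarantees the components are exactly the equivalence classes, and
non-transitive inputs are rejected rather than silently mis-partitioned.
Sweeping λ over the distinct closure entries, descending, gives the nested
partition hierarchy; the cut at an arbitrary λ equals the recorded cut at
the smallest grid value ≥ λ.

On the packaged 10-athlete table the closure's largest off-diagonal entry
is ≈ 0.761, so the λ = 0.90 cut yields ten singletons. This partition is
kept as a frozen regression snapshot (`tests/golden/`) — it documents what
the pipeline computes on that input, and any change to the arithmetic will
surface as a golden-file mismatch.

## Agglomerative hierarchy

Agglomeration starts from *n* singletons and repeatedly merges the pair of
clusters with the smallest inter-center Euclidean distance ("adjacent" is
read as nearest-center; ties break to the lexicographically lowest pair of
cluster ids, making runs deterministic and subject-order-stable when
distances are distinct). The new center is computed from the two merged
centers alone; two update rules are provided:

- **weighted** (default): size-weighted mean of the two centers. This is
  algebraically identical to the member mean of the merged cluster
  (centroid/UPGMC linkage), so the recorded centers are genuine centroids
  — which is what the K-Means warm start needs them to be.
- **midpoint**: unweighted midpoint of the two centers (median/WPGMC
  linkage). Kept as an explicit option for completeness. Its centers
  drift toward whichever side merged most recently; in testing this
  strands moderate outliers as singletons and merges genuinely separate
  groups (on 3 well-separated Gaussian clusters it recovers the generating
  labels in only ~60% of draws versus ~90% for the weighted rule), and
  the stray singletons then corrupt the silhouette-based choice of K. It
  is therefore not the default. Under this rule the final center of a
  full agglomeration is the iterated pairwise midpoint, generally not the
  grand mean.

Merge distances are recorded in the merge tree but monotonicity is *not*
asserted: center-based linkages can produce inversions. A single merge
pass records the partition at every intermediate cluster count
(`agglomerate_sweep`), since the greedy sequence does not depend on where
it stops; the silhouette sweep exploits this instead of re-running the
agglomeration per candidate K.

## Hybrid K-Means

1. **K selection.** For each K in a user-supplied range (default 2–6),
   take the agglomerative partition at K and score it by the mean
   silhouette coefficient s(i) = (b−a)/max(a,b) (singleton clusters
   contribute 0); the argmax wins, smallest K on ties.
2. **Warm start.** Agglomerate to K − R clusters (R = `split_budget`,
   constrained to 0 ≤ R < K − 2 and R = 0 at K = 2; default 1 when K ≥ 4,
   else 0; configured values are clamped into the feasible range once K
   is known) and take the recorded centers.
3. **Split.** While fewer than K clusters exist: pick the cluster with the
   largest class radius (maximum member-to-center distance — the proxy for
   lowest intra-cluster cohesion), find member x₁ farthest from its
   center and member x₂ farthest from x₁ (ties to the lowest subject
   index), and replace that cluster's center with the two points.
4. **Refine.** Lloyd's algorithm: nearest-center assignment (ties to the
   lowest center index) alternating with member-mean updates, until the
   maximum center displacement ≤ `tol` (default 1e−6) or `max_iter`
   (default 300). A cluster emptied by an assignment is reseeded with the
   point farthest from its former center, so the cluster count never
   drops; reseeding can only lower the objective, so the within-cluster
   SSE is non-increasing across iterations, which every run records and
   the test suite asserts. The split-refine loop re-evaluates cohesion
   only while the cluster count is below K; at K only Lloyd runs, which
   terminates — a literal unconditional split-refine loop would not.

Diagnostics report the chosen K, resolved split budget, splits performed,
total Lloyd iterations, SSE history and convergence flag. Runs are fully
deterministic given the configuration.

## Stress index and source aggregation

Q = Σ w_i e_i / Σ w_i is a convex combination of the per-source scores, so
min(e) ≤ Q ≤ max(e), Q is monotone in every score, and affine rescaling of
the scores rescales Q the same way. The exponential weight generator
w_i = base^{n_i} (base > 1, n_i = repetition count of that kind of
pressure across the subject pool) is normalized to sum 1; shares are
invariant to uniform weight rescaling. Sources are classified acute vs.
chronic by a user-supplied taxonomy; the per-class share is the class's
fraction of total weighted pressure Σ w_i e_i summed over subjects. The
default taxonomy for the packaged athlete table treats family (M4) and
social (M5) pressure as chronic/external and the competition-linked
sources (training, life, development, performance) as acute. Interpretation
bands on the [0, 10] scale default to low < 4 ≤ medium ≤ 7 < high. Weights,
bands and taxonomy are configuration, not constants.

## Synthetic data

`generate_labeled(n, k, m, separation, seed)` draws k spherical unit-σ
Gaussian clusters with centers `separation` standard deviations apart
(exactly, on scaled coordinate axes, when k ≤ m; minimum pairwise distance
when k > m, with isotropic random center directions), cluster sizes as
equal as possible, then rescales each attribute onto [0, 10] affinely.
Affine rescaling was chosen over clipping because it preserves the mixture
geometry — the generating labels remain a valid ground truth. What the
generator does *not* emulate: correlated attributes, non-spherical or
unequal-spread clusters, heavy tails, discreteness of questionnaire
scores. Passing recovery tests therefore demonstrates correctness of the
algorithms on well-specified mixtures, not robustness on real psychometric
data.

Two fixed suites:

- `benchmark_suite(seed)`: shapes (n, k) = (150, 3), (300, 2), (4000, 30)
  with m = 4 and separation 6 — shape-compatible stand-ins for the classic
  Iris / Breast-Cancer / Abalone evaluation trio, with no download and no
  attempt to mimic those datasets' feature distributions.
- `generate_hard_mixture(seed)`: n = 160, k = 8, m = 4, separation 3. This
  is the initialization-stress regime: with few well-separated clusters
  K-Means reaches the same optimum from almost any start and comparisons
  between initializations are tie-dominated, whereas with eight
  overlapping clusters a random start frequently places two centers in
  one group and none in another, which Lloyd cannot repair. The
  warm-start-vs-random comparison is run here.

## Evaluation

Best-match accuracy solves the optimal one-to-one label assignment on the
contingency table (Hungarian algorithm); unmatched clusters contribute 0.
With k balanced true clusters any prediction scores ≥ 1/k (pigeonhole).
The adjusted Rand index uses the standard pair-counting form; both
partitions trivial (identical all-singleton or single-block) returns 1.
The comparison runner gives the random baseline the *same K the hybrid
chose*, isolating initialization quality from model selection, and draws
baseline centers uniformly within the per-attribute data range. Runtime is
reported as iteration counts, a hardware-independent proxy.

## Problem sizes and numerical choices

The test and acceptance workloads use n ≤ 300 per fit (50-seed sweeps at
n = 150–160) and 200–500 random relations at n ≤ 12; these sizes give
stable aggregate statistics while keeping a full run in minutes on one
core. The CLI `benchmark` command subsamples any suite dataset above
`--max-n` (default 600) before the comparison, since the agglomeration is
O(n²) per merge; the full-size suite is still generated and shape-checked.
Floating-point policy: exact equality where the algebra guarantees value
selection (max–min closure, its fixed-point test, λ-grid construction),
1e−12 tolerances for symmetry/reflexivity validation, 1e−9 for golden-file
float comparisons.

## Known limitations

- The fuzzy pipeline is O(n³ log n) in the closure squaring; it targets
  squad-sized cohorts (tens of subjects), not the thousands the K-Means
  path handles.
- Silhouette-based K selection inherits the hierarchy's biases; on
  strongly overlapping mixtures it tends to choose fewer clusters than the
  generator used.
- The acute/chronic shares depend entirely on the user-supplied taxonomy
  and weights; the defaults are documented conventions, not fitted values.
- The midpoint center-update option is provided for comparison but is
  known to be fragile (see above); results obtained with it should be
  treated accordingly.
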