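# Methods

This note documents the models, estimators and numerical choices behind
`angionet`, in the order the pipeline runs.

## Growth simulator

Vascular images are generated by a discrete-time persistent random walk
with stochastic branching.  Each active tip advances `step_len` pixels
per iteration along its heading, which is perturbed each step by
Gaussian jitter of standard deviation `angle_sigma` (radians).  With
probability `branch_prob` per step the tip is replaced by two daughters
whose headings straddle the parent heading by ±`branch_angle`.  Tips die
on boundary contact or at the `max_steps` iteration cap; seed origins and
death sites are recorded as terminal events, bifurcations as branch
events, and every inter-event trajectory as a segment with its polyline
length.  The vessel mask is the union of discs of radius `radius`
stamped along all trajectories (morphological dilation of the rasterised
polylines).  One seeded NumPy generator drives each simulation, so
`(params, rng_seed) → mask` is a pure function.

Modelling choices and what they imply:

* **No anastomosis rule by default.**  Disc rasterisation may still fuse
  nearby vessels, producing loops as real images do.  Free 2-D branching
  walks additionally *cross* themselves at an appreciable rate
  (≈0.5–0.8 crossings per branch event at the densities used), creating
  network junctions that correspond to no branching event.
* **Optional contact inhibition** (`contact_inhibition=True`): a tip also
  dies when its next position comes within `contact_radius` pixels of
  vessel territory laid down more than three iterations earlier,
  emulating anastomotic stopping of sprouting tips.  Fresh territory is
  exempt so daughters survive their first steps after a bifurcation.
  This suppresses crossings almost entirely.
* **Diffusion-limited aggregation is not implemented**; the branching
  walk is the simplest process producing realistic branching statistics,
  and growth is strictly 2-D with no flow coupling.

### Treatment presets

The seven presets map biological treatment groups onto frozen parameter
sets (384×384 canvas, radius 2, step 4).  The biology provides group
means, not growth parameters, so the presets were calibrated once, before
freezing, such that over 30-replicate cohorts the group means of vessel
percentage area sit near the published per-group values (≈17.4, 9.6,
7.9, 7.0, 6.1, 4.6, 4.0 % for `pge1`, `amino8`, `amino3`, `amino5`,
`hydroxy8`, `control`, `quinoline`) with comparable spreads, and both
vessel coverage and junction-count means decrease strictly along that
ordering.  Junction-count magnitudes (≈28–240 per image) are a
desk-scale rendition of the biological span (≈40–353): absolute counts
depend on canvas resolution, which the source assay does not specify, so
only the ranking and relative separation are treated as meaningful.

### Extraction-validation condition

Extraction accuracy cannot be judged on the treatment presets: at their
densities, rasterisation fuses neighbouring branches and free-walk
crossings add junctions with no ground-truth counterpart, so a
ground-truth comparison would measure rasterisation limits rather than
tracing correctness.  Accuracy is therefore validated on a dedicated
frozen configuration (`EXTRACTION_VALIDATION`): thin vessels (radius 1),
wide branch half-angle (1.0 rad), near-straight walks (jitter 0.06), two
seeds on a 768×768 canvas, contact inhibition on.  Under this condition
every branching event is geometrically resolvable at a 3-pixel matching
tolerance.  Passing accuracy checks here demonstrates that the
skeleton→graph tracing is correct; it does not bound the (unavoidable)
fusion losses on dense imagery.

### Deterministic fixtures

`make_fixture` provides closed-form patterns: `line`/`diagonal`/`cross`/
`ystem`/`hbar`/`ring` are single-pixel-wide (valid skeletons as drawn),
`filled`/`half`/`checkerboard` have exact coverage fractions, the
depth-k Sierpinski carpet has exactly 8^k foreground pixels and
box-counting dimension log 8/log 3.

## Morphometry

* **Binarisation**: Otsu (foreground strictly above the returned level,
  the bin-edge convention) or a fixed threshold (foreground ≥ level);
  boolean input passes through.  A constant image has no Otsu threshold
  and is rejected.
* **Thinning**: `skimage.morphology.skeletonize` (two-subiteration
  Zhang–Suen-family thinning), which preserves the 8-connected component
  count and never adds foreground.
* **Node detection**: endpoints have exactly one skeleton neighbour;
  junction candidates have ≥ 3.  Candidates are merged over 8-connected
  clusters to one junction at the rounded cluster centroid, so a thick
  crossing or a T whose adjacent pixels also exceed two neighbours
  counts once.
* **Skeleton length**: 1 per orthogonally adjacent skeleton pair,
  √2 per diagonal pair, each pair once — except diagonal pairs whose
  shared orthogonal neighbour is foreground, which are corner shortcuts
  of an already-counted path and are skipped (otherwise a plus-shaped
  cross would measure 4 arms + 4√2).  Multiplied by the pixel scale
  (default 1; the source assay gives no magnification calibration).
* **Junction density** is junctions per 100 units of skeleton length, a
  scale-free denominator chosen because the original tool does not
  define one.  **Average length** is skeleton length per traced segment
  (graph edge).
* **Lacunarity**: gliding-box Λ(r) = E[M²]/E[M]² over all fully
  contained r×r windows.  Default box sizes are dyadic
  {2, 4, …, side/4}; the window stride defaults to max(1, r/4) because
  stride-1 gliding is quadratic in image size — closed-form checks
  (checkerboard Λ(1) = 2, filled Λ ≡ 1) are evaluated at stride 1, where
  the estimator is exact.  Λ is undefined (error) on an empty mask; the
  composite `quantify` record reports NaN there instead.

## Skeleton → graph

Tracing marches from every node-cluster pixel along unvisited skeleton
pixels to the next node cluster; each centerline pixel belongs to exactly
one edge, guaranteeing the skeleton is accounted once.  Edge `weight` is
the Euclidean chord between node coordinates (the convention of the
re-implemented workflow); `path_len` is the traced arc.  Because cluster
centroids can sit a fraction of a pixel beyond the traced pixels,
`path_len` is clamped to be ≥ `weight` (chord ≤ arc holds exactly in the
continuum; discretisation can violate it by < √2).  Parallel edges and
self-loops are kept; a connected component with no node (pure cycle)
becomes an `anchor` node with a self-loop of weight 0 and `path_len`
equal to the cycle perimeter; isolated pixels become edgeless endpoints.
The adjacency export takes the minimum over parallel edges and puts
self-loop weights on the diagonal.  `simplify` contracts chains of
degree-2 non-anchor nodes (summing arcs, re-chording the ends) until
fixpoint; it is idempotent, and an all-degree-2 cycle collapses to one
node with a self-loop, consistent with the pure-cycle convention.

## Topology metrics

Counts and average degree (2E/N, self-loops contributing 2) come from
the multigraph; clustering, betweenness, density, diameter and average
path length are computed on the simple unweighted projection (parallel
edges collapsed, self-loops dropped) via NetworkX.  Betweenness is
normalised by (N−1)(N−2)/2 with endpoints excluded, so values are
comparable with the ~10⁻³–10⁻² magnitudes conventional in this
literature.  Shortest paths are hop counts (weighted variants can be
obtained from the exported graphs but are not the default).  Diameter
and average path length are taken over the largest connected component,
with the component count reported alongside, since disconnected
vessel fields are common.  Graphs with < 2 nodes return density and
betweenness 0 with a `degenerate` flag; the empty graph is an error.

## Structural analyses

* **Modularity** is evaluated directly from the cluster/degree sums
  Q = Σ_c [e_c/m − (d_c/2m)²] on the simple projection (tested against
  the pairwise double-sum formulation to 1e-12 and against exhaustive
  partition enumeration for N ≤ 8).  Q of the one-community partition is
  identically 0; the edgeless graph is an error.
* **Community detection** is greedy agglomerative modularity
  maximisation (CNM-style): singleton start, repeatedly merge the
  connected pair with the largest ΔQ = e_ab/m − d_a d_b/(2m²) while
  ΔQ > 0, ties broken by the smallest community-id pair, making the
  result deterministic.  Per-community statistics report size, mean
  degree centrality deg/(N−1) and mean incident edge weight.
* **Fractal dimension**: grid-aligned box counting at dyadic sizes
  (origin-anchored, no offset averaging — a simplicity/accuracy
  trade-off that is exact on the reference objects used for validation);
  d is the least-squares slope of log N(r) vs log(1/r), with the fit R²
  reported.  At least four scales are required.  For network complexity
  the skeleton mask is the conventional input; passing the full vessel
  mask measures the area-covering object (dimension → 2 as coverage
  grows).
* **Robustness**: a nested removal order per replicate (uniform shuffle,
  or static descending degree/betweenness with id tie-breaks), so each
  replicate's largest-component-fraction curve is non-increasing by
  construction.  lcc_frac divides by the original N, so curves start
  below 1 on disconnected graphs.

## Cohort statistics

Sample (n−1) standard deviations; variance is the exact square of the
reported std; quartiles by linear interpolation (the common
statistical-software default — published per-group variances that
disagree with squared printed stds are rounding artefacts, and the
internally exact pair 1.80² = 3.24 is used as the consistency check).
One-way ANOVA is computed from explicit between/within sums of squares
with p from the upper F tail (cross-checked against
`scipy.stats.f_oneway`); Kruskal–Wallis uses SciPy's midrank tie
correction with the χ²(k−1) approximation.  All-identical data make both
tests 0/0-degenerate and raise.  Post hoc procedures (Tukey HSD, Dunn)
are deliberately left to standard statistical packages.

## Problem sizes and determinism

Validation runs use 30-replicate cohorts per preset on 384×384 canvases,
50 validation images at 768×768 for extraction accuracy, 2000 null
replicates for test-size calibration, and exhaustive graph enumeration
up to 6–8 nodes; these sizes give stable Monte-Carlo estimates (rank
orderings and accuracy figures reproduce across independent seed bases)
while keeping a full run in tens of seconds.  Every stochastic component
takes an explicit integer seed.

## Known limitations

* The simulator is 2-D, flowless, and its presets are calibrated to one
  canvas size; absolute junction counts scale with resolution.
* Synthetic images lack imaging noise, uneven illumination and
  segmentation artefacts, so passing tests demonstrates correctness of
  the measurement chain on clean masks, not robustness of binarisation
  on real micrographs.
* Dense networks fuse branches under rasterisation; ground-truth
  accuracy is certified only under the validation condition.
* Lacunarity at the default stride is an approximation of the stride-1
  estimator; box-counting uses a single grid origin.
* The "lateralization index" of the original tool has no published
  definition and is not implemented.
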