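# Methods

## Scope and data model

`isoclust` operates downstream of integration and scaling: its input is
one table of scaled, unmerged observations per crystal (Miller index,
intensity, sigma) plus shared metadata (unit cell, rotation parts of the
symmetry operations, anomalous flag). Symmetry is supplied as explicit
matrices; space-group symbols are carried as documentation only, so no
space-group tables are embedded. Miller indices are mapped to a canonical
asymmetric unit by taking the lexicographically greatest member of the
orbit {R^T h} (extended by Friedel mates -R^T h unless anomalous pairs
are kept separate). Any consistent canonicalization yields identical
merging; the lexicographic rule was chosen because it needs no tables
and is trivially idempotent.

## Merging and the resolution filter

Merged intensities are inverse-variance weighted means,
I_w = sum(I_j/sigma_j^2) / sum(1/sigma_j^2), with standard error
sigma_w = [sum(1/sigma_j^2)]^(-1/2). A single global resolution limit is
applied to all pairwise comparisons so every correlation sees the same
reflection set. The limit is derived from the pooled study: observations
are binned into 10 equal-count resolution shells (one shell when fewer
than 10 unique groups exist), and two conservative per-shell filters are
evaluated — mean(I)/mean(sigma) > 4.0, and half-split CC1/2 > 0.6. Each
filter proposes the inner edge of the highest-resolution shell it
accepts; the proposal at better resolution wins. The half-split is a
seeded random partition of each symmetry group's observations into two
inverse-variance-merged halves (the extra observation of an odd group
goes to the first half); shells with fewer than three multi-observation
groups leave the CC filter unconstrained. The shell count and the split
scheme are our choices — equal-count shells stabilize the per-shell
statistics at the study sizes we target, and the seed makes the filter
reproducible.

## Weighted correlations and reliability weights

The pairwise statistic is the Pearson correlation of merged intensities
over common symmetry-unique reflections. In sigma-weighted mode each
term carries w_i = 1/(sigma_x,i^2 + sigma_y,i^2), the reciprocal of the
combined variance of the pair of merged values; means, variances and the
cross term are all w-weighted. This removes the dominance of poorly
measured (typically strong, high-variance) reflections that makes
unweighted correlations unreliable for narrow-wedge and serial data.
The Kish effective sample size n_e = (sum w)^2 / sum w^2 measures how
many equally weighted reflections the pair is worth (1 <= n_e <= n, with
equality only for equal weights); normalized by the study maximum it
becomes the pair's reliability weight in the embedding objective.
Pairs with fewer than three common reflections, or with degenerate
variance, are incalculable: they get zero weight and are excluded
everywhere (three points is the minimum for a non-degenerate Pearson r).
Computed correlations are clamped to [-1, 1] against floating-point
overshoot.

## Embedding and dimension selection

Coordinates x_i (one row per data set, d columns) minimize
Phi = sum_{i<j} w_ij (r_ij - x_i . x_j)^2, so inner products reproduce
the observed correlations. Self-pairs are excluded (they would add only
a constant pull), and coordinates are unconstrained apart from the
uniform random [0, 1]^d start. Minimization is a limited-memory BFGS
(two-loop recursion, memory 10) with Armijo backtracking and the
standard s.y/y.y Hessian scaling, implemented as a compiled kernel; it
stops when the gradient max-norm falls below 1e-6 or after 1000
iterations. One restart per dimension is the default; `--restarts`
reruns from independent starts and keeps the lowest residual for
multimodal cases. On planted Gram matrices of rank <= d the optimizer
reaches residuals near machine precision, comfortably below the 1e-8
level we regard as "exactly solvable".

The scan minimizes Phi for every d in 1..min(N, 50) (the cap keeps the
cost linear in N at large studies), deriving each start deterministically
from the master seed. The selected dimension is the elbow of the
residual curve: both axes are normalized to the unit square and the
interior point with the greatest perpendicular distance from the chord
joining the curve's endpoints is taken, ties toward the smaller
dimension. Residuals below 1e-8 are clamped to that floor first — at the
gradient tolerance used they are indistinguishable from zero, and
without the clamp their random fluctuations would masquerade as
curvature (a rank-1 study would otherwise select a spurious dimension).
Flat and strictly linear curves, and curves of length <= 2, select d=1.

For presentation the coordinates are centered and rotated onto their
principal axes (an SVD; rigid, distance-preserving) with the variance
percentage of each axis reported.

## Hierarchical clustering

Ward (default) and average linkage are implemented via Lance–Williams
updates on the distance matrices 1 - r_ij and 1 - cos(x_i, x_j), with
deterministic smallest-(i, j) tie-breaking; merge heights reproduce the
standard reference recurrence, which treats input distances as
Euclidean. These intensity-derived distances are not Euclidean, so
height inversions are possible; they are tolerated, matching common
practice. Flat labels come from cutting at a fraction of the maximum
merge height; 60% and 70% (the proposed "isomorphic threshold" range for
correlation dendrograms) are both reported by default. Dendrograms are
exported as merge lists (JSON) and Newick with branch lengths equal to
height differences.

## Density-based extraction (OPTICS)

OPTICS runs on the optimized coordinates with the Euclidean metric and
an unbounded neighbourhood radius. The core distance of a point is the
distance to its s_min-th nearest neighbour with the point itself
counted, matching the mainstream implementation's convention. The
expansion always continues at the unprocessed point with the smallest
current reachability (first index on ties), making ordering,
reachability and predecessor arrays fully deterministic; distances are
computed by the exact difference-based formula rather than the
inner-product shortcut, because last-ulp differences can flip tie-breaks
in the ordering. Cluster extraction uses the xi steep-area method with
predecessor correction, delegated to scikit-learn's
`cluster_optics_xi` on our arrays — the extraction rules are standard
and the contract here is exact agreement with the reference
implementation, which the test suite checks on dozens of seeded
instances. Points in no extracted cluster are labeled -1 and excluded
from per-cluster outputs.

The minimum cluster population follows s_min = max(5, floor(b N / d)):
the embedding dimension d is a rough proxy for the number of distinct
groups, b = 0.5 buffers against unequal group sizes, and the floor of 5
keeps tiny studies meaningful. Larger xi values merge shallow valleys
(never increasing the cluster count); the defaults xi = 0.05, b = 0.5
are appropriate for all scenarios we model, and both are exposed on the
command line.

## Quality metrics

Davies–Bouldin uses cluster centroids and mean member-centroid
distances; for correlation-based clustering the rows of the r matrix
serve as feature vectors, for coordinate-based clustering the embedded
coordinates. Outliers (-1) are excluded there, since a noise class has
no meaningful centroid, but kept as their own predicted class in
V-Measure so that spurious outlier calls cost homogeneity and
completeness. Both metrics are implemented from their definitions and
verified against scikit-learn to 1e-10 on random labelings.

## The synthetic study generator

The generator produces the situation the method targets with known truth
labels. Base true intensities are Exponential(1) draws (acentric Wilson
statistics). Each group perturbs a seeded fraction of reflections
multiplicatively, J -> J exp(delta z) with independent standard-normal
z per group — positivity-preserving, and concentrated on a subset the
way a localized structural change is. Each data set observes a random
subset (or contiguous wedge) of the unique reflections with Poisson
multiplicity (minimum 1), Gaussian noise of standard deviation
noise_scale * sqrt(J + 1) (counting-statistics-like, intensity-linked),
and honestly reported sigmas. Indices sit on a cubic grid so d-spacings
span a real range and the resolution filter is exercised; symmetry is
identity-only, isolating clustering behaviour from ASU bookkeeping
(which is tested separately).

Two emulation choices deserve comment:

* **Variable-quality data sets** (`hetero_fraction`) carry threefold
  sigma inflation on a random *half* of their observations, not
  uniformly. A uniform inflation leaves the relative per-reflection
  weights — and therefore the weighted correlation and the Kish n_e,
  both scale-invariant — unchanged, so no weighting scheme could ever
  help against it. Per-observation quality loss is also what actually
  happens upstream (partiality errors, beam-centring drift), and it is
  precisely what sigma-weighting can down-weight.
* **Planted outliers** are aberrant data sets of the same crystal form:
  the base intensities perturbed by a *shared* aberration mode plus an
  individual component, J -> J exp(delta_out u_i (z_shared + z_i)/sqrt2),
  with per-outlier severity u_i ~ U(0.7, 1.3). Real outlier crops arise
  from a common failure mechanism of varying severity (beam-centring
  drift, collapsing scale factors), so they are far from every group,
  partially correlated with each other, and occupy roughly one coherent
  extra embedding direction. Two simpler models fail to emulate this:
  unrelated intensity realizations are orthogonal to everything and add
  one spurious embedding dimension per outlier, while fully independent
  per-outlier perturbations spread their variance over many weak
  directions so the dimension scan stops at the pure group rank — in
  both cases the s_min heuristic is distorted in ways real aberrant data
  sets do not cause.

Preset scenarios fix the study shapes used throughout the tests:
`two_group_small` (2 x 8 data sets), `three_group_balanced` (3 x 12),
`three_group_unbalanced_outliers` (83/85/28 plus 19 outliers, 20%
variable-quality), and `sparse_overlap` (2 x 8 with coverage chosen so
pairs share ~100 unique reflections). Noise levels are set so the clean
presets resemble high-quality data (overall I/sigma around 7–10 — data
that would clearly pass the mean(I)/mean(sigma) > 4 filter), with the
unbalanced preset noisier (room-temperature-like). Unique-reflection
counts (1500–3000) are desk-scale stand-ins for the tens of thousands of
a real cubic-insulin-type study; they keep a full 215-data-set pipeline
run under half a minute while preserving the statistical regime
(common-reflection counts per pair in the hundreds to low thousands).
In `sparse_overlap` the group difference is a weak perturbation on
*every* reflection (delta 0.1) rather than a strong one on 5%: with only
~100 common reflections a pair would share just ~10 perturbed ones, and
the between-group correlation deficit would be a heavy-tailed lottery
rather than the systematic signal the sparse-data regime actually
exhibits when differences touch all structure factors weakly.

What passing on these studies does **not** show: robustness to
mis-scaled inputs (scaling is upstream and assumed done), to indexing
ambiguities, to radiation-damage time series within a wedge, to
non-identity symmetry interacting with anisotropic differences, or to
real detector artefacts. The generator's noise is Gaussian and its
sigmas are honest; real uncertainty models can be mis-estimated in ways
no weighting repairs.

## Determinism and degenerate inputs

A single master seed drives the resolution-filter split, every
per-dimension random start (derived as (seed, dimension, restart)), and
synthetic generation; identical inputs and seed reproduce reports
bit-for-bit. Degenerate cases have defined behaviour: incalculable pairs
get zero weight (a data set incalculable against all others triggers a
warning and behaves as an outlier downstream); zero-norm embedded
coordinates receive maximal cosine distance with a warning; fewer than
10 unique groups fall back to a single resolution shell; all-zero weight
matrices, sub-s_min studies and single-cluster Davies–Bouldin requests
raise errors naming the problem.

## Known limitations

The pairwise matrix is O(N^2) in data sets and dominates cost for large
N, as expected. The Ward recurrence on non-Euclidean distances is a
pragmatic convention, not a theoretically clean Ward. The s_min
heuristic assumes the embedding dimension tracks the number of groups;
heavily outlier-inflated dimensionality weakens it. The elbow criterion
needs the residual curve to actually flatten — at very low
common-reflection counts with noisy data the curve decays smoothly and
dimension selection (then clustering) degrades, which is the observed
failure mode of the method rather than a bug.
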