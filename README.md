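# isoclust

Intensity-based isomorphism clustering for multi-crystal X-ray
diffraction experiments.

## The problem

Modern multi-crystal experiments collect small rotation wedges from tens
to hundreds of crystals and merge them into one data set. Crystals that
share a unit cell and space group can still differ systematically — a
bound ligand, a sequence difference, conformational changes — and these
*non-isomorphous* subsets must be separated before merging, or the subtle
signal is averaged away. Unit-cell clustering misses such differences;
the discriminating signal lives in the measured intensities themselves.

`isoclust` implements an uncertainty-aware intensity-clustering pipeline
for this situation, aimed at crystallographers and beamline-pipeline
developers. It is a library with a thin command-line interface, and it is
fully testable on synthetic studies with planted group structure.

## The method

For every pair of data sets *x*, *y*, the Pearson correlation between
merged intensities of their common symmetry-unique reflections is
computed with inverse-variance weights:

    w_i = 1 / (sigma_x_i^2 + sigma_y_i^2)
    r_xy = sum_i w_i (x_i - m_x)(y_i - m_y) /
           sqrt( sum_i w_i (x_i - m_x)^2 * sum_i w_i (y_i - m_y)^2 )

where each merged intensity is the inverse-variance weighted mean of its
symmetry-equivalent observations and m_x, m_y are weighted means. The
Kish effective sample size `n_e = (sum w)^2 / sum w^2` of each pair
supplies its reliability weight `w_xy` in the embedding objective

    Phi(x) = sum_{i<j} w_ij (r_ij - x_i . x_j)^2 ,

minimized over coordinates `x_i` in d dimensions (quasi-Newton descent
from a random start). The dimension d is chosen automatically: Phi is
minimized for every d up to min(N, 50) and the elbow of the residual
curve — the first dimension whose residual reaches the noise floor —
is selected. Clusters are then extracted two ways:

* **Hierarchical**: Ward (default) or average linkage on the distances
  `1 - r_ij` and `1 - cos(x_i, x_j)`, cut at 60% and 70% of the maximum
  merge height (the "isomorphic threshold" range).
* **Density-based (OPTICS)**: on the optimized coordinates, with minimum
  cluster size `s_min = max(5, floor(b N / d))` (b = 0.5) and xi = 0.05
  steep-area extraction. Data sets in no dense region are labeled `-1`
  (outliers).

Partitions are scored with the Davies–Bouldin index and, when true
labels are known, V-Measure (homogeneity/completeness).

## Worked example

```sh
python examples/simulate_and_cluster.py
```

simulates two groups of eight isomorphous data sets whose true
intensities differ only on 5% of reflections (30% r.m.s. perturbation),
then runs the full pipeline:

```
data sets               : 16
resolution filter d_min : 6.95 A
selected dimensions     : 2
OPTICS clusters         : 2
OPTICS labels           : [0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
V-Measure vs truth      : 1.000
Ward HCA @60% V-Measure : 1.000
```

Two dimensions suffice (one shared mode, one group-splitting mode), and
both OPTICS and the thresholded Ward dendrogram recover the planted
groups exactly (V-Measure 1.0). The other scripts in `examples/` show
the sigma-weighting contrast on variable-quality data, the dimension
scan on a planted rank-3 structure, and how to read an OPTICS
reachability profile.

The same pipeline is available from the shell:

```sh
isoclust simulate --preset two_group_small --seed 1 --out study/
isoclust run study/ --truth study/truth.tsv --seed 1 --out results/
```

`results/` then holds `report.json`, the correlation and weight
matrices, coordinates, dendrograms (JSON + Newick), the reachability
table and per-cluster data-set lists.

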