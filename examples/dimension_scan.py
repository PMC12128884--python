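"""Automatic dimensionality selection for the correlation embedding.

The number of dimensions needed grows with the number of systematic
differences between data sets.  Here the correlation matrix is planted
with a rank-3 structure (three orthogonal group directions); the residual
of the embedding objective drops to the noise floor exactly at d = 3, and
the elbow detector picks that dimension.
"""

import numpy as np

from isoclust import PairwiseMatrix, scan_dimensions

rng = np.random.default_rng(0)
vecs = []
for g in range(3):
    axis = np.zeros(3)
    axis[g] = 1.0
    for _ in range(10):
        v = axis + 0.05 * rng.standard_normal(3)
        vecs.append(v / np.linalg.norm(v))
vecs = np.asarray(vecs)
r = vecs @ vecs.T
np.fill_diagonal(r, 1.0)
w = np.ones((30, 30))
np.fill_diagonal(w, 0.0)
m = PairwiseMatrix(
    dataset_ids=[f"ds{i}" for i in range(30)],
    r=r,
    weights=w,
    n_common=np.full((30, 30), 30, dtype=np.int64),
    n_effective=np.full((30, 30), 30.0),
    valid=w > 0,
)

scan = scan_dimensions(m, seed=0)
for d, res in zip(scan.dims_tested[:6], scan.residuals[:6]):
    marker = "  <- selected" if d == scan.selected else ""
    print(f"d={d}: residual = {res:.3e}{marker}")
# The residual falls by orders of magnitude until the planted rank is
# reached, then flattens: the elbow at d=3 is the embedding dimension.
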