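"""Clustering quality metrics: Davies-Bouldin score and V-Measure.

Davies-Bouldin is unsupervised: the mean over clusters of the worst-case
ratio (s_i + s_j) / d(c_i, c_j), with s the mean member-to-centroid
distance; lower is denser and better separated.  V-Measure compares a
predicted partition to known labels through conditional entropies,
combining homogeneity and completeness in a harmonic mean; 1 means
perfect agreement up to relabeling.

Convention for outliers (label -1): excluded from Davies-Bouldin (a noise
class has no meaningful centroid) but kept as their own predicted class in
V-Measure, so spurious outlier calls cost homogeneity/completeness.
"""

from __future__ import annotations

import numpy as np

__all__ = ["davies_bouldin", "v_measure"]


def davies_bouldin(points: np.ndarray, labels) -> float:
    """Davies-Bouldin score of a labeled point set (label -1 excluded).

    ``points`` are feature rows: the rows of the r matrix for correlation
    clustering, or the embedded coordinates for cosine-angle / density
    clustering.  Needs at least two non-outlier clusters.
    """
    x = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    keep = lab != -1
    x, lab = x[keep], lab[keep]
    clusters = np.unique(lab)
    k = len(clusters)
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least two non-outlier clusters")
    centroids = np.stack([x[lab == c].mean(axis=0) for c in clusters])
    scatter = np.array(
        [np.linalg.norm(x[lab == c] - centroids[i], axis=1).mean()
         for i, c in enumerate(clusters)]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / sep
    np.fill_diagonal(ratio, -np.inf)
    return float(np.max(ratio, axis=1).mean())


def v_measure(reference, predicted) -> tuple[float, float, float]:
    """(homogeneity, completeness, v) of predicted labels vs a reference.

    h = 1 - H(C|K)/H(C) and c = 1 - H(K|C)/H(K) from the contingency
    table (0/0 taken as 1); v is their harmonic mean (0 when h + c = 0).
    Predicted label -1 counts as an ordinary predicted class.  Symmetric
    under swapping the two labelings (h and c swap, v is unchanged).
    """
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if len(ref) != len(pred):
        raise ValueError("label vectors must have the same length")
    if len(ref) == 0:
        raise ValueError("empty labelings")
    n = len(ref)
    _, ri = np.unique(ref, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    cont = np.zeros((ri.max() + 1, pi.max() + 1))
    np.add.at(cont, (ri, pi), 1.0)

    h_c = _entropy(cont.sum(axis=1), n)
    h_k = _entropy(cont.sum(axis=0), n)
    h_c_given_k = _conditional_entropy(cont, n)
    h_k_given_c = _conditional_entropy(cont.T, n)
    h = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    v = 0.0 if h + c == 0 else 2.0 * h * c / (h + c)
    return float(h), float(c), float(v)


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _conditional_entropy(cont: np.ndarray, n: int) -> float:
    """H(rows | columns) of a contingency table."""
    col = cont.sum(axis=0)
    total = 0.0
    nz = cont > 0
    for j in range(cont.shape[1]):
        cj = cont[nz[:, j], j]
        total += float((cj * np.log(cj / col[j])).sum())
    return -total / n
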