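"""Agglomerative (hierarchical) clustering of pairwise distance matrices.

Used on the two intensity-derived distances, 1 - r_ij (correlation
clustering) and 1 - cos(x_i, x_j) (cosine-angle clustering).  Ward linkage
is the default: it minimizes the within-cluster variance increase and
avoids the chaining behaviour of average linkage.  The input distances are
treated as Euclidean in the Ward recurrence, the convention shared by the
mainstream linkage implementations; with such non-Euclidean inputs height
inversions are possible and are tolerated.

Cluster labels come from cutting the dendrogram at a fraction of the
maximum merge height — the "isomorphic threshold" proposal cuts the
correlation dendrogram at 60-70% of the maximum Ward distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LinkageTree", "linkage", "cut_at_fraction", "to_newick"]


@dataclass
class LinkageTree:
    """Merge history of an agglomerative clustering.

    Nodes 0..N-1 are the leaves (data sets, in input order); merge t
    creates node N + t.  ``merges`` rows are (left, right, height, size)
    with left < right.
    """

    n_leaves: int
    merges: np.ndarray  # (N-1, 4) float array, scipy linkage layout
    leaf_ids: list[str] | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def linkage(dist: np.ndarray, method: str = "ward") -> LinkageTree:
    """Agglomerate a symmetric distance matrix by Lance-Williams updates.

    ``ward`` reproduces the standard reference recurrence treating the
    input distances as Euclidean; ``average`` is UPGMA.  Ties break
    deterministically toward the smallest (left-index, right-index) pair.
    """
    if method not in ("ward", "average"):
        raise ValueError(f"unknown linkage method {method!r}")
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    bad = np.argwhere(np.isnan(d))
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"NaN distance between entries {int(i)} and {int(j)}")
    if n < 2:
        raise ValueError("need at least two items to cluster")

    d = d.copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.int64)
    node_of = np.arange(n)  # current scipy-style node id of each slot
    merges = np.empty((n - 1, 4))

    for t in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], d, np.inf)
        # row-major argmin -> smallest (i, j) among ties
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = d[i, j]
        ni, nj = sizes[i], sizes[j]
        left, right = node_of[i], node_of[j]
        if left > right:
            left, right = right, left
        merges[t] = (left, right, h, ni + nj)

        k = active.copy()
        k[i] = k[j] = False
        if method == "ward":
            nk = sizes[k]
            new = np.sqrt(
                ((ni + nk) * d[i, k] ** 2 + (nj + nk) * d[j, k] ** 2 - nk * h * h)
                / (ni + nj + nk)
            )
        else:
            new = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
        d[i, k] = new
        d[k, i] = new
        active[j] = False
        sizes[i] = ni + nj
        node_of[i] = n + t
    return LinkageTree(n_leaves=n, merges=merges)


def cut_at_fraction(tree: LinkageTree, fraction: float) -> np.ndarray:
    """Flat labels from severing the tree at fraction x (max merge height).

    Merges at height <= the cut are kept; connected components become
    clusters.  Labels are 0..k-1 in order of first leaf appearance, so
    fraction 1.0 yields a single cluster and a fraction below the smallest
    relative merge height leaves every leaf alone.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = tree.n_leaves
    cut = fraction * tree.heights.max()
    parent = np.arange(2 * n - 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t, (left, right, h, _) in enumerate(tree.merges):
        if h <= cut:
            node = n + t
            parent[find(int(left))] = node
            parent[find(int(right))] = node
    roots = [find(i) for i in range(n)]
    labels = np.empty(n, dtype=np.int64)
    seen: dict[int, int] = {}
    for i, root in enumerate(roots):
        labels[i] = seen.setdefault(root, len(seen))
    return labels


def to_newick(tree: LinkageTree, leaf_ids: list[str] | None = None) -> str:
    """Serialize the dendrogram as Newick with branch length = height gap."""
    n = tree.n_leaves
    ids = leaf_ids or tree.leaf_ids or [f"leaf{i}" for i in range(n)]
    height = {i: 0.0 for i in range(n)}
    node_str = {i: ids[i] for i in range(n)}
    for t, (left, right, h, _) in enumerate(tree.merges):
        left, right = int(left), int(right)
        bl = max(h - height[left], 0.0)
        br = max(h - height[right], 0.0)
        node = n + t
        node_str[node] = f"({node_str[left]}:{bl:.6g},{node_str[right]}:{br:.6g})"
        height[node] = h
    return node_str[2 * n - 2] + ";"
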