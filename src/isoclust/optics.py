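"""Density-based cluster extraction on the embedded coordinates (OPTICS).

OPTICS orders the data sets by spatial density: each point's core distance
is the distance to its s_min-th nearest neighbour (the point itself
counted, matching the mainstream implementation), and the reachability of
a point is the larger of its distance to the expanding point and that
point's core distance.  Clusters appear as valleys of the reachability
profile and are extracted with the xi steep-area method; points in no
extracted cluster are labeled -1 (outliers).  No global density threshold
is needed, so clusters of very different density coexist.

The minimum cluster population follows the heuristic

    s_min = max(5, floor(b * N / d)),

where d, the embedding dimension, proxies the number of distinct groups
and b (default 0.5) buffers against unequal group populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import cluster_optics_xi

__all__ = [
    "OpticsConfig",
    "DensityClusteringResult",
    "derive_s_min",
    "optics_run",
    "reachability_report",
]

S_MIN_FLOOR = 5


@dataclass
class OpticsConfig:
    s_min: int
    xi: float = 0.05
    b: float = 0.5

    def __post_init__(self) -> None:
        if self.s_min < 2:
            raise ValueError("s_min must be >= 2")
        if not 0 < self.xi < 1:
            raise ValueError("xi must lie in (0, 1)")
        if self.b <= 0:
            raise ValueError("b must be positive")


@dataclass
class DensityClusteringResult:
    ordering: np.ndarray  # permutation of dataset indices
    reachability: np.ndarray  # np.inf for expansion starting points
    labels: np.ndarray  # -1 marks outliers
    cluster_count: int
    core_distances: np.ndarray
    predecessor: np.ndarray


def derive_s_min(n_datasets: int, d: int, b: float = 0.5) -> int:
    """Heuristic minimum cluster size: max(5, floor(b * N / d))."""
    if n_datasets < 2 or d < 1 or b <= 0:
        raise ValueError("need n_datasets >= 2, d >= 1, b > 0")
    return max(S_MIN_FLOOR, int(np.floor(b * n_datasets / d)))


def optics_run(coords: np.ndarray, cfg: OpticsConfig) -> DensityClusteringResult:
    """OPTICS ordering, reachability and xi cluster extraction.

    Euclidean metric, unbounded neighbourhood radius.  The expansion
    always continues at the unprocessed point with the smallest current
    reachability (first index on ties), which makes the ordering fully
    deterministic.  Labels come from the xi steep-area extraction with
    predecessor correction; result is invariant under rigid motions of the
    coordinates.
    """
    x = np.asarray(coords, dtype=float)
    n = x.shape[0]
    if n < cfg.s_min:
        raise ValueError(
            f"only {n} data sets but s_min={cfg.s_min}; lower b (or s_min)"
        )
    # exact difference-based Euclidean distances (not the inner-product
    # shortcut): bitwise-stable ordering under ties matters here
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    # core distance: s_min-th smallest including the zero self-distance
    core = np.partition(dist, cfg.s_min - 1, axis=1)[:, cfg.s_min - 1]

    reach = np.full(n, np.inf)
    predecessor = np.full(n, -1, dtype=np.int64)
    processed = np.zeros(n, dtype=bool)
    ordering = np.empty(n, dtype=np.int64)
    for step in range(n):
        unproc = np.flatnonzero(~processed)
        point = unproc[int(np.argmin(reach[unproc]))]
        processed[point] = True
        ordering[step] = point
        todo = unproc[unproc != point]
        if len(todo):
            rdist = np.maximum(dist[point, todo], core[point])
            better = rdist < reach[todo]
            upd = todo[better]
            reach[upd] = rdist[better]
            predecessor[upd] = point

    labels, _ = cluster_optics_xi(
        reachability=reach,
        predecessor=predecessor,
        ordering=ordering,
        min_samples=cfg.s_min,
        xi=cfg.xi,
    )
    labels = np.asarray(labels, dtype=np.int64)
    n_clusters = int(labels.max()) + 1 if (labels >= 0).any() else 0
    return DensityClusteringResult(
        ordering=ordering,
        reachability=reach,
        labels=labels,
        cluster_count=n_clusters,
        core_distances=core,
        predecessor=predecessor,
    )


def reachability_report(
    res: DensityClusteringResult, dataset_ids: list[str] | None = None
) -> list[tuple[int, str, float, int]]:
    """Rows (position, dataset_id, reachability, label) in OPTICS order.

    The machine-readable basis of the reachability plot: cluster
    boundaries show as spikes, clusters as valleys.
    """
    ids = dataset_ids or [str(i) for i in range(len(res.ordering))]
    return [
        (
            pos,
            ids[idx],
            float(res.reachability[idx]),
            int(res.labels[idx]),
        )
        for pos, idx in enumerate(res.ordering)
    ]
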