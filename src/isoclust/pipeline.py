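"""End-to-end isomorphism analysis: read -> filter -> merge -> correlate ->
embed -> cluster (hierarchical + OPTICS) -> evaluate -> report.

Defaults follow the recommended configuration: sigma-weighted correlations,
automatic dimension selection, Ward linkage with both the 60% and 70%
dendrogram cuts reported, OPTICS with xi = 0.05, b = 0.5 and a floor of 5
on the minimum cluster size.  A single master seed makes the whole run
reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hclust, optics
from .correlation import PairwiseMatrix, pairwise_matrix
from .embedding import (
    DimensionScan,
    EmbeddingResult,
    cosine_distance_matrix,
    minimize_objective,
    pca_align,
    scan_dimensions,
)
from .merging import MergedGroupTable, ResolutionFilter, merge_dataset, resolution_cutoff
from .metrics import davies_bouldin, v_measure
from .reflections import CrystalMetadata, ReflectionTable, map_to_asu, read_study
from .synthetic import TruthLabels

logger = logging.getLogger("isoclust")

__all__ = ["PipelineOptions", "PipelineReport", "run_pipeline", "analyze_study"]


@dataclass
class PipelineOptions:
    weighting: str = "sigma"  # "sigma" | "unweighted"
    dimensions: int | None = None  # None => automatic elbow selection
    max_dim: int = 50
    linkage: str = "ward"
    xi: float = 0.05
    b: float = 0.5
    s_min: int | None = None  # None => derive from N, d and b
    cut_fractions: tuple[float, ...] = (0.6, 0.7)
    restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weighting not in ("sigma", "unweighted"):
            raise ValueError("weighting must be 'sigma' or 'unweighted'")


@dataclass
class PipelineReport:
    dataset_ids: list[str]
    d_min: float
    matrix: PairwiseMatrix
    scan: DimensionScan | None
    embedding: EmbeddingResult
    coords_pca: np.ndarray
    explained_variance: list[float]
    trees: dict[str, hclust.LinkageTree]
    labels: dict[str, np.ndarray]
    optics_result: optics.DensityClusteringResult
    s_min: int
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    options: PipelineOptions | None = None

    def summary(self) -> dict:
        """JSON-serializable digest of the run."""
        nc = self.matrix.n_common[np.triu_indices(len(self.dataset_ids), k=1)]
        ne = self.matrix.n_effective[np.triu_indices(len(self.dataset_ids), k=1)]
        return {
            "n_datasets": len(self.dataset_ids),
            "d_min": self.d_min,
            "n_common": {
                "min": int(nc.min()),
                "mean": float(nc.mean()),
                "max": int(nc.max()),
            },
            "n_effective": {
                "min": float(ne.min()),
                "mean": float(ne.mean()),
                "max": float(ne.max()),
            },
            "dimension_scan": None
            if self.scan is None
            else {
                "dims": self.scan.dims_tested,
                "residuals": self.scan.residuals,
                "selected": self.scan.selected,
            },
            "dimension": self.embedding.dimension,
            "embedding_residual": self.embedding.residual,
            "explained_variance_percent": self.explained_variance,
            "s_min": self.s_min,
            "labels": {k: np.asarray(v).tolist() for k, v in self.labels.items()},
            "optics_cluster_count": self.optics_result.cluster_count,
            "metrics": self.metrics,
            "options": None if self.options is None else vars(self.options).copy(),
        }


def analyze_study(
    tables: list[ReflectionTable],
    meta: CrystalMetadata,
    options: PipelineOptions | None = None,
    truth: TruthLabels | None = None,
) -> PipelineReport:
    """Run the full analysis on in-memory reflection tables."""
    opts = options or PipelineOptions()
    if len(tables) < 3:
        raise ValueError("meaningful clustering needs at least 3 data sets")
    ids = [t.dataset_id for t in tables]

    t0 = time.perf_counter()
    asu = [map_to_asu(t, meta) for t in tables]
    merged: list[MergedGroupTable] = [merge_dataset(t, meta) for t in asu]
    d_min = resolution_cutoff(asu, meta, ResolutionFilter(split_seed=opts.seed))
    logger.info("merge+filter: d_min=%.3f A (%.2fs)", d_min, time.perf_counter() - t0)

    t0 = time.perf_counter()
    mode = "sigma_weighted" if opts.weighting == "sigma" else "unweighted"
    matrix = pairwise_matrix(merged, d_min, mode=mode)
    logger.info("pairwise matrix: N=%d (%.2fs)", len(ids), time.perf_counter() - t0)

    t0 = time.perf_counter()
    scan = None
    if opts.dimensions is None:
        scan = scan_dimensions(
            matrix, max_dim=opts.max_dim, seed=opts.seed, restarts=opts.restarts
        )
        dim = scan.selected
    else:
        dim = int(opts.dimensions)
    emb = minimize_objective(matrix, dim, seed=opts.seed, restarts=opts.restarts)
    coords_pca, explained = pca_align(emb)
    logger.info(
        "embedding: d=%d residual=%.3g (%.2fs)",
        dim,
        emb.residual,
        time.perf_counter() - t0,
    )

    dist_corr = 1.0 - matrix.r
    np.fill_diagonal(dist_corr, 0.0)
    dist_corr = np.maximum(dist_corr, 0.0)
    dist_cos = cosine_distance_matrix(emb)
    trees = {
        "correlation": hclust.linkage(dist_corr, method=opts.linkage),
        "cosine": hclust.linkage(dist_cos, method=opts.linkage),
    }
    labels: dict[str, np.ndarray] = {}
    for name, tree in trees.items():
        for frac in opts.cut_fractions:
            labels[f"{name}_hca@{int(round(frac * 100))}"] = hclust.cut_at_fraction(
                tree, frac
            )

    s_min = (
        int(opts.s_min)
        if opts.s_min is not None
        else optics.derive_s_min(len(ids), dim, opts.b)
    )
    ores = optics.optics_run(
        emb.coordinates, optics.OpticsConfig(s_min=s_min, xi=opts.xi, b=opts.b)
    )
    labels["optics"] = ores.labels

    report = PipelineReport(
        dataset_ids=ids,
        d_min=float(d_min),
        matrix=matrix,
        scan=scan,
        embedding=emb,
        coords_pca=coords_pca,
        explained_variance=explained,
        trees=trees,
        labels=labels,
        optics_result=ores,
        s_min=s_min,
        options=opts,
    )
    report.metrics = _score_methods(report, truth)
    return report


def _score_methods(report: PipelineReport, truth: TruthLabels | None) -> dict:
    """Davies-Bouldin (correlation rows vs coordinates) and V-Measure."""
    scores: dict[str, dict[str, float]] = {}
    ref = truth.as_array(report.dataset_ids) if truth is not None else None
    for name, lab in report.labels.items():
        feats = (
            report.matrix.r if name.startswith("correlation") else report.embedding.coordinates
        )
        entry: dict[str, float] = {}
        try:
            entry["davies_bouldin"] = davies_bouldin(feats, lab)
        except ValueError:
            entry["davies_bouldin"] = float("nan")
        if ref is not None:
            h, c, v = v_measure(ref, lab)
            entry.update(homogeneity=h, completeness=c, v_measure=v)
        scores[name] = entry
    return scores


def run_pipeline(
    study_dir,
    options: PipelineOptions | None = None,
    truth: TruthLabels | None = None,
    out_dir=None,
) -> PipelineReport:
    """Analyze a study directory and optionally write all result files."""
    tables, meta = read_study(study_dir)
    report = analyze_study(tables, meta, options, truth)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: PipelineReport, out_dir) -> None:
    """Write report.json, matrices, dendrograms, reachability and cluster lists."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = report.dataset_ids

    (out / "report.json").write_text(json.dumps(report.summary(), indent=1))
    _write_matrix(out / "rij.tsv", report.matrix.r, ids)
    _write_matrix(out / "weights.tsv", report.matrix.weights, ids)

    with open(out / "coords.tsv", "w") as fh:
        dims = report.embedding.dimension
        fh.write("dataset_id\t" + "\t".join(f"x{k}" for k in range(dims)) + "\n")
        for i, name in enumerate(ids):
            row = "\t".join(f"{v:.8g}" for v in report.embedding.coordinates[i])
            fh.write(f"{name}\t{row}\n")

    for key, tree in report.trees.items():
        tag = "corr" if key == "correlation" else "cos"
        (out / f"dendrogram_{tag}.json").write_text(
            json.dumps({"leaves": ids, "merges": tree.merges.tolist()}, indent=1)
        )
        (out / f"dendrogram_{tag}.nwk").write_text(hclust.to_newick(tree, ids) + "\n")

    with open(out / "reachability.tsv", "w") as fh:
        fh.write("position\tdataset_id\treachability\tlabel\n")
        for pos, name, reach, lab in optics.reachability_report(
            report.optics_result, ids
        ):
            fh.write(f"{pos}\t{name}\t{reach:.8g}\t{lab}\n")

    opt_labels = report.labels["optics"]
    for k in range(report.optics_result.cluster_count):
        members = [ids[i] for i in np.flatnonzero(opt_labels == k)]
        (out / f"cluster_{k}.txt").write_text("\n".join(members) + "\n")
    outliers = [ids[i] for i in np.flatnonzero(opt_labels == -1)]
    (out / "outliers.txt").write_text("\n".join(outliers) + ("\n" if outliers else ""))


def _write_matrix(path, mat: np.ndarray, ids: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("dataset_id\t" + "\t".join(ids) + "\n")
        for i, name in enumerate(ids):
            fh.write(name + "\t" + "\t".join(f"{v:.8g}" for v in mat[i]) + "\n")
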