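"""Pairwise correlation coefficients between merged data sets.

Two data sets are compared through the Pearson correlation of the merged
intensities of their common symmetry-unique reflections.  The sigma-weighted
variant weights each term with

    w_i = 1 / (sigma_x_i^2 + sigma_y_i^2),

the reciprocal of the combined variance of the pair of merged intensities,
so poorly measured reflections no longer dominate the statistic.  The Kish
effective sample size

    n_e = (sum w_i)^2 / sum w_i^2

quantifies how many equally weighted reflections the pair is worth; it
supplies the reliability weight w_ij of each pair in the embedding
objective (zero for incalculable pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .merging import MergedGroupTable, PairedMergedSeries, decode_hkl, encode_hkl

__all__ = [
    "PairwiseMatrix",
    "unweighted_cc",
    "weighted_cc",
    "pairwise_matrix",
    "IncalculableDatasetWarning",
]

#: fewest common groups for which a Pearson r is considered calculable
MIN_COMMON = 3


class IncalculableDatasetWarning(UserWarning):
    """A data set has no calculable correlation against any other."""


@dataclass
class PairwiseMatrix:
    """Symmetric pairwise statistics of a study.

    ``r`` holds the correlation coefficients (unit diagonal, clamped to
    [-1, 1]); ``weights`` the reliability weights w_ij (max-normalized
    effective sample sizes, or 1 for constant weighting); ``valid`` masks
    the calculable pairs.  Invalid pairs carry r = 0 and weight 0 and are
    never used downstream.
    """

    dataset_ids: list[str]
    r: np.ndarray
    weights: np.ndarray
    n_common: np.ndarray
    n_effective: np.ndarray
    valid: np.ndarray

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)


def unweighted_cc(series: PairedMergedSeries) -> float:
    """Plain Pearson correlation of the paired merged intensities.

    Returns NaN for incalculable input (fewer than MIN_COMMON entries or a
    degenerate variance); callers turn that into an invalid, zero-weight
    pair.
    """
    x, y = series.x, series.y
    if len(x) < MIN_COMMON:
        return float("nan")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def weighted_cc(series: PairedMergedSeries) -> tuple[float, float]:
    """Sigma-weighted Pearson correlation and Kish effective sample size.

    With equal sigmas this reduces exactly to the unweighted statistic and
    n_e equals the number of common reflections; unequal weights pull n_e
    below n, down to 1 in the limit of a single dominating reflection.
    """
    x, y = series.x, series.y
    if len(x) < MIN_COMMON:
        return float("nan"), 0.0
    w = series.weights
    sw = w.sum()
    n_e = float(sw * sw / (w @ w))
    mx = float(w @ x) / sw
    my = float(w @ y) / sw
    dx = x - mx
    dy = y - my
    sxx = float(w @ (dx * dx))
    syy = float(w @ (dy * dy))
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), n_e
    r = float(w @ (dx * dy)) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0)), n_e


def pairwise_matrix(
    tables: list[MergedGroupTable],
    d_min: float,
    mode: str = "sigma_weighted",
) -> PairwiseMatrix:
    """All-against-all correlation matrix at a single global resolution limit.

    Every unordered pair of data sets is intersected on the canonical
    symmetry-unique indices with d >= d_min and scored with the requested
    correlation.  In ``sigma_weighted`` mode the reliability weight of each
    pair is its effective sample size normalized by the study maximum; in
    ``unweighted`` mode all calculable pairs get weight 1 (n_e is still
    reported).  Incalculable pairs get valid=False and weight 0.
    """
    if mode not in ("sigma_weighted", "unweighted"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(tables)
    if n < 2:
        raise ValueError("pairwise matrix needs at least two data sets")

    ids = [t.dataset_id for t in tables]
    intens, var, col_of = _dense_layout(tables, d_min)

    r = np.zeros((n, n))
    np.fill_diagonal(r, 1.0)
    n_common = np.zeros((n, n), dtype=np.int64)
    n_eff = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=bool)

    observed = np.isfinite(intens)
    for i in range(n):
        for j in range(i + 1, n):
            both = observed[i] & observed[j]
            m = int(both.sum())
            n_common[i, j] = n_common[j, i] = m
            if m < MIN_COMMON:
                continue
            x = intens[i, both]
            y = intens[j, both]
            if mode == "sigma_weighted":
                w = 1.0 / (var[i, both] + var[j, both])
                rij, ne = _wcc_arrays(x, y, w)
            else:
                rij = _ucc_arrays(x, y)
                w = 1.0 / (var[i, both] + var[j, both])
                sw = w.sum()
                ne = float(sw * sw / (w @ w))
            n_eff[i, j] = n_eff[j, i] = ne
            if np.isnan(rij):
                continue
            r[i, j] = r[j, i] = rij
            valid[i, j] = valid[j, i] = True

    weights = np.zeros((n, n))
    if mode == "sigma_weighted":
        max_ne = n_eff[valid].max() if valid.any() else 0.0
        if max_ne > 0:
            weights[valid] = n_eff[valid] / max_ne
    else:
        weights[valid] = 1.0

    isolated = [
        ids[i] for i in range(n) if not valid[i].any()
    ]
    if isolated:
        warnings.warn(
            "no calculable pairwise correlation for data set(s): "
            + ", ".join(isolated),
            IncalculableDatasetWarning,
            stacklevel=2,
        )
    return PairwiseMatrix(
        dataset_ids=ids,
        r=r,
        weights=weights,
        n_common=n_common,
        n_effective=n_eff,
        valid=valid,
    )


def _dense_layout(tables, d_min):
    """Stack merged tables into dense (N, M) intensity/variance arrays over
    the union of canonical indices at d >= d_min (NaN where unobserved)."""
    kept = []
    for t in tables:
        keep = t.d >= d_min
        kept.append((t.hkl[keep], t.intensity[keep], t.sigma[keep]))
    all_hkl = np.concatenate([k[0] for k in kept]) if kept else np.empty((0, 3), int)
    uniq_keys, inv = np.unique(encode_hkl(all_hkl), return_inverse=True)
    uniq = decode_hkl(uniq_keys)
    m = len(uniq_keys)
    n = len(tables)
    intens = np.full((n, m), np.nan)
    var = np.full((n, m), np.nan)
    pos = 0
    for i, (hkl, ii, ss) in enumerate(kept):
        cols = inv[pos : pos + len(hkl)]
        pos += len(hkl)
        intens[i, cols] = ii
        var[i, cols] = ss**2
    return intens, var, uniq


def _ucc_arrays(x: np.ndarray, y: np.ndarray) -> float:
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    return float(np.clip(float(dx @ dy) / np.sqrt(sxx * syy), -1.0, 1.0))


def _wcc_arrays(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    ne = float(sw * sw / (w @ w))
    mx = float(w @ x) / sw
    my = float(w @ y) / sw
    dx = x - mx
    dy = y - my
    sxx = float(w @ (dx * dx))
    syy = float(w @ (dy * dy))
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), ne
    return float(np.clip(float(w @ (dx * dy)) / np.sqrt(sxx * syy), -1.0, 1.0)), ne
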