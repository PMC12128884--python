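"""Inverse-variance merging of symmetry-equivalent observations and the
global resolution filter.

The merged intensity of a symmetry-unique group is the inverse-variance
weighted mean of its observations,

    I_w = sum(I_j / sigma_j^2) / sum(1 / sigma_j^2),

with standard error sigma_w = [sum(1 / sigma_j^2)]^(-1/2).  A single global
resolution limit d_min is chosen for the whole study so every pairwise
correlation is computed on a consistent set of reflections: the data are
pooled, binned into equal-count resolution shells, and the more optimistic
(higher-resolution) of two conservative shell filters is applied —
mean(I)/mean(sigma) > 4.0 and half-split CC1/2 > 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reflections import CrystalMetadata, ReflectionTable, d_spacing

__all__ = [
    "MergedGroupTable",
    "PairedMergedSeries",
    "ResolutionFilter",
    "merge_dataset",
    "common_groups",
    "resolution_cutoff",
]


@dataclass
class MergedGroupTable:
    """Per-dataset merged intensities, one row per symmetry-unique reflection.

    Rows are sorted lexicographically by canonical (h, k, l) so that two
    tables can be intersected deterministically.
    """

    dataset_id: str
    hkl: np.ndarray  # (m, 3) canonical indices, lexicographically sorted
    intensity: np.ndarray  # merged I_w
    sigma: np.ndarray  # SE of the weighted mean
    multiplicity: np.ndarray  # member count per group
    d: np.ndarray  # resolution of each group, angstrom

    def __len__(self) -> int:
        return len(self.hkl)


@dataclass
class PairedMergedSeries:
    """Merged intensities of the reflections two data sets have in common.

    Carries (x_i, sigma_x_i, y_i, sigma_y_i) per common symmetry-unique
    group i, ordered by canonical index.  The per-entry weight used by the
    sigma-weighted correlation is 1 / (sigma_x_i^2 + sigma_y_i^2).
    """

    x: np.ndarray
    sigma_x: np.ndarray
    y: np.ndarray
    sigma_y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.sigma_x = np.asarray(self.sigma_x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        if np.any(self.sigma_x <= 0) or np.any(self.sigma_y <= 0):
            raise ValueError("paired series requires positive sigmas")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / (self.sigma_x**2 + self.sigma_y**2)


@dataclass
class ResolutionFilter:
    """Thresholds for the global resolution cutoff."""

    criterion_i_over_sigma: float = 4.0
    criterion_cc: float = 0.6
    n_shells: int = 10
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion_i_over_sigma <= 0 or self.criterion_cc <= 0:
            raise ValueError("filter thresholds must be positive")


# Packed-integer Miller keys: sorting/uniquing a single int64 per reflection
# is far faster than row-wise operations, and the +offset packing preserves
# lexicographic (h, k, l) order.
_ENC_OFFSET = 2048  # supports |index| <= 2047


def encode_hkl(hkl: np.ndarray) -> np.ndarray:
    if np.abs(hkl).max(initial=0) >= _ENC_OFFSET:
        raise ValueError("Miller index out of packable range (|index| < 2048)")
    h = hkl.astype(np.int64)
    return (
        ((h[:, 0] + _ENC_OFFSET) << 24)
        | ((h[:, 1] + _ENC_OFFSET) << 12)
        | (h[:, 2] + _ENC_OFFSET)
    )


def decode_hkl(keys: np.ndarray) -> np.ndarray:
    out = np.empty((len(keys), 3), dtype=np.int64)
    out[:, 2] = (keys & 0xFFF) - _ENC_OFFSET
    out[:, 1] = ((keys >> 12) & 0xFFF) - _ENC_OFFSET
    out[:, 0] = (keys >> 24) - _ENC_OFFSET
    return out


def merge_dataset(table: ReflectionTable, meta: CrystalMetadata) -> MergedGroupTable:
    """Merge symmetry-equivalent observations of one (ASU-mapped) data set.

    For equal sigmas the merged value reduces to the arithmetic mean with
    SE sigma/sqrt(n); in general the weighted-mean SE never exceeds the
    best single observation's sigma.
    """
    keys = encode_hkl(table.hkl)
    uniq_keys, inverse, counts = np.unique(
        keys, return_inverse=True, return_counts=True
    )
    uniq = decode_hkl(uniq_keys)  # key order == lexicographic hkl order
    w = 1.0 / table.sigma**2
    sum_w = np.bincount(inverse, weights=w)
    sum_wi = np.bincount(inverse, weights=w * table.intensity)
    merged_i = sum_wi / sum_w
    merged_sigma = 1.0 / np.sqrt(sum_w)
    d = np.asarray(d_spacing(uniq, meta.unit_cell))
    return MergedGroupTable(
        dataset_id=table.dataset_id,
        hkl=uniq,
        intensity=merged_i,
        sigma=merged_sigma,
        multiplicity=counts.astype(np.int64),
        d=d,
    )


def common_groups(
    a: MergedGroupTable, b: MergedGroupTable, d_min: float
) -> PairedMergedSeries:
    """Intersect two merged tables at resolution d >= d_min.

    Returns the paired merged intensities in canonical-index order; an
    empty intersection is a valid length-0 series.
    """
    keep_a = a.d >= d_min
    keep_b = b.d >= d_min
    va = encode_hkl(a.hkl[keep_a])
    vb = encode_hkl(b.hkl[keep_b])
    # merged tables have unique keys; intersection comes back key-sorted,
    # i.e. in canonical hkl order
    _, ia, ib = np.intersect1d(va, vb, assume_unique=True, return_indices=True)
    idx_a = np.flatnonzero(keep_a)[ia]
    idx_b = np.flatnonzero(keep_b)[ib]
    return PairedMergedSeries(
        x=a.intensity[idx_a],
        sigma_x=a.sigma[idx_a],
        y=b.intensity[idx_b],
        sigma_y=b.sigma[idx_b],
    )


def resolution_cutoff(
    tables: list[ReflectionTable],
    meta: CrystalMetadata,
    filt: ResolutionFilter | None = None,
) -> float:
    """Global d_min from conservative shell filters on the pooled study.

    All observations (ASU-mapped) are pooled and binned into
    ``filt.n_shells`` equal-count resolution shells.  Two criteria are
    evaluated per shell: mean(I)/mean(sigma) > threshold, and the
    half-split correlation CC1/2 > threshold, where each symmetry group's
    observations are split into two random halves (seeded), each half is
    inverse-variance merged, and the Pearson correlation is taken across
    groups.  Each criterion proposes the inner edge of the
    highest-resolution shell it accepts; the proposal at better resolution
    (smaller d) wins.  Shells where CC1/2 is undefined (fewer than 3 groups
    of multiplicity >= 2) are skipped by the CC criterion.
    """
    if len(tables) < 2:
        raise ValueError("resolution cutoff needs at least two data sets")
    filt = filt or ResolutionFilter()
    hkl = np.concatenate([t.hkl for t in tables])
    intensity = np.concatenate([t.intensity for t in tables])
    sigma = np.concatenate([t.sigma for t in tables])
    d = np.asarray(d_spacing(hkl, meta.unit_cell))

    uniq_keys, gidx = np.unique(encode_hkl(hkl), return_inverse=True)
    n_groups = len(uniq_keys)
    n_shells = filt.n_shells if n_groups >= filt.n_shells else 1

    # shell edges: equal observation counts, descending d
    order = np.argsort(-d, kind="stable")
    edges_idx = np.array_split(order, n_shells)
    rng = np.random.default_rng(filt.split_seed)

    d_min_isig = None
    d_min_cc = None
    for shell in edges_idx:
        if len(shell) == 0:
            continue
        shell_d_min = float(d[shell].min())
        i_over_sig = intensity[shell].mean() / sigma[shell].mean()
        if i_over_sig > filt.criterion_i_over_sigma:
            d_min_isig = shell_d_min
        cc_half = _shell_cc_half(intensity[shell], sigma[shell], gidx[shell], rng)
        if cc_half is not None and cc_half > filt.criterion_cc:
            d_min_cc = shell_d_min

    proposals = [p for p in (d_min_isig, d_min_cc) if p is not None]
    if not proposals:
        # nothing passes: keep only the lowest-resolution shell
        first = next(s for s in edges_idx if len(s))
        return float(d[first].min())
    return min(proposals)


def _shell_cc_half(
    intensity: np.ndarray, sigma: np.ndarray, gidx: np.ndarray, rng
) -> float | None:
    """Half-split CC1/2 of one shell; None when undefined.

    Observations of each symmetry group are split randomly into two halves
    (the extra observation of an odd count goes to the first half), each
    half is inverse-variance merged, and the Pearson correlation is taken
    across groups with both halves populated.
    """
    _, inv = np.unique(gidx, return_inverse=True)
    n_g = inv.max() + 1
    perm = rng.permutation(len(inv))
    order = np.lexsort((perm, inv))  # random order within each group
    inv_sorted = inv[order]
    counts = np.bincount(inv_sorted, minlength=n_g)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    rank = np.arange(len(inv)) - starts[inv_sorted]
    first_half = rank < (counts[inv_sorted] + 1) // 2
    # inverse-variance merge per (group, half)
    key = inv_sorted * 2 + (~first_half)
    w = 1.0 / sigma[order] ** 2
    sw = np.bincount(key, weights=w, minlength=2 * n_g)
    swi = np.bincount(key, weights=w * intensity[order], minlength=2 * n_g)
    both = (sw[0::2] > 0) & (sw[1::2] > 0)
    if both.sum() < 3:
        return None
    x = swi[0::2][both] / sw[0::2][both]
    y = swi[1::2][both] / sw[1::2][both]
    if np.var(x) == 0 or np.var(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
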