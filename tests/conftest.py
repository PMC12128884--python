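import numpy as np
import pytest

from isoclust import CrystalMetadata, PairwiseMatrix, ReflectionTable


@pytest.fixture
def cubic_meta():
    """Identity-only cubic cell, Friedel pairs merged."""
    return CrystalMetadata(unit_cell=(78, 78, 78, 90, 90, 90))


def make_table(dataset_id, hkl, intensity, sigma=None):
    intensity = np.asarray(intensity, dtype=float)
    if sigma is None:
        sigma = np.ones_like(intensity)
    return ReflectionTable(
        dataset_id=dataset_id, hkl=np.asarray(hkl), intensity=intensity, sigma=sigma
    )


def planted_matrix(vectors, weights=None):
    """PairwiseMatrix whose r is the Gram matrix of the given row vectors."""
    v = np.asarray(vectors, dtype=float)
    n = len(v)
    r = v @ v.T
    np.fill_diagonal(r, 1.0)
    if weights is None:
        weights = np.ones((n, n))
    w = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    valid = w > 0
    return PairwiseMatrix(
        dataset_ids=[f"ds{i}" for i in range(n)],
        r=r,
        weights=w,
        n_common=np.full((n, n), 100, dtype=np.int64),
        n_effective=np.full((n, n), 100.0),
        valid=valid,
    )


def group_unit_vectors(n_groups, per_group, rng=None, jitter=0.0):
    """Unit vectors clustered along n_groups orthogonal axes."""
    rng = rng or np.random.default_rng(0)
    vecs = []
    for g in range(n_groups):
        base = np.zeros(n_groups)
        base[g] = 1.0
        for _ in range(per_group):
            v = base + jitter * rng.standard_normal(n_groups)
            vecs.append(v / np.linalg.norm(v))
    return np.asarray(vecs)
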