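"""Inverse-variance merging and the global resolution filter."""

import numpy as np
import pytest

from isoclust import (
    CrystalMetadata,
    ResolutionFilter,
    common_groups,
    map_to_asu,
    merge_dataset,
    resolution_cutoff,
)

from .conftest import make_table


class TestMergeDataset:
    def test_equal_sigma_is_mean_with_sqrt_n_error(self, cubic_meta):
        t = make_table("a", [(1, 2, 3)] * 4, [10.0] * 4, [2.0] * 4)
        m = merge_dataset(t, cubic_meta)
        assert len(m) == 1
        assert m.intensity[0] == pytest.approx(10.0)
        assert m.sigma[0] == pytest.approx(1.0)  # 2 / sqrt(4)
        assert m.multiplicity[0] == 4

    def test_hand_worked_weighted_mean(self, cubic_meta):
        # (10, 1) and (20, 2): I_w = (10 + 5) / 1.25 = 12, SE = 1.25^-0.5
        t = make_table("a", [(1, 0, 0)] * 2, [10.0, 20.0], [1.0, 2.0])
        m = merge_dataset(t, cubic_meta)
        assert m.intensity[0] == pytest.approx(12.0, abs=1e-12)
        assert m.sigma[0] == pytest.approx(1.25**-0.5, abs=1e-12)

    def test_single_observation_passthrough(self, cubic_meta):
        m = merge_dataset(make_table("a", [(1, 2, 3)], [7.0], [0.3]), cubic_meta)
        assert m.intensity[0] == pytest.approx(7.0)
        assert m.sigma[0] == pytest.approx(0.3)
        assert m.multiplicity[0] == 1

    def test_permutation_invariance(self, cubic_meta):
        rng = np.random.default_rng(2)
        hkl = [(1, 0, 0)] * 3 + [(2, 1, 0)] * 2 + [(3, 1, 1)]
        i = rng.uniform(1, 10, 6)
        s = rng.uniform(0.1, 2, 6)
        perm = rng.permutation(6)
        m1 = merge_dataset(make_table("a", hkl, i, s), cubic_meta)
        m2 = merge_dataset(
            make_table("a", np.asarray(hkl)[perm], i[perm], s[perm]), cubic_meta
        )
        np.testing.assert_array_equal(m1.hkl, m2.hkl)
        np.testing.assert_allclose(m1.intensity, m2.intensity, rtol=1e-14)
        np.testing.assert_allclose(m1.sigma, m2.sigma, rtol=1e-14)

    def test_sigma_never_exceeds_best_member_and_shrinks(self, cubic_meta):
        rng = np.random.default_rng(8)
        sig = rng.uniform(0.2, 3.0, 6)
        prev = np.inf
        for n in range(2, 7):
            m = merge_dataset(
                make_table("a", [(1, 1, 1)] * n, np.ones(n), sig[:n]), cubic_meta
            )
            assert m.sigma[0] <= sig[:n].min() + 1e-12
            assert m.sigma[0] <= prev + 1e-12
            prev = m.sigma[0]


class TestCommonGroups:
    def test_self_intersection(self, cubic_meta):
        m = merge_dataset(
            make_table("a", [(1, 0, 0), (2, 0, 0), (3, 0, 0)], [1.0, 2.0, 3.0]),
            cubic_meta,
        )
        s = common_groups(m, m, d_min=0.0)
        assert len(s) == 3
        np.testing.assert_allclose(s.x, s.y)

    def test_disjoint_sets_empty(self, cubic_meta):
        a = merge_dataset(make_table("a", [(1, 0, 0)], [1.0]), cubic_meta)
        b = merge_dataset(make_table("b", [(2, 0, 0)], [1.0]), cubic_meta)
        assert len(common_groups(a, b, d_min=0.0)) == 0

    def test_d_min_excludes_high_resolution_groups(self, cubic_meta):
        # d for (1,0,0), (2,0,0), (3,0,0): 78, 39, 26 A
        hkl = [(1, 0, 0), (2, 0, 0), (3, 0, 0)]
        a = merge_dataset(make_table("a", hkl, [1.0, 2.0, 3.0]), cubic_meta)
        b = merge_dataset(make_table("b", hkl, [4.0, 5.0, 6.0]), cubic_meta)
        assert len(common_groups(a, b, d_min=30.0)) == 2


def _pooled_study(n_unique, n_datasets, noise, sigma_fn, rng, cell=(78, 78, 78, 90, 90, 90)):
    """Simple multi-dataset study on a cubic index grid for filter tests."""
    from isoclust.synthetic import _cubic_grid_indices

    hkl = _cubic_grid_indices(n_unique)
    j = rng.exponential(1.0, n_unique) + 0.5
    meta = CrystalMetadata(unit_cell=cell)
    tables = []
    for i in range(n_datasets):
        mult = 2
        rows = np.repeat(np.arange(n_unique), mult)
        sigma = sigma_fn(hkl[rows], j[rows])
        intensity = j[rows] + noise * sigma * rng.standard_normal(len(rows))
        tables.append(make_table(f"d{i}", hkl[rows], intensity, sigma))
    return tables, meta, hkl


class TestResolutionCutoff:
    def test_noiseless_identical_data_keeps_everything(self, cubic_meta):
        rng = np.random.default_rng(0)
        tables, meta, hkl = _pooled_study(
            200, 3, 0.0, lambda h, j: 0.05 * np.sqrt(j), rng
        )
        d_min = resolution_cutoff(tables, meta)
        from isoclust import d_spacing

        best = d_spacing(hkl, meta.unit_cell).min()
        assert d_min == pytest.approx(best)

    def test_cc_criterion_sets_the_better_resolution(self):
        # I/sigma fails in the high-resolution shells (huge claimed sigma)
        # but the data are nearly exact, so CC1/2 ~ 1 everywhere and the
        # CC filter proposes the best resolution, which wins.
        rng = np.random.default_rng(1)

        def sigma_fn(hkl, j):
            from isoclust import d_spacing

            d = d_spacing(hkl, (78, 78, 78, 90, 90, 90))
            lowres_cut = np.quantile(d, 0.25)
            return np.where(d <= lowres_cut, 10.0 * (j + 1), 0.01 * np.sqrt(j))

        tables, meta, hkl = _pooled_study(400, 3, 0.001, sigma_fn, rng)
        from isoclust import d_spacing

        d_all = d_spacing(hkl, meta.unit_cell)
        d_min = resolution_cutoff(tables, meta)
        assert d_min == pytest.approx(d_all.min())

    def test_deterministic_given_split_seed(self):
        rng = np.random.default_rng(4)
        tables, meta, _ = _pooled_study(
            300, 3, 1.0, lambda h, j: 0.4 * np.sqrt(j + 1), rng
        )
        f = ResolutionFilter(split_seed=17)
        assert resolution_cutoff(tables, meta, f) == resolution_cutoff(
            tables, meta, ResolutionFilter(split_seed=17)
        )

    def test_single_shell_fallback_under_ten_groups(self, cubic_meta):
        tables = [
            make_table("a", [(1, 0, 0), (2, 0, 0)] * 2, [5.0, 6.0, 5.1, 6.1],
                       [0.1] * 4),
            make_table("b", [(1, 0, 0), (2, 0, 0)] * 2, [5.0, 6.0, 5.2, 6.2],
                       [0.1] * 4),
        ]
        d_min = resolution_cutoff(tables, cubic_meta)
        assert d_min == pytest.approx(39.0)  # the single shell's inner edge
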