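"""Unweighted and sigma-weighted correlation coefficients, Kish n_e, and
the pairwise matrix."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoclust import (
    CrystalMetadata,
    IncalculableDatasetWarning,
    PairedMergedSeries,
    merge_dataset,
    pairwise_matrix,
    unweighted_cc,
    weighted_cc,
)
from isoclust.synthetic import _cubic_grid_indices

from .conftest import make_table


def series(x, y, sx=None, sy=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return PairedMergedSeries(
        x=x,
        sigma_x=np.ones_like(x) if sx is None else np.asarray(sx, float),
        y=y,
        sigma_y=np.ones_like(y) if sy is None else np.asarray(sy, float),
    )


class TestUnweightedCC:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            # frozen from direct Pearson evaluation: 48 / sqrt(42 * 78)
            ([1, 2, 4], [2, 1, 5], 0.8386278693775346),
        ],
    )
    def test_examples(self, x, y, expected):
        assert unweighted_cc(series(x, y)) == pytest.approx(expected, abs=1e-12)

    def test_too_short_or_degenerate_is_nan(self):
        assert np.isnan(unweighted_cc(series([1, 2], [1, 2])))
        assert np.isnan(unweighted_cc(series([1, 1, 1], [1, 2, 3])))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = unweighted_cc(series(x, y))
        assert unweighted_cc(series(3.7 * x + 11, y)) == pytest.approx(base, abs=1e-12)


class TestWeightedCC:
    def test_equal_sigma_limit_matches_unweighted(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=30)
            y = x + rng.normal(size=30)
            s = series(x, y, np.full(30, 0.7), np.full(30, 0.7))
            r_w, n_e = weighted_cc(s)
            assert r_w == pytest.approx(unweighted_cc(series(x, y)), abs=1e-12)
            assert n_e == pytest.approx(30.0)

    def test_kish_effective_sample_size_value(self):
        # weights (1000, 1, 1): n_e = 1002^2 / 1000002
        sig = np.sqrt(1.0 / (2 * np.array([1000.0, 1.0, 1.0])))
        s = series([1.0, 2.0, 4.0], [2.0, 1.0, 5.0], sig, sig)
        _, n_e = weighted_cc(s)
        assert n_e == pytest.approx(1002**2 / 1000002, rel=1e-12)

    def test_identical_series_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(1.0, 25)
        s = series(x, x, rng.uniform(0.1, 3, 25), rng.uniform(0.1, 3, 25))
        r, _ = weighted_cc(s)
        assert r == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=50.0), min_size=3, max_size=40)
    )
    def test_kish_bounds(self, sigmas):
        """1 <= n_e <= n, with n_e = n exactly iff all weights are equal."""
        sig = np.asarray(sigmas)
        n = len(sig)
        x = np.linspace(0, 1, n)
        _, n_e = weighted_cc(series(x, x, sig, sig))
        assert 1.0 - 1e-9 <= n_e <= n + 1e-9
        w = 1.0 / (2 * sig**2)
        if np.allclose(w, w[0], rtol=1e-12):
            assert n_e == pytest.approx(n)
        elif np.ptp(w) / w.max() > 1e-6:
            assert n_e < n


def _merged_tables_for(n_sets, n_unique, cubic_meta, rng, sigma_profile=None,
                       group_of=None, delta=0.0):
    """Merged tables over a shared grid with optional group structure."""
    hkl = _cubic_grid_indices(n_unique)
    j = rng.exponential(1.0, n_unique)
    shift = {g: rng.standard_normal(n_unique) for g in set(group_of or [0] * n_sets)}
    tables = []
    for i in range(n_sets):
        g = group_of[i] if group_of else 0
        truth = j * np.exp(delta * shift[g]) if delta else j
        sigma = sigma_profile(j) if sigma_profile else np.full(n_unique, 0.1)
        intensity = truth + sigma * rng.standard_normal(n_unique)
        tables.append(
            merge_dataset(make_table(f"d{i}", hkl, intensity, sigma), cubic_meta)
        )
    return tables


class TestPairwiseMatrix:
    def test_copies_of_one_dataset_correlate_perfectly(self, cubic_meta):
        hkl = _cubic_grid_indices(50)
        vals = np.random.default_rng(0).exponential(1.0, 50)
        tables = [
            merge_dataset(make_table(f"d{i}", hkl, vals, np.full(50, 0.5)), cubic_meta)
            for i in range(4)
        ]
        m = pairwise_matrix(tables, d_min=0.0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(m.r[off], 1.0, atol=1e-12)
        assert m.valid[off].all()

    def test_disjoint_pair_flagged_invalid(self, cubic_meta):
        hkl = _cubic_grid_indices(20)
        t1 = merge_dataset(make_table("a", hkl[:10], np.ones(10)), cubic_meta)
        t2 = merge_dataset(make_table("b", hkl[10:], np.ones(10)), cubic_meta)
        t3 = merge_dataset(make_table("c", hkl, np.ones(20)), cubic_meta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IncalculableDatasetWarning)
            m = pairwise_matrix([t1, t2, t3], d_min=0.0)
        assert not m.valid[0, 1]
        assert m.weights[0, 1] == 0.0
        assert m.r[0, 1] == 0.0

    def test_isolated_dataset_warns(self, cubic_meta):
        hkl = _cubic_grid_indices(40)
        a = merge_dataset(make_table("a", hkl[:20], np.ones(20)), cubic_meta)
        b = merge_dataset(
            make_table("b", hkl[:20], np.arange(20.0) + 1), cubic_meta
        )
        lone = merge_dataset(make_table("lone", hkl[38:], np.ones(2)), cubic_meta)
        with pytest.warns(IncalculableDatasetWarning, match="lone"):
            pairwise_matrix([a, b, lone], d_min=0.0)

    def test_symmetric_and_bit_reproducible(self, cubic_meta):
        rng = np.random.default_rng(5)
        tables = _merged_tables_for(5, 100, cubic_meta, rng)
        m1 = pairwise_matrix(tables, d_min=0.0)
        m2 = pairwise_matrix(tables, d_min=0.0)
        np.testing.assert_array_equal(m1.r, m1.r.T)
        np.testing.assert_array_equal(m1.r, m2.r)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.n_effective, m2.n_effective)

    def test_two_group_study_separates_in_mean_r(self, cubic_meta):
        rng = np.random.default_rng(9)
        group_of = [0] * 4 + [1] * 4
        tables = _merged_tables_for(
            8, 400, cubic_meta, rng, group_of=group_of, delta=0.3
        )
        m = pairwise_matrix(tables, d_min=0.0)
        lab = np.asarray(group_of)
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(8, 1)
        assert m.r[iu][same[iu]].mean() > m.r[iu][~same[iu]].mean()

    def test_sigma_weighting_widens_the_group_gap(self, cubic_meta):
        """With a minority of reflections carrying large sigma, the
        within-minus-between gap is larger sigma-weighted than unweighted
        (median over seeds) — the mechanism that rescues noisy studies."""
        gaps_w, gaps_u = [], []
        lab = np.asarray([0] * 4 + [1] * 4)
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(8, 1)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = rng.random(300) < 0.25

            def profile(j, noisy=noisy):
                s = 0.05 * np.sqrt(j + 1)
                return np.where(noisy, 20 * s, s)

            tables = _merged_tables_for(
                8, 300, cubic_meta, rng, sigma_profile=profile,
                group_of=list(lab), delta=0.3,
            )
            for mode, out in (("sigma_weighted", gaps_w), ("unweighted", gaps_u)):
                m = pairwise_matrix(tables, d_min=0.0, mode=mode)
                r = m.r[iu]
                out.append(r[same[iu]].mean() - r[~same[iu]].mean())
        assert np.median(gaps_w) > np.median(gaps_u)
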