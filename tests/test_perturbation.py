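"""Perturbation-graph generation: statistics and edge-selection rules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pgtr.dataset import ExpressionDataset
from pgtr.perturbation import (
    CorrelationBundle,
    DegenerateDataWarning,
    build_pg1,
    build_pg2,
    build_pg_new,
    compute_conditional_correlation,
    compute_zc,
    compute_zscores,
    minmax_offdiag,
)


def _dataset(wt, ko, ids=None):
    n = len(wt)
    return ExpressionDataset(ids or [f"G{k + 1}" for k in range(n)],
                             np.asarray(wt, float), np.asarray(ko, float))


class TestZScores:
    def test_matches_hand_computation(self):
        # column 0 measurements are {3 (wt), 1, 2, 4, 5}: mu=3, sd=1.5811
        wt = [3.0, 1.0, 1.0, 1.0]
        ko = np.ones((4, 4))
        ko[:, 0] = [1.0, 2.0, 4.0, 5.0]
        ko[:, 1:] = np.random.default_rng(0).uniform(0.5, 2, (4, 3))
        zb = compute_zscores(_dataset(wt, ko))
        assert zb.mu[0] == pytest.approx(3.0)
        assert zb.sigma[0] == pytest.approx(1.5811, abs=1e-4)
        assert zb.Z[3, 0] == pytest.approx(1.2649, abs=1e-4)

    def test_zero_when_measurement_equals_mean(self):
        wt = [2.0, 5.0, 1.0]
        ko = np.array([[1.0, 4.0, 1.5], [2.0, 6.0, 0.5], [3.0, 5.0, 2.0]])
        zb = compute_zscores(_dataset(wt, ko))
        # column 0 values {2,1,2,3}: mean 2, so ko[1,0]=2 has z exactly 0
        assert zb.Z[1, 0] == 0.0

    def test_constant_column_warns_and_zeroes(self):
        wt = [1.0, 2.0]
        ko = np.array([[1.0, 3.0], [1.0, 1.0]])
        with pytest.warns(DegenerateDataWarning):
            zb = compute_zscores(_dataset(wt, ko))
        assert np.all(zb.Z[:, 0] == 0)
        assert zb.degenerate_columns == [0]

    def test_reconstruction_from_stored_statistics(self, random_dataset):
        zb = compute_zscores(random_dataset)
        rebuilt = (random_dataset.ko - zb.mu) / zb.sigma
        assert np.allclose(zb.Z, rebuilt, rtol=1e-12, atol=0)


class TestConditionalCorrelation:
    def test_perfect_linear_dependence(self):
        rng = np.random.default_rng(1)
        n = 4
        ko = rng.uniform(1, 3, (n, n))
        ko[:, 1] = 2.0 * ko[:, 0]          # gene 1 tracks gene 0
        ko[:, 2] = -ko[:, 0] + 10.0        # gene 2 mirrors gene 0
        wt = np.array([1.5, 3.0, 8.5, 2.0])
        cb = compute_conditional_correlation(_dataset(wt, ko))
        assert cb.C[0, 1] == pytest.approx(1.0)
        assert cb.C[0, 2] == pytest.approx(-1.0)

    def test_matches_scipy_on_retained_rows(self):
        """drop_j retains the wild type plus every knockout row except j's."""
        rng = np.random.default_rng(2)
        n = 5
        wt = rng.uniform(1, 2, n)
        ko = rng.uniform(0.5, 3, (n, n))
        cb = compute_conditional_correlation(_dataset(wt, ko))
        X = np.vstack([wt, ko])
        for i, j in [(0, 1), (3, 2), (4, 0)]:
            keep = [r for r in range(n + 1) if r != j + 1]
            expected = stats.pearsonr(X[keep, i], X[keep, j]).statistic
            assert cb.C[i, j] == pytest.approx(expected, abs=1e-12)

    def test_frozen_four_point_example(self):
        """Four retained measurements (1,2,3,5) vs (2,1,4,6) -> r = 0.90224."""
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 6.0])
        r = stats.pearsonr(x, y).statistic
        # hand computation: cov-sum 10.25, ss 8.75 and 14.75
        assert r == pytest.approx(10.25 / np.sqrt(8.75 * 14.75), abs=1e-12)
        assert r == pytest.approx(0.90224, abs=5e-6)
        # same pair embedded in a dataset: wt row + 3 retained knockout rows
        wt = np.array([1.0, 2.0, 1.0, 1.0])
        ko = np.zeros((4, 4))
        # drop_j for target gene 1 discards knockout row 1
        ko[:, 0] = [2.0, 50.0, 3.0, 5.0]
        ko[:, 1] = [1.0, 7.0, 4.0, 6.0]
        ko[:, 2] = [1.1, 0.9, 1.3, 0.8]
        ko[:, 3] = [0.9, 1.2, 0.7, 1.4]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            cb = compute_conditional_correlation(_dataset(wt, ko))
        assert cb.C[0, 1] == pytest.approx(r, abs=1e-12)

    def test_drop_both_rule_matches_scipy(self):
        rng = np.random.default_rng(3)
        n = 5
        wt = rng.uniform(1, 2, n)
        ko = rng.uniform(0.5, 3, (n, n))
        cb = compute_conditional_correlation(
            _dataset(wt, ko), exclusion_rule="drop_i_and_j"
        )
        X = np.vstack([wt, ko])
        for i, j in [(0, 1), (2, 4)]:
            keep = [r for r in range(n + 1) if r not in (i + 1, j + 1)]
            expected = stats.pearsonr(X[keep, i], X[keep, j]).statistic
            assert cb.C[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_pair_warns(self):
        wt = [1.0, 1.0, 2.0]
        ko = np.array([[1.0, 2.0, 1.0], [1.0, 3.0, 2.0], [1.0, 1.0, 3.0]])
        with pytest.warns(DegenerateDataWarning):
            cb = compute_conditional_correlation(_dataset(wt, ko))
        assert cb.C[0, 1] == 0.0


class TestZcStandardization:
    def test_column_standardization_and_offset(self):
        # column 3 off-diagonal |C| = (0.1, 0.2, 0.3) -> (-1, 0, 1) pre-shift
        C = np.array(
            [
                [np.nan, 0.5, 0.6, 0.1],
                [0.4, np.nan, 0.7, -0.2],
                [0.3, 0.2, np.nan, 0.3],
                [0.6, 0.1, 0.8, np.nan],
            ]
        )
        cb = compute_zc(CorrelationBundle(C=C))
        pre = cb.Zc[:, 3] - cb.offset
        assert pre[[0, 1, 2]] == pytest.approx([-1.0, 0.0, 1.0])
        offdiag = ~np.eye(4, dtype=bool)
        assert np.nanmin(cb.Zc[offdiag]) == pytest.approx(1e-6, abs=0)
        assert np.all(cb.Zc[offdiag] > 0)


class TestPGBuilders:
    def _bundles(self, ds, beta=2.0, gamma=0.05):
        zb = compute_zscores(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            cb = compute_zc(compute_conditional_correlation(ds))
        return zb, cb

    def test_pg1_strict_threshold(self, random_dataset):
        zb = compute_zscores(random_dataset)
        z_val = abs(zb.Z[0, 1])
        pg_hit = build_pg1(zb, z_val - 1e-9)
        pg_miss = build_pg1(zb, z_val)
        assert (0, 1) in pg_hit.edges
        assert (0, 1) not in pg_miss.edges  # equality does not pass
        assert pg_hit.edges[(0, 1)] == 0    # unsigned

    def test_pg1_infinite_threshold_keeps_wr(self, random_dataset):
        zb = compute_zscores(random_dataset)
        pg = build_pg1(zb, np.inf)
        assert not pg.edges
        offdiag = ~np.eye(pg.n, dtype=bool)
        assert np.isfinite(pg.Wr[offdiag]).all()

    def test_pg2_sign_and_weight(self):
        rng = np.random.default_rng(4)
        n = 5
        wt = np.full(n, 5.0)
        ko = rng.uniform(4.4, 5.6, (n, n))
        ko[0, 1] = 3.0  # knocking out gene 0 lowers gene 1: positive edge
        ds = _dataset(wt, ko)
        zb, cb = self._bundles(ds)
        pg = build_pg2(ds, zb, cb, beta=1.5, gamma=0.05)
        assert pg.edges[(0, 1)] == 1
        assert pg.Wt[0, 1] == pytest.approx(1.0 - abs(cb.C[0, 1]))
        # same deviation but gamma above it: edge vanishes
        pg_hi = build_pg2(ds, zb, cb, beta=1.5, gamma=2.5)
        assert (0, 1) not in pg_hi.edges

    def test_pgnew_sign_consistency_rules(self, small_benchmark):
        _, ds = small_benchmark
        zb, cb = self._bundles(ds)
        pg = build_pg_new(zb, cb, beta=2.0, gamma=0.05)
        assert pg.edges, "benchmark PG should not be empty"
        for (i, j), sign in pg.edges.items():
            assert cb.C[i, j] * zb.Z[i, j] < 0
            assert abs(zb.Z[i, j]) > 2.0
            assert abs(cb.C[i, j]) > 0.05
            assert sign == (1 if zb.Z[i, j] < 0 else -1)
            assert pg.Wt[i, j] == pytest.approx(1.0 - cb.Zc[i, j])

    def test_pgnew_rejects_sign_agreement(self):
        """C*Z > 0 (or |C| under gamma) blocks an otherwise strong edge."""
        rng = np.random.default_rng(6)
        n = 5
        wt = np.full(n, 1.0)
        ko = rng.uniform(0.9, 1.1, (n, n))
        ko[0, 1] = 2.0  # strong positive z for (0, 1)
        ds = _dataset(wt, ko)
        zb, cb = self._bundles(ds)
        z, c = zb.Z[0, 1], cb.C[0, 1]
        pg = build_pg_new(zb, cb, beta=min(2.0, abs(z) - 0.1), gamma=0.0)
        if c * z > 0:
            assert (0, 1) not in pg.edges
        pg_hi_gamma = build_pg_new(zb, cb, beta=0.5, gamma=abs(c) + 0.01)
        assert (0, 1) not in pg_hi_gamma.edges

    def test_wr_minmax_range(self, small_benchmark):
        _, ds = small_benchmark
        zb, cb = self._bundles(ds)
        for pg in (
            build_pg1(zb, 2.0, ds.gene_ids),
            build_pg2(ds, zb, cb, 2.0, 0.05),
            build_pg_new(zb, cb, 2.0, 0.05, ds.gene_ids),
        ):
            offdiag = ~np.eye(pg.n, dtype=bool)
            vals = pg.Wr[offdiag]
            assert vals.min() == 0.0 and vals.max() == 1.0
            assert not pg.has_edge(0, 0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        beta_lo=st.floats(0.1, 1.5),
        delta=st.floats(0.05, 1.5),
    )
    def test_threshold_monotonicity(self, seed, beta_lo, delta):
        """Raising beta or gamma never adds an edge, for every PG flavour."""
        rng = np.random.default_rng(seed)
        n = 6
        wt = rng.uniform(0.5, 2, n)
        ko = rng.uniform(0.2, 2.5, (n, n))
        ds = _dataset(wt, ko)
        zb = compute_zscores(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            cb = compute_zc(compute_conditional_correlation(ds))
        lo, hi = beta_lo, beta_lo + delta
        assert set(build_pg1(zb, hi).edges) <= set(build_pg1(zb, lo).edges)
        assert set(build_pg2(ds, zb, cb, hi, 0.1).edges) <= set(
            build_pg2(ds, zb, cb, lo, 0.1).edges
        )
        g_lo, g_hi = 0.05, 0.05 + delta / 4
        assert set(build_pg_new(zb, cb, lo, g_hi).edges) <= set(
            build_pg_new(zb, cb, lo, g_lo).edges
        )


def test_minmax_constant_matrix_maps_to_zero():
    M = np.full((3, 3), 0.7)
    out = minmax_offdiag(M)
    offdiag = ~np.eye(3, dtype=bool)
    assert np.all(out[offdiag] == 0.0)
    assert np.isnan(out[0, 0])
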