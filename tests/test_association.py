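"""Correlation CIs, nested F-tests, DHS windows and mark clustering."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from capra.association import (
    bedgraph_window_means,
    dhs_window_stats,
    exclude_tss_proximal,
    nested_f_test,
    pearson_with_ci,
    ptm_cluster,
)
from capra.core import GeneModel, GenomicInterval, MidpointTrack


def brute_force_f(y, a, b):
    """Independent normal-equations least-squares oracle."""
    y = np.asarray(y, float)
    n = y.size

    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones(n)
    sse_r = sse(np.column_stack([ones, a]))
    sse_f = sse(np.column_stack([ones, a, b]))
    return ((sse_r - sse_f) / 1) / (sse_f / (n - 3))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = pearson_with_ci([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)

    def test_fisher_ci_closed_form(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=500), rng.normal(size=500)
        res = pearson_with_ci(x, y)
        half = 1.959963984540054 / np.sqrt(500 - 3)
        assert res.ci_low == pytest.approx(np.tanh(np.arctanh(res.r) - half))
        assert res.ci_high == pytest.approx(np.tanh(np.arctanh(res.r) + half))
        assert res.ci_low <= res.r <= res.ci_high

    def test_degenerate_input(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        base = pearson_with_ci(x, y)
        scaled = pearson_with_ci(3 * x + 10, y)
        assert scaled.r == pytest.approx(base.r)
        flipped = pearson_with_ci(-x, y)
        assert flipped.r == pytest.approx(-base.r)


class TestNestedF:
    def test_duplicate_predictor_gives_zero(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        y = a + rng.normal(size=30)
        res = nested_f_test(y, a, a)
        assert res.f == pytest.approx(0.0, abs=1e-8)

    def test_perfect_fit_infinite_f(self):
        a = np.arange(10.0)
        b = np.array([1, 0] * 5, dtype=float)
        res = nested_f_test(a + b, a, b)
        assert np.isinf(res.f) and res.p == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            y = a + 0.5 * b + rng.normal(size=20)
            res = nested_f_test(y, a, b)
            assert res.f == pytest.approx(brute_force_f(y, a, b), rel=1e-8)
            assert res.sse_full <= res.sse_reduced + 1e-12

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            nested_f_test([1, 2, 3], [1, 2, 3], [3, 2, 1])


class TestDhsWindows:
    def _setup(self):
        genome = {"c": 10_000}
        dhs = [GenomicInterval("c", 2000, 2200)]
        empty = MidpointTrack({}, "x")
        return genome, dhs, empty

    def test_window_inside_dhs_zero_distance(self):
        genome = {"c": 3000}
        dhs = [GenomicInterval("c", 0, 3000)]
        track = MidpointTrack({}, "x")
        stats = dhs_window_stats(dhs, track, track, [], genome)
        assert (stats["dhs_dist"] == 0).all()

    def test_arithmetic_series_mean_distance(self):
        genome, dhs, empty = self._setup()
        stats = dhs_window_stats(dhs, empty, empty, [], genome)
        first = stats.iloc[0]
        # window [0,1000): distances 1001..2000 to a DHS starting at 2000
        assert first["dhs_dist"] == pytest.approx(np.log2(1500.5 + 1), abs=1e-9)

    def test_two_dhs_pointwise_minimum(self):
        genome = {"c": 6000}
        dhs = [GenomicInterval("c", 0, 100), GenomicInterval("c", 5900, 6000)]
        empty = MidpointTrack({}, "x")
        stats = dhs_window_stats(dhs, empty, empty, [], genome)
        # symmetric layout -> symmetric window distances
        d = stats["dhs_dist"].to_numpy()
        np.testing.assert_allclose(d, d[::-1], atol=1e-9)

    def test_tss_proximal_exclusion_boundary(self):
        stats = pd.DataFrame({"tss_dist": [1999, 2000, 2001]})
        kept = exclude_tss_proximal(stats)
        assert kept["tss_dist"].tolist() == [2000, 2001]

    def test_no_genes_keeps_everything(self):
        genome, dhs, empty = self._setup()
        stats = dhs_window_stats(dhs, empty, empty, [], genome)
        assert len(exclude_tss_proximal(stats)) == len(stats)

    def test_toy_layout_survivor_count(self):
        genome = {"c": 10_000}
        dhs = [GenomicInterval("c", 0, 100)]
        empty = MidpointTrack({}, "x")
        gene = GeneModel("g", "g.t", "c", 5000, 6500, "+", ((5000, 6500),))
        stats = dhs_window_stats(dhs, empty, empty, [gene], genome)
        kept = exclude_tss_proximal(stats)
        # centers 500..9500; |center-5000| >= 2000 keeps 500..2500 and 7500..9500
        assert len(kept) == 6


class TestPtmCluster:
    def _tracks(self):
        rng = np.random.default_rng(99)
        return (MidpointTrack({"c": rng.integers(0, 60_000, 600)}, "hmgd"),
                MidpointTrack({"c": rng.integers(0, 60_000, 600)}, "h1"),
                MidpointTrack({"c": rng.integers(0, 60_000, 1500)}, "total"))

    def _genes(self, n=10):
        return [GeneModel(f"g{i}", f"g{i}.t", "c", 2000 + 5000 * i,
                          3500 + 5000 * i, "+", ((2000 + 5000 * i, 3500 + 5000 * i),))
                for i in range(n)]

    def test_duplicate_experiments_merge_first(self):
        rng = np.random.default_rng(4)
        genes = self._genes()
        sig = rng.normal(size=len(genes))
        values = pd.DataFrame({"a": sig, "a_copy": sig,
                               "b": rng.normal(size=len(genes))})
        res = ptm_cluster(values, *self._tracks(), genes)
        i, j = sorted(int(x) for x in res.merges[0, :2])
        assert {res.labels[i], res.labels[j]} == {"a", "a_copy"}
        assert res.merges[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_negated_track_maximal_distance(self):
        rng = np.random.default_rng(5)
        genes = self._genes()
        sig = rng.normal(size=len(genes))
        values = pd.DataFrame({"a": sig, "neg_a": -sig})
        res = ptm_cluster(values, *self._tracks(), genes)
        assert 1 - res.correlation.loc["a", "neg_a"] == pytest.approx(2.0)

    def test_constant_experiment_excluded(self):
        genes = self._genes()
        rng = np.random.default_rng(6)
        values = pd.DataFrame({"flat": np.ones(len(genes)),
                               "a": rng.normal(size=len(genes)),
                               "b": rng.normal(size=len(genes))})
        with pytest.warns(UserWarning, match="constant"):
            res = ptm_cluster(values, *self._tracks(), genes)
        assert "flat" not in res.labels


def test_bedgraph_window_means_partial_overlap():
    bg = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [50], "value": [2.0]})
    w = [GenomicInterval("c", 0, 100)]
    assert bedgraph_window_means(bg, w)[0] == pytest.approx(1.0)
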