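import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from neuroflex import (
    RoiTimeSeries,
    bh_fdr,
    build_layer_stack,
    correlation_pvalue,
    sliding_windows,
    window_correlation,
)
from neuroflex.errors import InsufficientDataError


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "t, width, step, expected",
        [(225, 30, 1, 196), (30, 30, 1, 1), (100, 30, 5, 15), (31, 30, 1, 2)],
    )
    def test_window_count(self, t, width, step, expected):
        wins = sliding_windows(t, width, step)
        assert len(wins) == expected
        assert wins[0] == (0, width)
        assert all(hi - lo == width for lo, hi in wins)

    def test_too_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            sliding_windows(29, 30)

    @given(t=st.integers(2, 300), width=st.integers(2, 60), step=st.integers(1, 7))
    def test_windows_stay_in_bounds(self, t, width, step):
        if t < width:
            with pytest.raises(InsufficientDataError):
                sliding_windows(t, width, step)
            return
        wins = sliding_windows(t, width, step)
        assert len(wins) == (t - width) // step + 1
        assert wins[-1][1] <= t


class TestWindowCorrelation:
    def test_identical_columns_correlate_perfectly(self, rng):
        x = rng.standard_normal(20)
        corr, valid = window_correlation(np.column_stack([x, x, rng.standard_normal(20)]))
        assert corr[0, 1] == pytest.approx(1.0)
        assert valid.all()

    def test_orthogonal_sign_patterns(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        corr, _ = window_correlation(np.column_stack([x, y]))
        assert corr[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        # r = 6.5 / sqrt(43.75)
        win = np.column_stack([[1.0, 2, 3, 4], [1.0, 2, 3, 5]])
        corr, _ = window_correlation(win)
        assert corr[0, 1] == pytest.approx(6.5 / np.sqrt(43.75), abs=1e-12)

    def test_constant_column_flagged_not_fatal(self):
        win = np.column_stack([np.ones(10), np.arange(10.0)])
        corr, valid = window_correlation(win)
        assert not valid[0] and valid[1]
        assert corr[0, 1] == 0.0
        assert corr[0, 0] == 1.0


class TestCorrelationPvalue:
    def test_null_center_and_degenerate_bounds(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)
        assert correlation_pvalue(1.0, 10) == 0.0
        assert correlation_pvalue(-1.0, 10) == 0.0

    def test_matches_t_reference(self):
        # t = 0.5*sqrt(28/0.75) = 3.055, df = 28 -> p ~ 0.0049
        assert correlation_pvalue(0.5, 30) == pytest.approx(0.0049, abs=2e-4)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            correlation_pvalue(0.5, 2)

    def test_vectorized_matches_scalar(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        vec = correlation_pvalue(r, 20)
        scal = [correlation_pvalue(float(v), 20) for v in r]
        np.testing.assert_allclose(vec, scal, rtol=1e-12)


class TestBhFdr:
    def test_all_small_pvalues_rejected(self):
        reject, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert reject.all()

    def test_single_large_p_kept(self):
        reject, q = bh_fdr(np.array([0.5]), alpha=0.05)
        assert not reject.any()
        assert q[0] == pytest.approx(0.5)

    def test_stepup_rejects_nothing_when_smallest_fails(self):
        reject, _ = bh_fdr(np.array([0.04, 0.5, 0.9]), alpha=0.05)
        assert not reject.any()

    def test_empty_input(self):
        reject, q = bh_fdr(np.array([]))
        assert reject.size == 0 and q.size == 0

    def test_qvalues_match_statsmodels(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            reject, q = bh_fdr(p, alpha=0.05)
            sm_rej, sm_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, sm_q, atol=1e-12)
            np.testing.assert_array_equal(reject, sm_rej)

    @given(st.integers(0, 2**31 - 1))
    def test_alpha_monotonicity(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 30)
        r1, _ = bh_fdr(p, alpha=0.01)
        r2, _ = bh_fdr(p, alpha=0.10)
        assert r1.sum() <= r2.sum()


class TestBuildLayerStack:
    def test_three_regions_three_pairs(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((40, 3)), ["a", "b", "c"], "s")
        stack = build_layer_stack(ts, width=30)
        assert stack.n_regions == 3
        r = stack.n_regions
        assert r * (r - 1) // 2 == 3

    def test_layers_symmetric_zero_diagonal(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((60, 8)), [f"n{i}" for i in range(8)], "s")
        stack = build_layer_stack(ts, width=30)
        for w in range(stack.n_layers):
            lay = stack.layers[w]
            np.testing.assert_array_equal(lay, lay.T)
            assert np.all(np.diag(lay) == 0)
            assert np.all(np.abs(lay) <= 1)
            assert np.all(lay[~stack.retained[w]] == 0)

    def test_shared_signal_edge_retained_noise_zeroed(self, rng):
        common = rng.standard_normal(30)
        data = rng.standard_normal((30, 5)) * 0.2
        data[:, 0] += common
        data[:, 1] += common
        ts = RoiTimeSeries(data, [f"n{i}" for i in range(5)], "s")
        stack = build_layer_stack(ts, width=30)
        assert stack.retained[0, 0, 1]
        noise_pairs = [(i, j) for i in range(2, 5) for j in range(i + 1, 5)]
        retained_noise = sum(stack.retained[0, i, j] for i, j in noise_pairs)
        assert retained_noise <= 1

    def test_matches_per_window_reference(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((50, 6)), [f"n{i}" for i in range(6)], "s")
        stack = build_layer_stack(ts, width=20, step=3)
        for w, (lo, hi) in enumerate(sliding_windows(50, 20, 3)):
            corr, _ = window_correlation(ts.values[lo:hi])
            mask = stack.retained[w]
            np.testing.assert_allclose(stack.layers[w][mask], corr[mask], atol=1e-10)

    def test_negative_policy(self, rng):
        n = 40
        x = rng.standard_normal(n)
        data = np.column_stack([x, -x + 0.05 * rng.standard_normal(n), rng.standard_normal(n)])
        ts = RoiTimeSeries(data, ["a", "b", "c"], "s")
        zeroed = build_layer_stack(ts, width=40, alpha=0.05, negatives="zero")
        kept = build_layer_stack(ts, width=40, alpha=0.05, negatives="retain")
        assert zeroed.layers[0, 0, 1] == 0.0
        assert kept.layers[0, 0, 1] < -0.9

    def test_alpha_monotone_in_retained_edges(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((60, 10)), [f"n{i}" for i in range(10)], "s")
        lo = build_layer_stack(ts, width=30, alpha=0.01)
        hi = build_layer_stack(ts, width=30, alpha=0.20)
        assert lo.retained.sum() <= hi.retained.sum()

    def test_pure_noise_rarely_survives_fdr(self):
        fractions = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            ts = RoiTimeSeries(r.standard_normal((60, 15)), [f"n{i}" for i in range(15)], "s")
            stack = build_layer_stack(ts, width=30)
            pair_count = 15 * 14 / 2
            fractions.append(stack.retained.sum() / (stack.n_layers * 2 * pair_count))
        assert np.mean(fractions) < 0.01
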