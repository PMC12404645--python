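"""Resampling inference: sign permutations, clusters, FDR, bootstrap, peaks."""

import itertools

import numpy as np
import pytest

from maskmvpa.stats import (
    bootstrap_peak_ci,
    cluster_inference,
    fdr_bh,
    hedges_g,
    peak_shift_test,
    sign_perm_test,
)


def exhaustive_sign_p(values, tail="right"):
    """Brute-force oracle: all 2^n sign assignments."""
    values = np.asarray(values, float)
    n = values.size
    obs = values.mean()
    stats = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        stats.append((np.array(signs) * values).mean())
    stats = np.array(stats)
    if tail == "right":
        return np.mean(stats >= obs)
    return np.mean(np.abs(stats) >= abs(obs))


class TestSignPermutation:
    def test_strong_uniform_effect_reaches_minimal_p(self):
        p = sign_perm_test(np.full(10, 10.0), n_perm=2000, rng=0)
        oracle = exhaustive_sign_p(np.full(10, 10.0))  # 1/1024
        assert p <= 0.01
        assert p >= 1.0 / 2000  # observed sample included
        assert oracle == pytest.approx(1 / 1024)

    def test_symmetric_values_give_p_near_half(self):
        rng = np.random.default_rng(1)
        ps = [
            sign_perm_test(rng.standard_normal(12), n_perm=500, rng=s)
            for s in range(40)
        ]
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_matches_exhaustive_enumeration_within_binomial_error(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            values = rng.standard_normal(10) + 0.4
            exact = exhaustive_sign_p(values)
            mc = sign_perm_test(values, n_perm=4000, rng=0)
            se = np.sqrt(exact * (1 - exact) / 4000)
            assert abs(mc - exact) < 4 * se + 1e-3

    def test_map_input_returns_map_of_p(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((8, 5, 4))
        p = sign_perm_test(maps, n_perm=200, rng=0)
        assert p.shape == (5, 4)
        assert np.all((p >= 1 / 200) & (p <= 1))

    def test_low_permutation_count_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            sign_perm_test(np.ones(4), n_perm=50, rng=0)


class TestClusterInference:
    def test_planted_block_detected_with_minimal_cluster_p(self):
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((14, 40))
        maps[:, 10:25] += 2.5
        res = cluster_inference(maps, n_perm=500, rng=1)
        assert res.sig_mask[10:25].all()
        assert min(res.cluster_p.values()) == pytest.approx(1 / 500)

    def test_all_zero_maps_yield_no_clusters(self):
        maps = np.zeros((6, 20))
        res = cluster_inference(maps, n_perm=200, rng=0)
        assert res.cluster_p == {}
        assert not res.sig_mask.any()

    def test_1d_equals_2d_on_a_one_row_grid(self):
        rng = np.random.default_rng(2)
        maps = rng.standard_normal((10, 30))
        maps[:, 5:12] += 1.5
        r1 = cluster_inference(maps, n_perm=300, rng=7)
        r2 = cluster_inference(maps[:, None, :], n_perm=300, rng=7)
        np.testing.assert_allclose(r1.point_p, r2.point_p[0])
        np.testing.assert_array_equal(r1.sig_mask, r2.sig_mask[0])

    def test_3d_grid_supported_with_orthogonal_adjacency(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((14, 6, 6, 4))
        maps[:, 1:4, 1:4, 1:3] += 3.0
        res = cluster_inference(maps, n_perm=400, rng=0)
        assert res.sig_mask[2, 2, 1]
        assert res.sig_mask.shape == (6, 6, 4)


class TestFDR:
    def test_hand_run_step_up_example(self):
        """BH on {0.001, 0.011, 0.021, 0.9} at q=0.05: sorted p_i vs i*q/m
        gives thresholds {0.0125, 0.025, 0.0375, 0.05} -> first three pass."""
        p = np.array([0.9, 0.001, 0.021, 0.011])
        reject = fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(reject, [False, True, True, True])

    def test_all_ones_reject_nothing_and_single_small_p_rejects(self):
        assert not fdr_bh(np.ones(7), q=0.05).any()
        assert fdr_bh(np.array([0.04]), q=0.05).all()

    def test_empty_input_gives_empty_mask(self):
        assert fdr_bh(np.array([]), q=0.05).size == 0

    def test_shape_preserved(self):
        p = np.full((3, 4), 0.5)
        assert fdr_bh(p).shape == (3, 4)


class TestBootstrapPeakCI:
    def test_identical_curves_give_degenerate_ci(self):
        t = np.arange(0.0, 500.0, 10.0)
        curve = np.exp(-0.5 * ((t - 200.0) / 40.0) ** 2)
        curves = np.tile(curve, (8, 1))
        lo, hi = bootstrap_peak_ci(curves, n_boot=200, rng=0, coords=t)
        assert (lo, hi) == (200.0, 200.0)

    def test_ci_width_grows_with_peak_jitter(self):
        t = np.arange(0.0, 500.0, 10.0)
        rng = np.random.default_rng(1)

        def curves(jitter_ms):
            peaks = 200.0 + jitter_ms * rng.standard_normal(12)
            return np.stack(
                [np.exp(-0.5 * ((t - p) / 40.0) ** 2) for p in peaks]
            )

        lo1, hi1 = bootstrap_peak_ci(curves(10.0), n_boot=300, rng=2, coords=t)
        lo2, hi2 = bootstrap_peak_ci(curves(60.0), n_boot=300, rng=2, coords=t)
        assert (hi2 - lo2) > (hi1 - lo1)

    def test_flat_curve_warns_and_spans_domain(self):
        curves = np.ones((5, 20))
        with pytest.warns(UserWarning, match="flat"):
            lo, hi = bootstrap_peak_ci(curves, n_boot=50, rng=0)
        assert (lo, hi) == (0.0, 19.0)


class TestPeakShift:
    def test_identical_conditions_are_null(self):
        rng = np.random.default_rng(0)
        peaks = rng.normal(5.0, 1.0, size=12)
        p, g = peak_shift_test(peaks, peaks.copy(), n_perm=1000, rng=1)
        assert p == 1.0
        assert g == 0.0

    def test_constant_shift_is_detected_with_large_effect(self):
        rng = np.random.default_rng(1)
        b = rng.normal(4.0, 0.3, size=20)
        a = b + 2.0 + 0.1 * rng.standard_normal(20)
        p, g = peak_shift_test(a, b, n_perm=2000, rng=2)
        assert p <= 2 / 2000 + 1e-12
        assert g > 2.0

    def test_matches_exhaustive_two_tailed_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 1.0, size=10)
        b = rng.normal(0.2, 1.0, size=10)
        exact = exhaustive_sign_p(a - b, tail="two")
        p, _ = peak_shift_test(a, b, n_perm=4000, rng=4)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(p - exact) < 4 * se + 1e-3

    def test_curve_input_reduces_to_peak_coordinates(self):
        t = np.arange(0.0, 100.0, 5.0)
        curves_a = np.stack(
            [np.exp(-0.5 * ((t - 60.0) / 10.0) ** 2)] * 6
        )
        curves_b = np.stack(
            [np.exp(-0.5 * ((t - 40.0) / 10.0) ** 2)] * 6
        )
        # zero variance in the paired differences: g defined as 0, p = 1/n
        p, g = peak_shift_test(curves_a, curves_b, n_perm=64, rng=0, coords=t)
        assert g == 0.0

    def test_hedges_g_small_sample_correction(self):
        diff = np.array([1.0, 2.0, 3.0, 4.0])
        d = diff.mean() / diff.std(ddof=1)
        assert hedges_g(diff) == pytest.approx(d * (1 - 3 / (4 * 3 - 1)))


class TestFamilywiseValidity:
    def test_permutation_p_values_are_valid_under_the_null(self):
        """P(p <= alpha) <= alpha + 2*SE over null simulations."""
        rng = np.random.default_rng(0)
        n_sim, n_perm = 150, 300
        ps = np.array(
            [
                sign_perm_test(rng.standard_normal(10), n_perm=n_perm, rng=s)
                for s in range(n_sim)
            ]
        )
        for alpha in (0.05, 0.2):
            rate = np.mean(ps <= alpha)
            se = np.sqrt(alpha * (1 - alpha) / n_sim)
            assert rate <= alpha + 2 * se
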