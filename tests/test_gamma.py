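"""Gamma analysis: analytic cases, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mlctip.dose import DoseMap, GridSpec
from mlctip.gamma import (
    CRITERIA_2_2,
    CRITERIA_3_3,
    GammaCriteria,
    gamma_bruteforce,
    gamma_index,
)
from mlctip.qa import SampledDose


def smooth_map(rng, n=41, spacing=2.0, sigma=3.0, base=10.0):
    """Random smooth positive dose field on an n x n grid."""
    grid = GridSpec(origin_mm=(-(n - 1) / 2 * spacing, -(n - 1) / 2 * spacing),
                    spacing_mm=spacing, nx=n, ny=n)
    vals = gaussian_filter(rng.uniform(0, 1, (n, n)), sigma) * 100.0 + base
    return DoseMap(grid, vals)


def subsample(dose_map, step=5):
    xs = dose_map.grid.x_coords()[::step]
    ys = dose_map.grid.y_coords()[::step]
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return SampledDose(pts, dose_map.sample(pts))


class TestAnalyticCases:
    def test_identical_distributions_give_zero_gamma(self):
        rng = np.random.default_rng(0)
        ev = smooth_map(rng)
        ref = subsample(ev)
        res = gamma_index(ref, ev, CRITERIA_3_3)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_values) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_3pct_scaling_passes_3pct_global(self):
        """Global normalization: a +3% scale error is at most 3% of the max."""
        rng = np.random.default_rng(1)
        ev = smooth_map(rng)
        ref = subsample(ev)
        scaled = DoseMap(ev.grid, 1.03 * ev.values)
        res = gamma_index(ref, scaled, CRITERIA_3_3)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_values) <= 1.0 + 1e-9

    def test_pure_translation_by_dta_passes_at_interior(self):
        rng = np.random.default_rng(2)
        ev = smooth_map(rng)
        shifted_pts = subsample(ev).points_xy
        interior = np.all(np.abs(shifted_pts) <= 20.0, axis=1)
        pts = shifted_pts[interior]
        # reference reads the evaluated field 3 mm away: DTA term alone reaches 1
        ref = SampledDose(pts, ev.sample(pts + np.array([3.0, 0.0])))
        res = gamma_index(ref, ev, CRITERIA_3_3)
        assert np.nanmax(res.gamma_values) <= 1.0 + 1e-9

    def test_single_point_dose_gap_of_exactly_dd_gives_gamma_one(self):
        grid = GridSpec(origin_mm=(-10, -10), spacing_mm=1.0, nx=21, ny=21)
        ev = DoseMap(grid, np.full((21, 21), 97.0))
        ref = SampledDose(np.array([[0.0, 0.0]]), np.array([100.0]))
        res = gamma_bruteforce(ref, ev, CRITERIA_3_3)  # dD = 3% of 100
        assert res.gamma_values[0] == pytest.approx(1.0, abs=1e-9)
        assert res.pass_rate == 100.0  # gamma exactly 1 counts as passing


class TestOracleEquivalence:
    def test_fast_gamma_matches_bruteforce_on_random_fields(self):
        rng = np.random.default_rng(42)
        for case in range(20):
            ev = smooth_map(rng, n=31, spacing=2.0, sigma=rng.uniform(1.5, 4.0))
            ref_clean = subsample(ev, step=4)
            noisy = ref_clean.values * (1 + rng.normal(0, 0.02, ref_clean.values.shape))
            ref = SampledDose(ref_clean.points_xy, noisy)
            crit = CRITERIA_2_2 if case % 2 else CRITERIA_3_3
            fast = gamma_index(ref, ev, crit)
            brute = gamma_bruteforce(ref, ev, crit)
            np.testing.assert_array_equal(fast.evaluated_mask, brute.evaluated_mask)
            diff = np.nanmax(np.abs(fast.gamma_values - brute.gamma_values))
            assert diff <= 0.01
            assert abs(fast.pass_rate - brute.pass_rate) <= 0.5

    def test_bruteforce_rejects_large_inputs(self):
        ev = smooth_map(np.random.default_rng(0), n=41)
        ref = subsample(ev, step=1)  # 1681 points
        with pytest.raises(ValueError):
            gamma_bruteforce(ref, ev, CRITERIA_3_3)


class TestInvariances:
    def test_scale_invariance_of_global_gamma(self):
        rng = np.random.default_rng(7)
        ev = smooth_map(rng)
        ref = subsample(ev)
        ref.values = ref.values * (1 + rng.normal(0, 0.03, ref.values.shape))
        res1 = gamma_index(ref, ev, CRITERIA_3_3)
        scaled_ref = SampledDose(ref.points_xy, 7.5 * ref.values)
        scaled_ev = DoseMap(ev.grid, 7.5 * ev.values)
        res2 = gamma_index(scaled_ref, scaled_ev, CRITERIA_3_3)
        np.testing.assert_allclose(res1.gamma_values, res2.gamma_values, atol=1e-9)

    def test_loosening_criteria_never_reduces_pass_rate(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            ev = smooth_map(rng, n=31)
            ref = subsample(ev, step=3)
            ref.values = ref.values * (1 + rng.normal(0, 0.05, ref.values.shape))
            tight = gamma_index(ref, ev, GammaCriteria(2.0, 2.0))
            loose_dose = gamma_index(ref, ev, GammaCriteria(3.0, 2.0))
            loose_dta = gamma_index(ref, ev, GammaCriteria(2.0, 3.0))
            assert loose_dose.pass_rate >= tight.pass_rate
            assert loose_dta.pass_rate >= tight.pass_rate

    def test_raising_threshold_never_adds_evaluated_points(self):
        rng = np.random.default_rng(9)
        ev = smooth_map(rng, base=1.0)
        ref = subsample(ev)
        counts = [
            gamma_index(ref, ev, GammaCriteria(3.0, 3.0, thr)).n_evaluated
            for thr in (5.0, 10.0, 50.0, 90.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_no_points_above_threshold_is_an_error(self):
        rng = np.random.default_rng(10)
        ev = smooth_map(rng)
        ref = subsample(ev)
        with pytest.raises(ValueError):
            gamma_index(ref, ev, GammaCriteria(3.0, 3.0, low_dose_threshold_pct=150.0))
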