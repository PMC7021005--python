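"""Double-step leaf-tip model: edges, profiles, rasterization."""

import numpy as np
import pytest

from mlctip.mlc import (
    BeamModelParams,
    ContractError,
    LeafPairAperture,
    Segment,
    effective_edges,
    leaf_pair_transmission,
    segment_transmission_map,
)
from mlctip.dose import GridSpec

from conftest import make_bank, random_bank, uniform_segment


def pair(left, right):
    return LeafPairAperture(0, -2.5, 2.5, left, right)


class TestBeamModelParams:
    def test_tip_rule_sqrt_gives_geometric_mean(self):
        m = BeamModelParams(0.0, 4.5, leaf_transmission=0.0049, tip_rule="sqrt")
        assert m.tip_transmission == pytest.approx(0.07)

    def test_tip_rule_intraleaf_collapses_to_T(self):
        m = BeamModelParams(0.0, 4.5, leaf_transmission=0.0049, tip_rule="intraleaf")
        assert m.tip_transmission == 0.0049

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(leaf_transmission=0.0),
            dict(leaf_transmission=1.0),
            dict(leaf_tip_width_mm=-1.0),
            dict(leaf_tip_offset_mm=6.0),
            dict(tip_rule="bogus"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        base = dict(leaf_tip_offset_mm=0.0, leaf_tip_width_mm=4.5, leaf_transmission=0.005)
        base.update(kwargs)
        with pytest.raises(ValueError):
            BeamModelParams(**base)

    def test_transmission_ordering_invariant(self):
        m = BeamModelParams(0.0, 4.5, leaf_transmission=0.005)
        assert m.leaf_transmission <= m.tip_transmission <= 1.0


class TestEffectiveEdges:
    def test_zero_offset_is_identity(self):
        m = BeamModelParams(0.0, 4.5)
        assert effective_edges(pair(-10, 10), m) == (-10, 10)

    def test_positive_offset_enlarges_field(self):
        # +1 mm per tip -> 22 mm effective gap from a 20 mm nominal gap
        m = BeamModelParams(1.0, 4.5)
        assert effective_edges(pair(-10, 10), m) == (-11, 11)

    def test_negative_offset_clamps_to_zero_gap_at_midpoint(self):
        m = BeamModelParams(-1.0, 4.5)
        assert effective_edges(pair(-0.5, 0.5), m) == (0.0, 0.0)

    def test_clamp_preserves_off_center_midpoint(self):
        m = BeamModelParams(-2.0, 4.5)
        assert effective_edges(pair(4.0, 5.0), m) == (4.5, 4.5)


class TestLeafPairTransmission:
    def test_open_midpoint_fully_transmits(self, model):
        assert leaf_pair_transmission(0.0, pair(-20, 20), model) == 1.0

    def test_deep_under_leaf_returns_intraleaf_T(self):
        m = BeamModelParams(0.0, 4.5, leaf_transmission=0.005)
        # x beyond right_eff + w is the full-leaf region
        assert leaf_pair_transmission(20.0, pair(-10, 10), m) == 0.005

    def test_tip_region_returns_tau(self):
        m = BeamModelParams(0.0, 4.5, leaf_transmission=0.0049)
        assert leaf_pair_transmission(12.0, pair(-10, 10), m) == pytest.approx(0.07)

    def test_closed_pair_matches_two_leaf_bruteforce(self):
        """Overlapping tip regions combine as the pointwise min of both leaves."""
        m = BeamModelParams(0.0, 4.5, leaf_transmission=0.005)
        p = pair(0.0, 0.0)
        xs = np.linspace(-15, 15, 601)
        got = leaf_pair_transmission(xs, p, m)
        # brute-force oracle: evaluate each leaf's step profile separately
        T, tau, w = m.leaf_transmission, m.tip_transmission, m.leaf_tip_width_mm
        expect = []
        for x in xs:
            left = 1.0 if x >= 0.0 else (tau if x >= -w else T)
            right = 1.0 if x <= 0.0 else (tau if x <= w else T)
            expect.append(min(left, right))
        np.testing.assert_allclose(got, expect)

    def test_result_bounded_by_T_and_one(self, model):
        xs = np.linspace(-50, 50, 401)
        vals = leaf_pair_transmission(xs, pair(-5, 3), model)
        assert np.all(vals >= model.leaf_transmission) and np.all(vals <= 1.0)


class TestSegmentTransmissionMap:
    def test_fully_open_is_one(self, small_grid):
        m = BeamModelParams(0.0, 4.5)
        seg = uniform_segment(-60, 60)
        assert np.all(segment_transmission_map(seg, m, small_grid) == 1.0)

    def test_fully_closed_far_beyond_tip_is_T(self, small_grid):
        m = BeamModelParams(0.0, 4.5, leaf_transmission=0.005)
        # grid x in [-40, 40]; leaves parked far left so tips never enter
        seg = Segment(make_bank([(-60.0, -60.0)] * 8), 1.0, 0.0)
        assert np.all(segment_transmission_map(seg, m, small_grid) == 0.005)

    def test_monotone_in_offset_on_random_apertures(self, small_grid):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seg = Segment(random_bank(rng), 1.0, 0.0)
            prev = None
            for off in np.arange(-1.0, 1.01, 0.25):
                m = BeamModelParams(float(off), 4.5)
                cur = segment_transmission_map(seg, m, small_grid)
                if prev is not None:
                    assert np.all(cur >= prev - 1e-12)
                prev = cur

    def test_zero_width_reduces_to_binary_aperture(self, small_grid):
        m = BeamModelParams(0.0, 0.0, leaf_transmission=0.005)
        seg = uniform_segment(-10.2, 10.7)
        vals = segment_transmission_map(seg, m, small_grid)
        xs = small_grid.x_coords()
        binary = np.where((xs >= -10.2) & (xs <= 10.7), 1.0, 0.005)
        np.testing.assert_allclose(vals, np.tile(binary, (small_grid.ny, 1)))

    def test_width_change_only_affects_tip_regions(self, small_grid):
        seg = uniform_segment(-10, 10)
        narrow = segment_transmission_map(seg, BeamModelParams(0.0, 2.5), small_grid)
        wide = segment_transmission_map(seg, BeamModelParams(0.0, 6.0), small_grid)
        xs = small_grid.x_coords()
        outside_tips = (np.abs(xs) <= 10) | (np.abs(xs) > 16)
        np.testing.assert_array_equal(narrow[:, outside_tips], wide[:, outside_tips])
        assert np.any(narrow != wide)

    def test_rasterization_matches_pointwise_oracle(self, small_grid):
        """Vectorized map equals scalar per-point evaluation on random apertures."""
        rng = np.random.default_rng(11)
        seg = Segment(random_bank(rng), 1.0, 0.0)
        m = BeamModelParams(-0.5, 4.5)
        vals = segment_transmission_map(seg, m, small_grid)
        ys = small_grid.y_coords()
        xs = small_grid.x_coords()
        for j in range(0, small_grid.ny, 5):
            owner = [p for p in seg.aperture if p.y_low_mm <= ys[j] < p.y_high_mm]
            if not owner:
                continue
            for i in range(0, small_grid.nx, 7):
                assert vals[j, i] == leaf_pair_transmission(xs[i], owner[0], m)

    def test_grid_not_covering_bank_is_rejected(self):
        m = BeamModelParams(0.0, 4.5)
        seg = uniform_segment(-10, 10, n_pairs=8)  # bank spans y in [-20, 20]
        tiny = GridSpec(origin_mm=(-40, -5), spacing_mm=1.0, nx=81, ny=11)
        with pytest.raises(ContractError):
            segment_transmission_map(seg, m, tiny)


class TestDeliveryContainers:
    def test_mixed_gantry_segments_rejected_in_beam(self):
        from mlctip.mlc import Beam

        s0 = uniform_segment(-10, 10, gantry=0.0)
        s1 = uniform_segment(-10, 10, gantry=40.0)
        with pytest.raises(ContractError):
            Beam((s0, s1))

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            uniform_segment(-10, 10, mu=-1.0)

    def test_inverted_pair_rejected(self):
        with pytest.raises(ValueError):
            LeafPairAperture(0, -2.5, 2.5, 5.0, -5.0)
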