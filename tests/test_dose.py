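"""Convolution dose engine: fluence linearity, kernel contracts, composite dose."""

import numpy as np
import pytest

from mlctip.dose import (
    BeamDoseCache,
    FluenceMap,
    GridSpec,
    KernelParams,
    beam_fluence,
    composite_point_dose,
    planar_dose,
    ray_depth_mm,
)
from mlctip.mlc import Beam, BeamModelParams, ContractError, Plan
from mlctip.plans import open_field_plan

from conftest import uniform_segment


@pytest.fixture
def grid():
    return GridSpec()  # 256 x 256 at 1 mm


class TestBeamFluence:
    def test_open_segment_gives_constant_mu(self, model, small_grid):
        fl = beam_fluence([uniform_segment(-60, 60, mu=100.0)], model, small_grid)
        np.testing.assert_allclose(fl.values, 100.0)

    def test_linearity_in_mu(self, model, small_grid):
        seg1 = uniform_segment(-10, 5, mu=30.0)
        seg2 = uniform_segment(-10, 5, mu=60.0)
        f1 = beam_fluence([seg1], model, small_grid)
        f2 = beam_fluence([seg2], model, small_grid)
        np.testing.assert_allclose(f2.values, 2.0 * f1.values)

    def test_additivity_over_segments(self, model, small_grid):
        a = uniform_segment(-10, 0, mu=20.0)
        b = uniform_segment(0, 10, mu=30.0)
        fab = beam_fluence([a, b], model, small_grid)
        fa = beam_fluence([a], model, small_grid)
        fb = beam_fluence([b], model, small_grid)
        np.testing.assert_allclose(fab.values, fa.values + fb.values)

    def test_mixed_gantry_angles_rejected(self, model, small_grid):
        with pytest.raises(ContractError):
            beam_fluence(
                [uniform_segment(-10, 10, gantry=0.0), uniform_segment(-10, 10, gantry=90.0)],
                model,
                small_grid,
            )


class TestPlanarDose:
    def test_flat_field_preserved_at_center(self, grid, kernel):
        fl = FluenceMap(grid, np.full((grid.ny, grid.nx), 50.0))
        dose = planar_dose(fl, kernel)
        center = dose.values[grid.ny // 2, grid.nx // 2]
        assert center == pytest.approx(50.0, rel=1e-3)

    def test_impulse_matches_closed_form_kernel(self, grid, kernel):
        values = np.zeros((grid.ny, grid.nx))
        values[grid.ny // 2, grid.nx // 2] = 1.0
        dose = planar_dose(FluenceMap(grid, values), kernel)
        xs = grid.x_coords()
        ys = grid.y_coords()
        x0, y0 = xs[grid.nx // 2], ys[grid.ny // 2]
        rr = np.hypot(xs[None, :] - x0, ys[:, None] - y0)
        expected = kernel.point_spread(rr) * grid.spacing_mm**2
        np.testing.assert_allclose(dose.values, expected, atol=1e-6 * expected.max())

    def test_linearity_of_convolution(self, grid, kernel):
        rng = np.random.default_rng(3)
        a = FluenceMap(grid, rng.uniform(0, 1, (grid.ny, grid.nx)))
        b = FluenceMap(grid, rng.uniform(0, 1, (grid.ny, grid.nx)))
        dsum = planar_dose(FluenceMap(grid, a.values + b.values), kernel)
        np.testing.assert_allclose(
            dsum.values,
            planar_dose(a, kernel).values + planar_dose(b, kernel).values,
            atol=1e-9,
        )


class TestRayDepth:
    def test_center_depth_equals_radius(self):
        for gantry in (0.0, 37.0, 180.0, 271.0):
            assert ray_depth_mm(np.array([[0.0, 0.0]]), gantry, 80.0)[0] == pytest.approx(80.0)

    def test_anterior_point_shallow_for_anterior_beam(self):
        # gantry 0 enters at z = +R; point at z = +60 sits 20 mm deep
        d = ray_depth_mm(np.array([[0.0, 60.0]]), 0.0, 80.0)[0]
        assert d == pytest.approx(20.0)

    def test_point_outside_phantom_rejected(self):
        with pytest.raises(ValueError):
            ray_depth_mm(np.array([[90.0, 0.0]]), 0.0, 80.0)


class TestCompositePointDose:
    def test_single_beam_is_attenuated_planar_dose(self, grid, kernel):
        plan = open_field_plan(100.0, mu=100.0, gantry_deg=0.0)
        model = BeamModelParams(0.0, 4.5)
        fl = beam_fluence(plan.beams[0], model, grid)
        planar = planar_dose(fl, kernel)
        d = composite_point_dose(plan, model, np.array([[0.0, 0.0, 0.0]]), 80.0, kernel, grid)
        expected = np.exp(-kernel.mu_attenuation_per_cm * 8.0) * planar.sample([[0.0, 0.0]])[0]
        assert d[0] == pytest.approx(expected, rel=1e-9)

    def test_opposed_beams_contribute_equally_at_center(self, grid, kernel):
        model = BeamModelParams(0.0, 4.5)
        single = open_field_plan(100.0, mu=50.0, gantry_deg=90.0)
        opposed = Plan(
            "OPP",
            "imrt",
            (
                open_field_plan(100.0, mu=50.0, gantry_deg=90.0).beams[0],
                open_field_plan(100.0, mu=50.0, gantry_deg=270.0).beams[0],
            ),
        )
        center = np.array([[0.0, 0.0, 0.0]])
        d_single = composite_point_dose(single, model, center, 80.0, kernel, grid)
        d_opp = composite_point_dose(opposed, model, center, 80.0, kernel, grid)
        assert d_opp[0] == pytest.approx(2.0 * d_single[0], rel=1e-9)

    def test_dose_monotone_in_offset(self, grid, kernel):
        """Fluence monotonicity propagates through the positive kernel."""
        rng = np.random.default_rng(5)
        from conftest import random_bank
        from mlctip.mlc import Segment

        for _ in range(3):
            bank = random_bank(rng, n_pairs=8, span=40.0)
            plan = Plan("R", "imrt", (Beam((Segment(bank, 100.0, float(rng.uniform(0, 360))),)),))
            pts = np.array([[0.0, 0.0, 0.0], [10.0, -20.0, 5.0], [-15.0, 10.0, -10.0]])
            prev = None
            for off in (-1.0, -0.5, 0.0, 0.5, 1.0):
                d = composite_point_dose(plan, BeamModelParams(off, 4.5), pts, 80.0, kernel, grid)
                if prev is not None:
                    assert np.all(d >= prev - 1e-9)
                prev = d

    def test_cache_matches_one_shot_evaluation(self, grid, kernel):
        plan = open_field_plan(60.0, mu=10.0, gantry_deg=45.0)
        model = BeamModelParams(-0.5, 4.5)
        pts = np.array([[5.0, 5.0, 0.0], [0.0, -30.0, 10.0]])
        cache = BeamDoseCache(plan, model, 80.0, kernel, grid)
        np.testing.assert_allclose(
            cache.dose_at(pts), composite_point_dose(plan, model, pts, 80.0, kernel, grid)
        )
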