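"""Virtual diode-array QA measurements.

A planar diode array at the isocenter coronal plane stands in for the
cylindrical commercial array: "measured" maps are the truth-model composite
dose sampled at the diode positions plus reproducible Gaussian noise, and
"calculated" maps are the candidate-model dose, noiseless.  The planar
simplification keeps the statistical character of the comparison (pointwise
dose pairs at centimeter pitch) without helical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import BeamDoseCache, DoseMap, GridSpec, KernelParams
from .mlc import BeamModelParams, Plan
from .plans import PhantomSpec

__all__ = [
    "ArraySpec",
    "SampledDose",
    "virtual_measurement",
    "predicted_on_array",
    "predicted_plane_dose",
]


@dataclass(frozen=True)
class ArraySpec:
    """Planar diode array in the isocenter coronal plane (z = 0).

    Diodes sit on a square grid of pitch ``spacing_mm`` covering
    ``[-extent_mm, extent_mm]`` in both the crossplane (x) and axial (y)
    directions.  ``noise_sigma_pct`` is the measurement-noise standard
    deviation as a percent of the map maximum.
    """

    spacing_mm: float = 10.0
    extent_mm: float = 60.0
    noise_sigma_pct: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")
        if self.noise_sigma_pct < 0:
            raise ValueError("noise_sigma_pct must be >= 0")

    def diode_positions(self) -> np.ndarray:
        """(n, 2) diode coordinates (x, y_axial) mm."""
        c = np.arange(-self.extent_mm, self.extent_mm + 1e-9, self.spacing_mm)
        xx, yy = np.meshgrid(c, c, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class SampledDose:
    """Dose sampled at scattered plane points (x, y_axial)."""

    points_xy: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.points_xy = np.atleast_2d(np.asarray(self.points_xy, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if len(self.points_xy) != len(self.values):
            raise ValueError("points/values length mismatch")


def _plane_points_xyz(points_xy: np.ndarray) -> np.ndarray:
    """Lift array-plane (x, y_axial) points into phantom (x, z=0, y) coords."""
    pts = np.atleast_2d(points_xy)
    return np.column_stack([pts[:, 0], np.zeros(len(pts)), pts[:, 1]])


def predicted_on_array(
    plan: Plan,
    candidate_model: BeamModelParams,
    array: ArraySpec,
    phantom: PhantomSpec,
    kernel: KernelParams | None = None,
    grid: GridSpec | None = None,
    cache: BeamDoseCache | None = None,
) -> SampledDose:
    """Noiseless candidate-model dose at the diode positions (deterministic)."""
    kernel = kernel or KernelParams()
    cache = cache or BeamDoseCache(plan, candidate_model, phantom.radius_mm, kernel, grid or GridSpec())
    pts = array.diode_positions()
    return SampledDose(pts, cache.dose_at(_plane_points_xyz(pts)))


def virtual_measurement(
    plan: Plan,
    truth_model: BeamModelParams,
    array: ArraySpec,
    phantom: PhantomSpec,
    kernel: KernelParams | None = None,
    grid: GridSpec | None = None,
    cache: BeamDoseCache | None = None,
) -> SampledDose:
    """Truth-model dose at the diodes plus seeded Gaussian noise.

    Noise is zero-mean with standard deviation ``noise_sigma_pct`` percent of
    the noiseless maximum, reproducible per ``array.seed``.
    """
    clean = predicted_on_array(plan, truth_model, array, phantom, kernel, grid, cache)
    if array.noise_sigma_pct == 0.0:
        return clean
    rng = np.random.default_rng(array.seed)
    sigma = array.noise_sigma_pct / 100.0 * clean.values.max()
    noisy = clean.values + rng.normal(0.0, sigma, size=clean.values.shape)
    return SampledDose(clean.points_xy, np.maximum(noisy, 0.0))


def predicted_plane_dose(
    plan: Plan,
    model: BeamModelParams,
    phantom: PhantomSpec,
    kernel: KernelParams | None = None,
    grid: GridSpec | None = None,
    extent_mm: float = 70.0,
    spacing_mm: float = 2.0,
    cache: BeamDoseCache | None = None,
) -> DoseMap:
    """Candidate dose on a fine grid over the array plane.

    This is the continuous "calculated" distribution the gamma analysis
    searches for distance-to-agreement; its extent should exceed the diode
    extent by at least the gamma search radius.
    """
    kernel = kernel or KernelParams()
    cache = cache or BeamDoseCache(plan, model, phantom.radius_mm, kernel, grid or GridSpec())
    n = int(round(2 * extent_mm / spacing_mm)) + 1
    plane_grid = GridSpec(origin_mm=(-extent_mm, -extent_mm), spacing_mm=spacing_mm, nx=n, ny=n)
    xx, yy = np.meshgrid(plane_grid.x_coords(), plane_grid.y_coords(), indexing="xy")
    pts_xy = np.column_stack([xx.ravel(), yy.ravel()])
    vals = cache.dose_at(_plane_points_xyz(pts_xy)).reshape(n, n)
    return DoseMap(plane_grid, vals)
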