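"""Synthetic head-and-neck plan suite and virtual phantom.

Generates the geometry and the nine-plan suite the study runs on: a
cylindrical phantom holding two spherical target volumes (PTV1, PTV2) and a
posterior spinal-cord avoidance structure, with four TLD-like point ROIs, and
heuristic step-and-shoot IMRT / arc plans whose apertures conform to the
targets while pulling leaves over the cord shadow.  The cord block is what
creates the steep dose gradient between the PTV1 edge and the cord — the
geometric feature the leaf-tip offset sensitivity analysis depends on.

Plans are constructed, not inverse-optimized: what matters downstream is
modulated apertures with penumbrae crossing the high-gradient ROIs, which the
generator produces explicitly.  Beam counts and total MU follow the published
suite design (five step-and-shoot plans with 7 or 9 beams, four arc plans
with 2 or 3 full arcs, total MU between 1469 and 2114).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mlc import Beam, LeafPairAperture, Plan, Segment

__all__ = [
    "PhantomSpec",
    "PlanSpec",
    "ROI",
    "default_phantom",
    "tld_rois",
    "generate_plan_suite",
    "PLAN_TABLE",
    "open_field_plan",
]

# leaf bank geometry (Agility-like): 40 pairs at 5 mm pitch, y in [-100, 100]
N_PAIRS = 40
LEAF_PITCH_MM = 5.0
BANK_HALF_MM = N_PAIRS * LEAF_PITCH_MM / 2.0
PARK_X_MM = -115.0  # closed pairs park off the phantom, inside the dose grid

APERTURE_MARGIN_MM = 3.0  # penumbra margin around target projections
CORD_BLOCK_MARGIN_MM = 2.0  # blocked shadow extends this far beyond the cord

# published suite design: (plan_id, technique, number of beams or arcs, total MU)
PLAN_TABLE: tuple[tuple[str, str, int, float], ...] = (
    ("IMRT0", "imrt", 7, 1542.0),
    ("IMRT1", "imrt", 7, 1772.0),
    ("IMRT2", "imrt", 7, 1733.0),
    ("IMRT3", "imrt", 9, 1747.0),
    ("IMRT4", "imrt", 9, 1818.0),
    ("VMAT1", "vmat", 2, 1711.0),
    ("VMAT2", "vmat", 2, 1871.0),
    ("VMAT3", "vmat", 2, 2114.0),
    ("VMAT4", "vmat", 3, 1469.0),
)

MU_RANGE = (1469.0, 2114.0)
ARC_CONTROL_POINT_DEG = 4.0  # arc discretization: one static segment per 4 degrees


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical phantom with two spherical PTVs and a cord cylinder.

    Transverse coordinates are (x, z) mm with the cylinder axis (axial y)
    through the origin; +z is anterior, so the cord sits at negative z.
    """

    radius_mm: float = 80.0
    ptv1_center: tuple[float, float] = (0.0, -5.0)
    ptv2_center: tuple[float, float] = (25.0, 10.0)
    cord_center: tuple[float, float] = (0.0, -35.0)
    ptv_radii_mm: tuple[float, float] = (20.0, 12.0)
    cord_radius_mm: float = 4.0
    cord_gap_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.cord_gap_mm <= 0:
            raise ValueError("cord_gap_mm must be > 0 (the PTV-cord gradient region)")
        for center, r in (
            (self.ptv1_center, self.ptv_radii_mm[0]),
            (self.ptv2_center, self.ptv_radii_mm[1]),
            (self.cord_center, self.cord_radius_mm),
        ):
            if math.hypot(*center) + r > self.radius_mm:
                raise ValueError(f"structure at {center} (r={r}) pokes out of the cylinder")
        for center, r in (
            (self.ptv1_center, self.ptv_radii_mm[0]),
            (self.ptv2_center, self.ptv_radii_mm[1]),
        ):
            gap = (
                math.dist(center, self.cord_center) - r - self.cord_radius_mm
            )
            if gap < self.cord_gap_mm - 1e-9:
                raise ValueError(
                    f"cord not separated from PTV at {center}: gap {gap:.2f} mm "
                    f"< declared {self.cord_gap_mm} mm"
                )


@dataclass(frozen=True)
class ROI:
    """Small disk ROI standing in for a TLD (mean dose over the disk)."""

    name: str
    center_xyz: tuple[float, float, float]  # (x, z, y_axial) mm
    radius_mm: float
    gradient: str  # "low" | "high"


@dataclass(frozen=True)
class PlanSpec:
    plan_id: str
    technique: str
    n_beams_or_arcs: int
    segments_per_beam: int
    total_mu: float
    modulation_strength: float
    seed: int

    def __post_init__(self) -> None:
        if self.technique == "imrt" and self.n_beams_or_arcs not in (7, 9):
            raise ValueError("step-and-shoot plans use 7 or 9 beams")
        if self.technique == "vmat" and self.n_beams_or_arcs not in (2, 3):
            raise ValueError("arc plans use 2 or 3 full arcs")
        if not MU_RANGE[0] <= self.total_mu <= MU_RANGE[1]:
            raise ValueError(f"total MU {self.total_mu} outside {MU_RANGE}")


def default_phantom() -> PhantomSpec:
    """The default head-and-neck-like phantom (deterministic)."""
    return PhantomSpec()


def tld_rois(phantom: PhantomSpec, radius_mm: float = 3.0) -> list[ROI]:
    """The four TLD-like ROIs with their dose-gradient tags.

    PTV1_center and PTV2 sit in the flat interior of their targets
    (low gradient); PTV1_periphery sits at the PTV1 edge facing the cord and
    SpinalCord inside the blocked cord shadow (both high gradient).
    """
    c1x, c1z = phantom.ptv1_center
    c2x, c2z = phantom.ptv2_center
    ccx, ccz = phantom.cord_center
    r1 = phantom.ptv_radii_mm[0]
    # periphery ROI: inside PTV1, its edge touching the PTV1 surface facing the cord
    dx, dz = ccx - c1x, ccz - c1z
    norm = math.hypot(dx, dz)
    px = c1x + dx / norm * (r1 - radius_mm)
    pz = c1z + dz / norm * (r1 - radius_mm)
    rois = [
        ROI("PTV1_center", (c1x, c1z, 0.0), radius_mm, "low"),
        ROI("PTV1_periphery", (px, pz, 0.0), radius_mm, "high"),
        ROI("PTV2", (c2x, c2z, 0.0), radius_mm, "low"),
        ROI("SpinalCord", (ccx, ccz, 0.0), radius_mm, "high"),
    ]
    for roi in rois:
        x, z, _ = roi.center_xyz
        if math.hypot(x, z) + roi.radius_mm > phantom.radius_mm:
            raise ValueError(f"ROI {roi.name} not inside the phantom")
    return rois


def roi_sample_points(roi: ROI, n_ring: int = 8) -> np.ndarray:
    """(n, 3) points covering the ROI disk (center + one ring) for mean dose."""
    cx, cz, cy = roi.center_xyz
    ang = 2 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack(
        [cx + 0.7 * roi.radius_mm * np.cos(ang), cz + 0.7 * roi.radius_mm * np.sin(ang),
         np.full(n_ring, cy)]
    )
    return np.vstack([[cx, cz, cy], ring])


# --- aperture construction ------------------------------------------------------


def _leaf_pairs_y() -> np.ndarray:
    """(N_PAIRS, 2) array of (y_low, y_high) for the bank."""
    edges = -BANK_HALF_MM + LEAF_PITCH_MM * np.arange(N_PAIRS + 1)
    return np.column_stack([edges[:-1], edges[1:]])


def _bev_axis(gantry_deg: float) -> np.ndarray:
    t = math.radians(gantry_deg)
    return np.array([math.cos(t), math.sin(t)])


def conformal_aperture(
    gantry_deg: float,
    phantom: PhantomSpec,
    rng: np.random.Generator | None = None,
    modulation_strength: float = 0.0,
    cord_block: bool = True,
) -> tuple[LeafPairAperture, ...]:
    """Aperture conforming to the PTV projections with the cord shadow blocked.

    Per leaf pair, the opening is the union span of the spherical-target
    projections (plus a fixed penumbra margin).  Where the cord shadow falls
    inside the opening, the pair is pulled to one side of the shadow — the
    wider remaining side by default, occasionally the narrower one when a
    modulating ``rng`` is supplied — so every beam direction contributes a
    penumbra across the cord.  Optional random inward leaf perturbations
    emulate optimizer modulation.
    """
    u = _bev_axis(gantry_deg)
    targets = [
        (np.array(phantom.ptv1_center), phantom.ptv_radii_mm[0]),
        (np.array(phantom.ptv2_center), phantom.ptv_radii_mm[1]),
    ]
    cord_x = float(np.array(phantom.cord_center) @ u)
    rb = phantom.cord_radius_mm + CORD_BLOCK_MARGIN_MM
    pairs = []
    for i, (y_low, y_high) in enumerate(_leaf_pairs_y()):
        y_c = 0.5 * (y_low + y_high)
        left = math.inf
        right = -math.inf
        for center, r in targets:
            ry2 = r * r - y_c * y_c  # spherical cross-section at this pair's axial slice
            if ry2 <= 0:
                continue
            ry = math.sqrt(ry2)
            cx = float(center @ u)
            left = min(left, cx - ry - APERTURE_MARGIN_MM)
            right = max(right, cx + ry + APERTURE_MARGIN_MM)
        if not math.isfinite(left):
            pairs.append(LeafPairAperture(i, y_low, y_high, PARK_X_MM, PARK_X_MM))
            continue
        if cord_block and cord_x - rb < right and cord_x + rb > left:
            keep_left = (cord_x - rb - left) >= (right - cord_x - rb)
            if rng is not None and modulation_strength > 0 and rng.random() < 0.25:
                keep_left = not keep_left
            if keep_left:
                right = cord_x - rb
            else:
                left = cord_x + rb
            if left >= right:  # shadow swallowed the opening; close here
                left = right = cord_x - rb if keep_left else cord_x + rb
        if rng is not None and modulation_strength > 0 and left < right:
            width = right - left
            if rng.random() < 0.5:
                left = left + rng.uniform(0, 0.5 * modulation_strength * width)
            if rng.random() < 0.5:
                right = right - rng.uniform(0, 0.5 * modulation_strength * width)
            if left > right:
                left = right = 0.5 * (left + right)
        pairs.append(LeafPairAperture(i, y_low, y_high, left, right))
    return tuple(pairs)


def _segment_mus(total: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform MU split with +/-30% jitter, renormalized to the exact total."""
    w = 1.0 + rng.uniform(-0.3, 0.3, size=n)
    return total * w / w.sum()


def _build_imrt_plan(spec: PlanSpec, phantom: PhantomSpec) -> Plan:
    rng = np.random.default_rng(spec.seed)
    n_beams = spec.n_beams_or_arcs
    start = rng.uniform(0.0, 360.0 / n_beams)
    angles = (start + 360.0 * np.arange(n_beams) / n_beams) % 360.0
    mu_per_beam = _segment_mus(spec.total_mu, n_beams, rng)
    beams = []
    for gantry, beam_mu in zip(angles, mu_per_beam):
        seg_mus = _segment_mus(beam_mu, spec.segments_per_beam, rng)
        segments = []
        for k, mu in enumerate(seg_mus):
            ap = conformal_aperture(
                gantry, phantom, rng=rng,
                modulation_strength=0.0 if k == 0 else spec.modulation_strength,
            )
            segments.append(Segment(ap, float(mu), float(gantry)))
        beams.append(Beam(tuple(segments)))
    return Plan(spec.plan_id, "imrt", tuple(beams))


def _build_vmat_plan(spec: PlanSpec, phantom: PhantomSpec) -> Plan:
    rng = np.random.default_rng(spec.seed)
    n_arcs = spec.n_beams_or_arcs
    n_cp = int(round(360.0 / ARC_CONTROL_POINT_DEG))
    mu_per_arc = _segment_mus(spec.total_mu, n_arcs, rng)
    beams = []
    for arc, arc_mu in enumerate(mu_per_arc):
        start = rng.uniform(0.0, ARC_CONTROL_POINT_DEG)
        angles = (start + ARC_CONTROL_POINT_DEG * np.arange(n_cp)) % 360.0
        cp_mus = _segment_mus(arc_mu, n_cp, rng)  # variable dose rate
        for gantry, mu in zip(angles, cp_mus):
            ap = conformal_aperture(
                gantry, phantom, rng=rng, modulation_strength=spec.modulation_strength
            )
            beams.append(Beam((Segment(ap, float(mu), float(gantry)),)))
    return Plan(spec.plan_id, "vmat", tuple(beams))


def generate_plan_suite(
    seed: int, phantom: PhantomSpec | None = None, segments_per_beam: int = 8
) -> list[tuple[PlanSpec, Plan]]:
    """The nine-plan suite: 5 step-and-shoot (7,7,7,9,9 beams) + 4 arcs (2,2,2,3).

    Reproducible: a ``SeedSequence`` fans the master seed out to one child
    seed per plan, and per-plan modulation strengths are drawn from the plan
    stream, emulating "uniquely optimized" plans.
    """
    phantom = phantom or default_phantom()
    children = np.random.SeedSequence(seed).spawn(len(PLAN_TABLE))
    suite = []
    for (plan_id, technique, n, total_mu), child in zip(PLAN_TABLE, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        mod = float(np.random.default_rng(child_seed).uniform(0.15, 0.35))
        spec = PlanSpec(
            plan_id=plan_id,
            technique=technique,
            n_beams_or_arcs=n,
            segments_per_beam=segments_per_beam if technique == "imrt" else 1,
            total_mu=total_mu,
            modulation_strength=mod,
            seed=child_seed,
        )
        build = _build_imrt_plan if technique == "imrt" else _build_vmat_plan
        suite.append((spec, build(spec, phantom)))
    return suite


def open_field_plan(field_size_mm: float = 100.0, mu: float = 100.0, gantry_deg: float = 0.0) -> Plan:
    """A single square open field (reference geometry for sensitivity baselines)."""
    half = field_size_mm / 2.0
    pairs = []
    for i, (y_low, y_high) in enumerate(_leaf_pairs_y()):
        y_c = 0.5 * (y_low + y_high)
        if abs(y_c) <= half:
            pairs.append(LeafPairAperture(i, y_low, y_high, -half, half))
        else:
            pairs.append(LeafPairAperture(i, y_low, y_high, PARK_X_MM, PARK_X_MM))
    seg = Segment(tuple(pairs), mu, gantry_deg)
    return Plan(f"OPEN{field_size_mm:g}", "imrt", (Beam((seg,)),))
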