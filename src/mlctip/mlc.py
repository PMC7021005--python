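"""Double-step MLC leaf-tip transmission model.

The leaf end is modeled as a double step in transmission: fully open beyond
the effective tip position, a partially transmitting tip region of width ``w``
under the leaf end, and full intraleaf attenuation ``T`` beyond that.  The
effective tip position is the nominal position shifted outward by the signed
leaf-tip offset ``delta``: a positive offset retracts both leaves of a pair,
enlarging the effective field; a negative offset shrinks it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamModelParams",
    "LeafPairAperture",
    "Segment",
    "Beam",
    "Plan",
    "ContractError",
    "effective_edges",
    "leaf_pair_transmission",
    "segment_transmission_map",
]


class ContractError(ValueError):
    """A caller violated an operation's precondition."""


#: Supported rules deriving the tip-region transmission tau from the
#: intraleaf transmission T.  "sqrt" is the default (geometric interpolation
#: between open and fully attenuated, giving a true double step with
#: T < tau < 1); "intraleaf" sets tau = T, collapsing the tip region to an
#: extension of the full leaf.
TIP_RULES = ("sqrt", "intraleaf")


@dataclass(frozen=True)
class BeamModelParams:
    """MLC beam-model parameters: leaf-tip offset/width and transmissions.

    Parameters
    ----------
    leaf_tip_offset_mm:
        Signed offset of each modeled leaf tip from its nominal position, in
        mm at isocenter.  Positive retracts the leaf (larger effective field).
    leaf_tip_width_mm:
        Width of the partially transmitting tip region, mm.
    leaf_transmission:
        Intraleaf transmission T, the fraction transmitted through the full
        leaf thickness.
    tip_rule:
        Rule deriving the tip transmission tau from T (see ``TIP_RULES``).
    """

    leaf_tip_offset_mm: float = 0.0
    leaf_tip_width_mm: float = 4.5
    leaf_transmission: float = 0.005
    tip_rule: str = "sqrt"
    model_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.leaf_transmission < 1.0:
            raise ValueError(f"leaf_transmission must be in (0, 1), got {self.leaf_transmission}")
        if self.leaf_tip_width_mm < 0.0:
            raise ValueError(f"leaf_tip_width_mm must be >= 0, got {self.leaf_tip_width_mm}")
        if abs(self.leaf_tip_offset_mm) > 5.0:
            raise ValueError(
                f"|leaf_tip_offset_mm| > 5 mm is outside the physically sane range "
                f"(got {self.leaf_tip_offset_mm})"
            )
        if self.tip_rule not in TIP_RULES:
            raise ValueError(f"unknown tip_rule {self.tip_rule!r}; expected one of {TIP_RULES}")
        if not self.model_id:
            object.__setattr__(self, "model_id", self.default_model_id())
        # cache tau; invariant T <= tau <= 1 holds for both rules
        object.__setattr__(self, "_tau", self._compute_tau())

    def _compute_tau(self) -> float:
        if self.tip_rule == "sqrt":
            return math.sqrt(self.leaf_transmission)
        return self.leaf_transmission

    @property
    def tip_transmission(self) -> float:
        """Tip-region transmission tau, derived from T by ``tip_rule``."""
        return self._tau  # type: ignore[attr-defined]

    def default_model_id(self) -> str:
        return f"off{self.leaf_tip_offset_mm:+.1f}_w{self.leaf_tip_width_mm:.1f}"

    def replace(self, **kwargs) -> "BeamModelParams":
        fields = dict(
            leaf_tip_offset_mm=self.leaf_tip_offset_mm,
            leaf_tip_width_mm=self.leaf_tip_width_mm,
            leaf_transmission=self.leaf_transmission,
            tip_rule=self.tip_rule,
        )
        fields.update(kwargs)
        return BeamModelParams(**fields)


@dataclass(frozen=True)
class LeafPairAperture:
    """Nominal opening of one leaf pair.

    ``x`` is the leaf-travel (crossplane) axis, ``y`` the pair axis; both in
    mm at the isocenter plane, beam's-eye view.
    """

    pair_index: int
    y_low_mm: float
    y_high_mm: float
    left_pos_mm: float
    right_pos_mm: float

    def __post_init__(self) -> None:
        if self.left_pos_mm > self.right_pos_mm:
            raise ValueError(
                f"pair {self.pair_index}: left ({self.left_pos_mm}) > right ({self.right_pos_mm})"
            )
        if self.y_low_mm >= self.y_high_mm:
            raise ValueError(f"pair {self.pair_index}: y_low >= y_high")


@dataclass(frozen=True)
class Segment:
    """One static MLC aperture with its monitor-unit weight."""

    aperture: tuple[LeafPairAperture, ...]
    mu: float
    gantry_deg: float
    collimator_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        idx = [p.pair_index for p in self.aperture]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate pair_index in aperture")


@dataclass(frozen=True)
class Beam:
    """A set of segments delivered from a single gantry angle.

    Arc deliveries are discretized into control points; each control point is
    represented as its own single-segment beam at that gantry angle.
    """

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a beam needs at least one segment")
        angles = {s.gantry_deg for s in self.segments}
        if len(angles) > 1:
            raise ContractError(f"segments of one beam must share gantry angle, got {sorted(angles)}")

    @property
    def gantry_deg(self) -> float:
        return self.segments[0].gantry_deg

    @property
    def mu(self) -> float:
        return sum(s.mu for s in self.segments)


@dataclass(frozen=True)
class Plan:
    """A deliverable treatment plan: a labeled collection of beams."""

    plan_id: str
    technique: str  # "imrt" (step-and-shoot) or "vmat" (arc control points)
    beams: tuple[Beam, ...]

    @property
    def total_mu(self) -> float:
        return sum(b.mu for b in self.beams)

    def scaled(self, factor: float) -> "Plan":
        """Plan with every segment MU multiplied by ``factor``."""
        beams = tuple(
            Beam(tuple(
                Segment(s.aperture, s.mu * factor, s.gantry_deg, s.collimator_deg)
                for s in b.segments
            ))
            for b in self.beams
        )
        return Plan(self.plan_id, self.technique, beams)


def effective_edges(pair: LeafPairAperture, model: BeamModelParams) -> tuple[float, float]:
    """Effective (left, right) tip positions after applying the offset.

    Each tip retracts outward by the offset; if the effective gap would be
    negative the pair is clamped to a zero-width gap at the nominal midpoint.
    """
    delta = model.leaf_tip_offset_mm
    left = pair.left_pos_mm - delta
    right = pair.right_pos_mm + delta
    if left > right:
        mid = 0.5 * (pair.left_pos_mm + pair.right_pos_mm)
        return mid, mid
    return left, right


def _single_leaf_profiles(
    x: np.ndarray, left_eff: float, right_eff: float, model: BeamModelParams
) -> np.ndarray:
    """Pointwise minimum of the two single-leaf double-step profiles."""
    T = model.leaf_transmission
    tau = model.tip_transmission
    w = model.leaf_tip_width_mm
    # left leaf occupies x < left_eff: open / tip band [left_eff - w, left_eff) / T
    left_prof = np.where(x >= left_eff, 1.0, np.where(x >= left_eff - w, tau, T))
    right_prof = np.where(x <= right_eff, 1.0, np.where(x <= right_eff + w, tau, T))
    return np.minimum(left_prof, right_prof)


def leaf_pair_transmission(
    x_mm: float | np.ndarray, pair: LeafPairAperture, model: BeamModelParams
) -> float | np.ndarray:
    """Transmission of one leaf pair at crossplane position(s) ``x_mm``.

    The pair profile is the pointwise minimum of the two single-leaf
    double-step profiles; values lie in [T, 1].
    """
    left_eff, right_eff = effective_edges(pair, model)
    x = np.asarray(x_mm, dtype=float)
    out = _single_leaf_profiles(x, left_eff, right_eff, model)
    if np.isscalar(x_mm) or np.ndim(x_mm) == 0:
        return float(out)
    return out


def segment_transmission_map(segment: Segment, model: BeamModelParams, grid) -> "np.ndarray":
    """Rasterize a segment's aperture into a (ny, nx) transmission map.

    Each grid row takes the profile of the leaf pair whose lateral interval
    contains its ``y``; rows beyond the leaf bank are blocked by the backup
    jaws and read as the intraleaf transmission ``T``.  The grid must cover
    the full leaf-pair extent.

    Returns the bare value array; callers wrap it in a
    :class:`~mlctip.dose.FluenceMap` as needed.
    """
    xs = grid.x_coords()
    ys = grid.y_coords()
    y_lows = np.array([p.y_low_mm for p in segment.aperture])
    y_highs = np.array([p.y_high_mm for p in segment.aperture])
    if y_lows.min() < ys.min() - 1e-9 or y_highs.max() > ys.max() + 1e-9:
        raise ContractError(
            "grid does not cover all leaf pairs: rows at "
            f"y in [{ys.min():g}, {ys.max():g}] vs bank [{y_lows.min():g}, {y_highs.max():g}]"
        )
    values = np.full((grid.ny, grid.nx), model.leaf_transmission, dtype=float)
    # profiles are constant per pair; fill all rows belonging to each pair
    for pair in segment.aperture:
        row_mask = (ys >= pair.y_low_mm) & (ys < pair.y_high_mm)
        if pair.y_high_mm >= y_highs.max():  # topmost pair owns its upper edge
            row_mask |= ys == pair.y_high_mm
        if not row_mask.any():
            continue
        left_eff, right_eff = effective_edges(pair, model)
        values[row_mask, :] = _single_leaf_profiles(xs, left_eff, right_eff, model)[None, :]
    return values
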