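"""Plain-text serialization: beam-model parameter files, plan tables, maps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dose import DoseMap, FluenceMap, GridSpec
from .mlc import Beam, BeamModelParams, LeafPairAperture, Plan, Segment
from .qa import SampledDose

__all__ = [
    "save_beam_model",
    "load_beam_model",
    "plan_to_frame",
    "frame_to_plan",
    "save_plan_csv",
    "load_plan_csv",
    "save_map_csv",
    "load_map_csv",
    "save_sampled_csv",
    "save_manifest",
]


def save_beam_model(model: BeamModelParams, path: str | Path) -> None:
    data = {
        "model_id": model.model_id,
        "leaf_tip_offset_mm": model.leaf_tip_offset_mm,
        "leaf_tip_width_mm": model.leaf_tip_width_mm,
        "leaf_transmission": model.leaf_transmission,
        "tip_rule": model.tip_rule,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_beam_model(path: str | Path) -> BeamModelParams:
    data = yaml.safe_load(Path(path).read_text())
    return BeamModelParams(
        leaf_tip_offset_mm=float(data["leaf_tip_offset_mm"]),
        leaf_tip_width_mm=float(data["leaf_tip_width_mm"]),
        leaf_transmission=float(data["leaf_transmission"]),
        tip_rule=data.get("tip_rule", "sqrt"),
        model_id=data.get("model_id", ""),
    )


def plan_to_frame(plan: Plan) -> pd.DataFrame:
    """One row per (beam, segment, leaf pair)."""
    rows = []
    for bi, beam in enumerate(plan.beams):
        for si, seg in enumerate(beam.segments):
            for pair in seg.aperture:
                rows.append(
                    dict(
                        plan_id=plan.plan_id,
                        technique=plan.technique,
                        beam=bi,
                        segment=si,
                        gantry_deg=seg.gantry_deg,
                        collimator_deg=seg.collimator_deg,
                        mu=seg.mu,
                        pair_index=pair.pair_index,
                        y_low_mm=pair.y_low_mm,
                        y_high_mm=pair.y_high_mm,
                        left_mm=pair.left_pos_mm,
                        right_mm=pair.right_pos_mm,
                    )
                )
    return pd.DataFrame(rows)


def frame_to_plan(df: pd.DataFrame) -> Plan:
    plan_ids = df["plan_id"].unique()
    if len(plan_ids) != 1:
        raise ValueError("frame_to_plan expects a single plan per frame")
    beams = []
    for _, bdf in df.groupby("beam", sort=True):
        segments = []
        for _, sdf in bdf.groupby("segment", sort=True):
            pairs = tuple(
                LeafPairAperture(
                    int(r.pair_index), r.y_low_mm, r.y_high_mm, r.left_mm, r.right_mm
                )
                for r in sdf.sort_values("pair_index").itertuples()
            )
            first = sdf.iloc[0]
            segments.append(
                Segment(pairs, float(first.mu), float(first.gantry_deg), float(first.collimator_deg))
            )
        beams.append(Beam(tuple(segments)))
    return Plan(str(plan_ids[0]), str(df["technique"].iloc[0]), tuple(beams))


def save_plan_csv(plan: Plan, path: str | Path) -> None:
    # %.17g keeps doubles round-trip exact through the text format
    plan_to_frame(plan).to_csv(path, index=False, float_format="%.17g")


def load_plan_csv(path: str | Path) -> Plan:
    return frame_to_plan(pd.read_csv(path, float_precision="round_trip"))


def save_map_csv(dose_map: FluenceMap | DoseMap, path: str | Path) -> None:
    g = dose_map.grid
    header = f"# grid origin_mm=({g.origin_mm[0]},{g.origin_mm[1]}) spacing_mm={g.spacing_mm} nx={g.nx} ny={g.ny}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, dose_map.values, delimiter=",")


def load_map_csv(path: str | Path) -> DoseMap:
    with open(path) as fh:
        header = fh.readline().strip()
        values = np.loadtxt(fh, delimiter=",")
    parts = dict(p.split("=", 1) for p in header.lstrip("# ").split() if "=" in p)
    ox, oy = (float(v) for v in parts["origin_mm"].strip("()").split(","))
    grid = GridSpec((ox, oy), float(parts["spacing_mm"]), int(parts["nx"]), int(parts["ny"]))
    return DoseMap(grid, values)


def save_sampled_csv(sampled: SampledDose, path: str | Path) -> None:
    pd.DataFrame(
        {"x_mm": sampled.points_xy[:, 0], "y_mm": sampled.points_xy[:, 1], "dose": sampled.values}
    ).to_csv(path, index=False)


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
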