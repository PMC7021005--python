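"""Orchestration of the full in-silico sensitivity and detectability study.

The study recalculates a fixed nine-plan suite on a grid of MLC beam models
(leaf-tip offset x leaf-tip width), extracts TLD-ROI dose deviations against
the clinical model, runs virtual diode-array QA with gamma analysis for the
offset sweep, and summarizes detectability as per-offset ROC curves.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dose import BeamDoseCache, GridSpec, KernelParams
from .gamma import CRITERIA_2_2, CRITERIA_3_3, GammaCriteria, gamma_index
from .io import save_manifest
from .mlc import BeamModelParams, Plan
from .plans import (
    PhantomSpec,
    PlanSpec,
    default_phantom,
    generate_plan_suite,
    open_field_plan,
    roi_sample_points,
    tld_rois,
)
from .qa import ArraySpec, predicted_plane_dose, virtual_measurement
from .roc import ROCCurve, auc_from_scores, roc_curve

__all__ = [
    "StudyConfig",
    "build_model_grid",
    "run_sensitivity",
    "run_detectability",
    "open_field_sensitivity",
    "summarize",
    "run_all",
]

log = logging.getLogger("mlctip")

DEFAULT_OFFSETS = tuple(np.round(np.arange(-2.0, 2.01, 0.5), 1))
DEFAULT_WIDTHS = (2.5, 4.5, 6.0)


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the default study.

    The model grid is the Cartesian product ``offsets_mm x widths_mm``; the
    clinical model (offset -0.5 mm, width 4.5 mm) must be contained in it.
    QA detectability sweeps only the offsets at the clinical width.
    """

    offsets_mm: tuple[float, ...] = DEFAULT_OFFSETS
    widths_mm: tuple[float, ...] = DEFAULT_WIDTHS
    clinical_offset_mm: float = -0.5
    clinical_width_mm: float = 4.5
    leaf_transmission: float = 0.005
    tip_rule: str = "sqrt"
    criteria: tuple[GammaCriteria, ...] = (CRITERIA_2_2, CRITERIA_3_3)
    noise_sigma_pct: float = 0.5
    n_replicates: int = 20
    master_seed: int = 1
    grid: GridSpec = field(default_factory=GridSpec)
    kernel: KernelParams = field(default_factory=KernelParams)
    array: ArraySpec = field(default_factory=ArraySpec)
    qa_eval_spacing_mm: float = 2.0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.offsets_mm or not self.widths_mm:
            raise ValueError("offset and width lists must be non-empty")
        offs = np.asarray(self.offsets_mm)
        if np.any(np.diff(offs) <= 0):
            raise ValueError("offsets_mm must be sorted increasing")
        if len(offs) > 2 and not np.allclose(np.diff(offs), np.diff(offs)[0]):
            raise ValueError("offsets_mm must be uniformly spaced")
        if self.clinical_offset_mm not in self.offsets_mm or self.clinical_width_mm not in self.widths_mm:
            raise ValueError("the clinical model must be contained in the model grid")

    def clinical_model(self) -> BeamModelParams:
        return BeamModelParams(
            self.clinical_offset_mm, self.clinical_width_mm, self.leaf_transmission, self.tip_rule
        )

    def phantom(self) -> PhantomSpec:
        return default_phantom()


def build_model_grid(config: StudyConfig) -> list[BeamModelParams]:
    """All offset x width combinations, deterministic order and ids."""
    return [
        BeamModelParams(off, w, config.leaf_transmission, config.tip_rule)
        for off in config.offsets_mm
        for w in config.widths_mm
    ]


def _roi_doses(cache: BeamDoseCache, rois) -> dict[str, float]:
    return {roi.name: float(cache.dose_at(roi_sample_points(roi)).mean()) for roi in rois}


def run_sensitivity(
    config: StudyConfig, suite: list[tuple[PlanSpec, Plan]] | None = None
) -> pd.DataFrame:
    """TLD-ROI percent dose deviation of every model against the clinical model.

    Returns one row per (plan, model, ROI) with
    ``pct_dev = 100 * (D_model - D_clinical) / D_clinical``; clinical-model
    rows are exactly zero by construction.
    """
    phantom = config.phantom()
    rois = tld_rois(phantom)
    suite = suite or generate_plan_suite(config.master_seed, phantom)
    models = build_model_grid(config)
    clinical = config.clinical_model()
    rows = []
    for spec, plan in suite:
        log.info("sensitivity: plan %s (%s)", spec.plan_id, spec.technique)
        clin_cache = BeamDoseCache(plan, clinical, phantom.radius_mm, config.kernel, config.grid)
        clin_doses = _roi_doses(clin_cache, rois)
        if any(d <= 0 for d in clin_doses.values()):
            raise RuntimeError(
                f"plan {spec.plan_id}: zero clinical ROI dose — broken plan generator"
            )
        for model in models:
            if model == clinical:
                doses = clin_doses
            else:
                cache = BeamDoseCache(plan, model, phantom.radius_mm, config.kernel, config.grid)
                doses = _roi_doses(cache, rois)
            for roi in rois:
                d = doses[roi.name]
                rows.append(
                    dict(
                        plan_id=spec.plan_id,
                        technique=spec.technique,
                        model_id=model.model_id,
                        offset_mm=model.leaf_tip_offset_mm,
                        width_mm=model.leaf_tip_width_mm,
                        roi=roi.name,
                        gradient=roi.gradient,
                        dose=d,
                        pct_dev=100.0 * (d - clin_doses[roi.name]) / clin_doses[roi.name],
                    )
                )
    return pd.DataFrame(rows)


def _noise_seeds(config: StudyConfig, n_plans: int) -> list[list[int]]:
    """Per-(plan, replicate) noise seeds fanned out from the master seed."""
    root = np.random.SeedSequence(config.master_seed, spawn_key=(1,))
    return [
        [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(config.n_replicates)]
        for child in root.spawn(n_plans)
    ]


def run_detectability(
    config: StudyConfig, suite: list[tuple[PlanSpec, Plan]] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, float], ROCCurve]]:
    """Virtual QA of the offset sweep: gamma pass rates, per-offset ROC, AUC.

    The truth (delivered) model is always the clinical one; candidates are
    the offset sweep at the clinical width.  Each plan gets
    ``n_replicates`` noise-replicate deliveries so the ROC is non-degenerate.
    Returns (records, auc summary, curves keyed by (criteria, deviation)).
    """
    phantom = config.phantom()
    suite = suite or generate_plan_suite(config.master_seed, phantom)
    clinical = config.clinical_model()
    candidates = [
        BeamModelParams(off, config.clinical_width_mm, config.leaf_transmission, config.tip_rule)
        for off in config.offsets_mm
    ]
    seeds = _noise_seeds(config, len(suite))
    search_margin = 3.0 * max(c.dta_mm for c in config.criteria)
    eval_extent = config.array.extent_mm + search_margin + 2.0

    rows = []
    for (spec, plan), plan_seeds in zip(suite, seeds):
        log.info("detectability: plan %s", spec.plan_id)
        caches = {
            m.model_id: BeamDoseCache(plan, m, phantom.radius_mm, config.kernel, config.grid)
            for m in candidates
        }
        eval_maps = {
            m.model_id: predicted_plane_dose(
                plan, m, phantom, config.kernel, config.grid,
                extent_mm=eval_extent, spacing_mm=config.qa_eval_spacing_mm,
                cache=caches[m.model_id],
            )
            for m in candidates
        }
        for rep_seed in plan_seeds:
            array = dataclasses.replace(
                config.array, noise_sigma_pct=config.noise_sigma_pct, seed=rep_seed
            )
            measured = virtual_measurement(
                plan, clinical, array, phantom, config.kernel, config.grid,
                cache=caches[clinical.model_id],
            )
            for model in candidates:
                for crit in config.criteria:
                    res = gamma_index(measured, eval_maps[model.model_id], crit)
                    rows.append(
                        dict(
                            plan_id=spec.plan_id,
                            technique=spec.technique,
                            candidate_model_id=model.model_id,
                            offset_mm=model.leaf_tip_offset_mm,
                            width_mm=model.leaf_tip_width_mm,
                            offset_deviation_mm=round(
                                abs(model.leaf_tip_offset_mm - config.clinical_offset_mm), 3
                            ),
                            criteria=crit.label,
                            replicate_seed=rep_seed,
                            n_evaluated=res.n_evaluated,
                            pass_rate=res.pass_rate,
                            label=0 if model == clinical else 1,
                        )
                    )
    records = pd.DataFrame(rows)
    summary, curves = summarize_roc(records)
    return records, summary, curves


def summarize_roc(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[tuple[str, float], ROCCurve]]:
    """Per-(criteria, offset deviation) ROC against the clinical negatives.

    Also includes a pooled row per criteria (all perturbed offsets together),
    keyed by deviation ``-1``.
    """
    rows = []
    curves: dict[tuple[str, float], ROCCurve] = {}
    for crit, cdf in records.groupby("criteria", sort=True):
        neg = cdf[cdf["label"] == 0]["pass_rate"].to_numpy()
        for dev, ddf in cdf[cdf["label"] == 1].groupby("offset_deviation_mm", sort=True):
            pos = ddf["pass_rate"].to_numpy()
            curve = roc_curve(
                np.concatenate([pos, neg]),
                np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)]),
            )
            curves[(crit, float(dev))] = curve
            rows.append(
                dict(criteria=crit, offset_deviation_mm=float(dev), auc=curve.auc,
                     n_pos=len(pos), n_neg=len(neg))
            )
        pooled = cdf[cdf["label"] == 1]["pass_rate"].to_numpy()
        curves[(crit, -1.0)] = roc_curve(
            np.concatenate([pooled, neg]),
            np.concatenate([np.ones(len(pooled), int), np.zeros(len(neg), int)]),
        )
        rows.append(
            dict(criteria=crit, offset_deviation_mm=-1.0, auc=curves[(crit, -1.0)].auc,
                 n_pos=len(pooled), n_neg=len(neg))
        )
    return pd.DataFrame(rows), curves


def open_field_sensitivity(config: StudyConfig, field_size_mm: float = 100.0) -> float:
    """Relative central-axis dose change of a square open field per mm of offset.

    Computed as the full-range slope ``|D(max) - D(min)| / D(clinical)``
    divided by the offset range in mm.
    """
    plan = open_field_plan(field_size_mm)
    phantom = config.phantom()
    center = np.array([[0.0, 0.0, 0.0]])
    doses = {}
    for off in (config.offsets_mm[0], config.clinical_offset_mm, config.offsets_mm[-1]):
        model = BeamModelParams(off, config.clinical_width_mm, config.leaf_transmission, config.tip_rule)
        cache = BeamDoseCache(plan, model, phantom.radius_mm, config.kernel, config.grid)
        doses[off] = float(cache.dose_at(center)[0])
    span = config.offsets_mm[-1] - config.offsets_mm[0]
    return abs(doses[config.offsets_mm[-1]] - doses[config.offsets_mm[0]]) / (
        doses[config.clinical_offset_mm] * span
    )


def roi_offset_sensitivity(sens: pd.DataFrame, config: StudyConfig) -> pd.Series:
    """Mean over plans of |pct dev| range per mm of offset, per ROI (clinical width)."""
    at_w = sens[sens["width_mm"] == config.clinical_width_mm]
    span = config.offsets_mm[-1] - config.offsets_mm[0]
    per_plan = (
        at_w.groupby(["roi", "plan_id"])["pct_dev"].agg(lambda s: (s.max() - s.min()) / 100.0 / span)
    )
    return per_plan.groupby("roi").mean()


def effect_ranges(sens: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Max |pct dev| per ROI for the offset sweep vs the width sweep."""
    offset_sweep = sens[sens["width_mm"] == config.clinical_width_mm]
    width_sweep = sens[sens["offset_mm"] == config.clinical_offset_mm]
    return pd.DataFrame(
        {
            "offset_effect": offset_sweep.groupby("roi")["pct_dev"].apply(lambda s: s.abs().max()),
            "width_effect": width_sweep.groupby("roi")["pct_dev"].apply(lambda s: s.abs().max()),
        }
    )


def curves_to_frame(curves: dict[tuple[str, float], ROCCurve]) -> pd.DataFrame:
    """Long-format (criteria, deviation, threshold, tpr, fpr) table of ROC curves."""
    rows = []
    for (crit, dev), curve in sorted(curves.items()):
        for t, tp, fp in zip(np.concatenate([[np.nan], curve.thresholds]), curve.tpr, curve.fpr):
            rows.append(dict(criteria=crit, offset_deviation_mm=dev, threshold=t, tpr=tp, fpr=fp))
    return pd.DataFrame(rows)


def summarize(
    config: StudyConfig,
    sens: pd.DataFrame,
    records: pd.DataFrame,
    roc_summary: pd.DataFrame,
    curves: dict[tuple[str, float], ROCCurve],
    suite: list[tuple[PlanSpec, Plan]],
) -> dict[str, Path]:
    """Write the study's CSV outputs and the run manifest; returns file paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["sensitivity"] = out / "sensitivity.csv"
    sens.to_csv(paths["sensitivity"], index=False)

    at_w = sens[sens["width_mm"] == config.clinical_width_mm]
    box = (
        at_w.groupby(["offset_mm", "technique", "roi"])["pct_dev"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    paths["sensitivity_summary"] = out / "sensitivity_summary.csv"
    box.to_csv(paths["sensitivity_summary"], index=False)

    paths["qa_records"] = out / "qa_records.csv"
    records.to_csv(paths["qa_records"], index=False)

    paths["roc_summary"] = out / "roc_summary.csv"
    roc_summary.to_csv(paths["roc_summary"], index=False)

    paths["roc_curves"] = out / "roc_curves.csv"
    curves_to_frame(curves).to_csv(paths["roc_curves"], index=False)

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "plan_seeds": {spec.plan_id: spec.seed for spec, _ in suite},
        "noise_seeds": _noise_seeds(config, len(suite)),
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("grid", "kernel", "array", "criteria", "output_dir")
        },
        "grid": dataclasses.asdict(config.grid),
        "kernel": dataclasses.asdict(config.kernel),
        "array": dataclasses.asdict(config.array),
        "criteria": [c.label for c in config.criteria],
    }
    paths["manifest"] = out / "manifest.json"
    save_manifest(manifest, paths["manifest"])
    return paths


def run_all(config: StudyConfig | None = None) -> dict:
    """Execute the default study end to end and write all outputs."""
    config = config or StudyConfig()
    phantom = config.phantom()
    suite = generate_plan_suite(config.master_seed, phantom)
    sens = run_sensitivity(config, suite)
    records, roc_summary, curves = run_detectability(config, suite)
    paths = summarize(config, sens, records, roc_summary, curves, suite)
    return {
        "suite": suite,
        "sensitivity": sens,
        "qa_records": records,
        "roc_summary": roc_summary,
        "curves": curves,
        "paths": paths,
    }
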