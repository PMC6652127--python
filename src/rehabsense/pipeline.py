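"""End-to-end orchestration: simulate -> process -> localize -> features ->
stats -> predict, with provenance sufficient to rerun any stage.

The activity classifier is trained on a small, separately seeded calibration
cohort whose ground-truth window labels come from its simulation schedules
(standing in for the labelled training recordings a real deployment would
collect), then applied to the analysis cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SyntheticCohort, generate_cohort, window_ground_truth
from .config import PipelineConfig
from .features import build_feature_table
from .localize import localize_windows
from .recognize import (
    HierarchicalModel,
    classify_windows,
    extract_window_features,
    train_hierarchical_classifier,
)
from .signal import FilterSpec, analyze_stream

logger = logging.getLogger(__name__)

# Feature subsets evaluated by the outcome-model stage (strongest single
# features and their combinations).
MODEL_SUBSETS = [
    ["time_pct_standing"],
    ["time_pct_standing", "time_pct_laying"],
    ["time_pct_standing", "time_pct_laying", "ei_resident_room"],
    ["ei_resident_room"],
]


@dataclass
class PipelineResult:
    config: PipelineConfig
    model: HierarchicalModel
    windows: pd.DataFrame  # all patient-day windows, stacked
    feature_table: pd.DataFrame
    comparisons: pd.DataFrame
    model_report: pd.DataFrame
    provenance: dict


def _labelled_windows(cohort: SyntheticCohort, config: PipelineConfig,
                      pid: str, day: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Window features plus ground-truth labels for one calibration day."""
    stream = cohort.accel(pid, day)
    wt = analyze_stream(
        stream,
        FilterSpec(config.filter_order, config.filter_band_hz, config.sample_rate_hz),
        config.mad_threshold_ms2,
        config.window_s,
        config.overlap_s,
    )
    feats = extract_window_features(wt.sm_filtered_ms2, config.sample_rate_hz)
    gt = window_ground_truth(cohort.schedule(pid, day), wt.grid.start_time, config.window_s)
    loco = np.where(gt["motion"].to_numpy() == "walk", "walking", "stationary")
    return feats, loco, gt["posture"].to_numpy()


# Scripted calibration protocol: training subjects perform a balanced mix of
# activities (walking deliberately over-represented relative to free living)
# so every stage class is well covered, as a dedicated labelled training
# collection would be.
CALIBRATION_EFFECT_MAP = {
    "time_pct_standing": (35.0, 35.0, 5.0),
    "time_pct_sitting": (25.0, 25.0, 5.0),
    "time_pct_laying": (32.0, 32.0, 5.0),
    "time_pct_walking": (8.0, 8.0, 1.5),
    "time_pct_active": (30.0, 30.0, 5.0),
    "ei_resident_room": (43.32, 26.99, 13.06),
    "ei_therapy_room": (70.75, 68.49, 40.0),
}


def train_activity_model(config: PipelineConfig, max_attempts: int = 5) -> HierarchicalModel:
    """Train the hierarchy on a separately seeded, scripted calibration
    cohort.  If a calibration draw still misses a stage class, the cohort is
    redrawn (deterministically from the pipeline seed)."""
    base = config.cohort_config()
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        cal_cfg = replace(
            base,
            n_community=2,
            n_hospital=1,
            n_days=max(1, config.n_calibration_days // 3),
            seed=(config.seed + 101 + 1000 * attempt) % (2**31),
            p_remove_early=0.0,
            p_midday_gap=0.0,
            group_effect_map=dict(CALIBRATION_EFFECT_MAP),
        )
        cal = generate_cohort(cal_cfg)
        parts = [
            _labelled_windows(cal, config, pid, day)
            for pid in cal.patient_ids()
            for day in range(1, cal_cfg.n_days + 1)
        ]
        feats = pd.concat([p[0] for p in parts], ignore_index=True)
        loco = np.concatenate([p[1] for p in parts])
        posture = np.concatenate([p[2] for p in parts])
        try:
            return train_hierarchical_classifier(
                feats, loco, posture, seed=config.seed, cv_folds=10
            )
        except ValueError as err:  # a stage class missing from this draw
            last_err = err
            logger.warning("calibration redraw (%s)", err)
    raise RuntimeError(f"could not assemble a calibration set: {last_err}")


def process_patient_day(
    cohort: SyntheticCohort,
    model: HierarchicalModel,
    config: PipelineConfig,
    pid: str,
    day: int,
) -> pd.DataFrame:
    """One patient-day through signal processing, activity recognition and
    localization; returns the per-window frame (with ground truth attached
    for later agreement audits)."""
    stream = cohort.accel(pid, day)
    wt = analyze_stream(
        stream,
        FilterSpec(config.filter_order, config.filter_band_hz, config.sample_rate_hz),
        config.mad_threshold_ms2,
        config.window_s,
        config.overlap_s,
    )
    if len(wt) == 0:
        return pd.DataFrame()
    feats = extract_window_features(wt.sm_filtered_ms2, config.sample_rate_hz)
    labels = classify_windows(model, feats, wt.mad_ms2)
    loc = localize_windows(
        cohort.rssi(pid, day), wt.grid.start_time, cohort.layout,
        config.window_s, config.rssi_clip_dbm,
    )
    gt = window_ground_truth(cohort.schedule(pid, day), wt.grid.start_time, config.window_s)
    out = pd.DataFrame(
        {
            "patient_id": pid,
            "day": day,
            "start_time_s": wt.grid.start_time,
            "credit_s": wt.grid.credit_s,
            "mad_ms2": wt.mad_ms2,
            "motion_state": wt.motion_state,
        }
    )
    out = pd.concat(
        [out, labels, loc[["raw_location", "canonical_location", "room"]]], axis=1
    )
    out["predicted_label"] = np.where(
        out["locomotion"] == "walking", "walk", out["posture"].astype(object)
    )
    out["gt_label"] = gt["label"]
    out["gt_room"] = gt["room"]
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage in order; idempotent for a fixed seed."""
    config.validate()
    cohort = generate_cohort(config.cohort_config())
    model = train_activity_model(config)

    window_tables: dict[tuple[str, int], pd.DataFrame] = {}
    day_rows = []
    all_windows = []
    for pid in cohort.patient_ids():
        for day in range(1, config.n_days + 1):
            win = process_patient_day(cohort, model, config, pid, day)
            window_tables[(pid, day)] = win
            sched = cohort.schedule(pid, day)
            therapy_min = (
                float(win.loc[win["room"] == "therapy", "credit_s"].sum()) / 60.0
                if len(win)
                else 0.0
            )
            day_rows.append(
                {
                    "patient_id": pid,
                    "day": day,
                    "uptime_min": sched.worn_seconds / 60.0,
                    "therapy_min": therapy_min,
                }
            )
            if len(win):
                all_windows.append(win)
    day_stats = pd.DataFrame(day_rows)
    windows = pd.concat(all_windows, ignore_index=True) if all_windows else pd.DataFrame()

    outcomes = {
        pid: cohort.params[pid].outcome for pid in cohort.patient_ids()
    }
    feature_table = build_feature_table(
        window_tables,
        day_stats,
        outcomes=outcomes,
        mad_threshold=config.mad_threshold_ms2,
        min_uptime_min=config.min_uptime_min,
        min_therapy_min=config.min_therapy_min,
        window_days=config.baseline_window_days,
    )

    from .stats import compare_features, evaluate_rf

    comparisons = pd.DataFrame()
    model_report = pd.DataFrame()
    if not feature_table.empty and feature_table["outcome"].nunique() == 2:
        comparisons = compare_features(feature_table)
        report_rows = []
        for subset in MODEL_SUBSETS:
            if not all(c in feature_table.columns for c in subset):
                continue
            try:
                ev = evaluate_rf(feature_table, subset)
            except ValueError as err:  # cohort too small for 3-fold CV
                logger.warning("skipping model subset %s: %s", subset, err)
                continue
            s = ev.summary
            report_rows.append(
                {
                    "features": "+".join(subset),
                    **{
                        f"{m}_{stat}": float(s.loc[m, stat])
                        for m in ("sensitivity", "specificity", "accuracy", "auc")
                        for stat in ("mean", "sd")
                    },
                    "flagged_folds": len(ev.flagged_folds),
                }
            )
        model_report = pd.DataFrame(report_rows)

    agreement = {}
    if len(windows):
        ok = windows["gt_label"].notna()
        agreement["label_agreement"] = float(
            (windows.loc[ok, "predicted_label"] == windows.loc[ok, "gt_label"]).mean()
        )
        agreement["room_agreement"] = float(
            (windows.loc[ok, "room"] == windows.loc[ok, "gt_room"]).mean()
        )
    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "version": __version__,
        "n_patients": len(cohort.patient_ids()),
        "n_patient_days": len(day_rows),
        "n_windows": int(len(windows)),
        "n_included": int(len(feature_table)),
        **agreement,
    }

    result = PipelineResult(
        config=config,
        model=model,
        windows=windows,
        feature_table=feature_table,
        comparisons=comparisons,
        model_report=model_report,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(result, cohort, day_stats, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, cohort: SyntheticCohort,
                   day_stats: pd.DataFrame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cohort.metadata.to_csv(out / "metadata.csv", index=False, float_format="%.3f")
    day_stats.to_csv(out / "day_stats.csv", index=False, float_format="%.3f")
    if len(result.windows):
        result.windows.drop(columns=["gt_label", "gt_room"]).to_csv(
            out / "windows.csv", index=False, float_format="%.6f"
        )
    result.feature_table.to_csv(out / "features.csv", index=False, float_format="%.6f")
    result.comparisons.to_csv(out / "stats.csv", index=False, float_format="%.6f")
    result.model_report.to_csv(out / "models.csv", index=False, float_format="%.6f")
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
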