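"""Config-driven pipeline: simulate -> track -> features -> train/classify
-> rater stats -> consolidated report.

One global seed fans out to per-stage seeds through a fixed stage-name hash
so each stage is independently reproducible; stage outputs are skipped if
present unless forced.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .classification import (
    ROIDataset,
    aggregate_patient,
    evaluate,
    predict_roi,
    save_model,
    train_ensemble,
)
from .curve_features import FeatureConfig, features_from_curves
from .datasets import make_milestone_dataset
from .rater_stats import RaterTable, build_report
from .roi_tracking import (
    ROISpec,
    TrackerConfig,
    curves_to_frame,
    extract_curve,
    track_roi,
)
from .synthetic_data import (
    JitterSpec,
    KineticParams,
    RaterModelParams,
    RegionSpec,
    SceneSpec,
    write_fixture_bundle,
)

__all__ = ["default_config", "validate_config", "run_pipeline", "stage_seed"]

log = logging.getLogger("fluoroperf")

STAGES = ("simulate", "track", "features", "train", "classify", "raterstats", "report")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def default_config(workdir: str | Path = "fluoroperf_run", seed: int = 0) -> dict:
    """A desk-scale end-to-end configuration (small frames, short video)."""
    return {
        "workdir": str(workdir),
        "seed": int(seed),
        "scene": {
            "frame_shape": [72, 96],
            "duration": 40.0,
            "fps": 30.0,
            "jitter": {"kind": "sinusoid", "amplitude": 3.0, "period_frames": 45},
            "noise_sd": 4.0,
            "wl_noise_sd": 100.0,
            "regions": [
                {"id": "lesion_a", "label": "malignant", "bbox": [12, 12, 30, 34]},
                {"id": "lesion_b", "label": "benign", "bbox": [40, 56, 58, 80]},
                {"id": "reference", "label": "normal", "bbox": [44, 12, 62, 34]},
            ],
        },
        "rater_model": {
            "n_raters": 32,
            "n_items": 14,
            "difficulty": 0.0,
            "skill": 0.0,
            "truth": ["benign", "cancer"] * 7,
        },
        "tracking": {"search_radius": 15, "min_correlation": 0.5, "subpixel": False},
        "features": {"reference_label": "normal"},
        "classifier": {
            "n_patients": 12,
            "rois_per_patient": 4,
            "noise_sd": 5.0,
            "duration": 60.0,
            "folds": 5,
            "aggregate": "any",
        },
    }


def _scene_from_config(cfg: dict, seed: int) -> SceneSpec:
    scene_cfg = dict(cfg)
    regions = [
        RegionSpec(r["id"], r["label"], tuple(r["bbox"])) for r in scene_cfg.pop("regions", [])
    ]
    jitter = JitterSpec(**scene_cfg.pop("jitter", {}))
    kinetics_cfg = scene_cfg.pop("class_kinetics", None)
    kwargs = {
        "frame_shape": tuple(scene_cfg.get("frame_shape", (72, 96))),
        "duration": scene_cfg.get("duration", 40.0),
        "fps": scene_cfg.get("fps", 30.0),
        "regions": regions,
        "jitter": jitter,
        "noise_sd": scene_cfg.get("noise_sd", 0.0),
        "wl_noise_sd": scene_cfg.get("wl_noise_sd", 0.0),
        "texture_seed": scene_cfg.get("texture_seed", seed),
        "seed": seed,
    }
    if kinetics_cfg is not None:
        kwargs["class_kinetics"] = {k: KineticParams(**v) for k, v in kinetics_cfg.items()}
    return SceneSpec(**kwargs)


def validate_config(config: dict) -> None:
    """Validate every stage's options before anything runs."""
    if "workdir" not in config:
        raise ValueError("config missing 'workdir'")
    scene_cfg = config.get("scene", {})
    if scene_cfg.get("fps", 30.0) <= 0:
        raise ValueError(f"invalid fps {scene_cfg.get('fps')}")
    if scene_cfg.get("duration", 40.0) <= 0:
        raise ValueError(f"invalid duration {scene_cfg.get('duration')}")
    _scene_from_config(scene_cfg, int(config.get("seed", 0)))  # full validation
    rm = config.get("rater_model", {})
    if rm:
        RaterModelParams(
            n_raters=rm["n_raters"], n_items=rm["n_items"],
            difficulty=rm.get("difficulty", 0.0), skill=rm.get("skill", 0.0),
            truth=rm["truth"], seed=0,
        )
    cl = config.get("classifier", {})
    if cl.get("folds", 5) < 2:
        raise ValueError("classifier folds must be >= 2")
    if cl.get("n_patients", 12) < cl.get("folds", 5):
        raise ValueError("need at least as many patients as folds")
    tr = config.get("tracking", {})
    TrackerConfig(**tr)


def run_pipeline(config: dict, force: bool = False) -> dict:
    """Run all stages in dependency order and write ``report.json``.

    Stage outputs already on disk are reused unless ``force``. Raises with
    the failing stage named; completed stage outputs are preserved.
    """
    validate_config(config)
    workdir = Path(config["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed, "stages": {}}

    stage = "simulate"
    try:
        sim_dir = workdir / "sim"
        manifest_path = sim_dir / "manifest.yaml"
        scene = _scene_from_config(config.get("scene", {}), stage_seed(seed, stage))
        rm = config.get("rater_model", {})
        rater_params = RaterModelParams(
            n_raters=rm.get("n_raters", 32), n_items=rm.get("n_items", 14),
            difficulty=rm.get("difficulty", 0.0), skill=rm.get("skill", 0.0),
            truth=rm.get("truth", ["benign", "cancer"] * 7),
            seed=stage_seed(seed, "raters"),
        )
        if force or not manifest_path.exists():
            log.info("stage %s: rendering scene (seed=%d)", stage, scene.seed)
            bundle = write_fixture_bundle(sim_dir, scene, rater_params)
        else:
            from .synthetic_data import read_fixture_bundle

            log.info("stage %s: reusing %s", stage, sim_dir)
            bundle = read_fixture_bundle(sim_dir)
        report["stages"]["simulate"] = {
            "n_frames": scene.n_frames, "frame_shape": list(scene.frame_shape),
            "seed": scene.seed, "regions": [r.id for r in scene.regions],
        }

        stage = "track"
        curves_path = workdir / "curves.csv"
        tracker_config = TrackerConfig(**config.get("tracking", {}))
        if force or not curves_path.exists():
            curves = []
            for reg in scene.regions:
                roi = ROISpec(id=reg.id, label=reg.label, bbox=reg.bbox)
                track = track_roi(bundle.rendered.white, roi, tracker_config)
                curve = extract_curve(bundle.rendered.nir, track, roi)
                curve.patient_id = "demo_patient"
                curves.append(curve)
            fio.write_curves_csv(curves_path, curves_to_frame(curves))
        else:
            from .roi_tracking import frame_to_curves

            curves = frame_to_curves(fio.read_curves_csv(curves_path), "demo_patient")
        report["stages"]["track"] = {
            "n_rois": len(curves),
            "valid_fraction": [
                float(np.mean(c.valid)) if c.valid is not None else 1.0 for c in curves
            ],
        }

        stage = "features"
        features_path = workdir / "features.csv"
        feat_cfg = config.get("features", {})
        reference_label = feat_cfg.get("reference_label", "normal")
        if force or not features_path.exists():
            features_df = features_from_curves(curves, reference_label=reference_label)
            fio.write_features_csv(features_path, features_df)
        else:
            features_df = fio.read_features_csv(features_path)
        report["stages"]["features"] = {
            "per_roi": features_df[
                ["roi_id", "label", "t_peak", "upslope", "downslope", "skew", "com"]
            ].to_dict(orient="records")
        }

        stage = "train"
        cl = config.get("classifier", {})
        train_df = make_milestone_dataset(
            n_patients=cl.get("n_patients", 12),
            rois_per_patient=cl.get("rois_per_patient", 4),
            noise_sd=cl.get("noise_sd", 5.0),
            duration=cl.get("duration", 60.0),
            seed=stage_seed(seed, stage),
        )
        fio.write_features_csv(workdir / "train_features.csv", train_df)
        dataset = ROIDataset.from_features_frame(train_df)
        model = train_ensemble(
            dataset, n_folds=cl.get("folds", 5), seed=stage_seed(seed, "cv")
        )
        save_model(model, workdir / "model.joblib")
        report["stages"]["train"] = {
            "family": model.family, "params": model.params,
            "cv_fold_accuracy": model.cv_fold_accuracy,
            "cv_mean_accuracy": model.cv_mean_accuracy,
        }

        stage = "classify"
        preds = predict_roi(model, dataset.features)
        preds["roi_id"] = train_df["roi_id"].to_numpy()
        preds["patient_id"] = train_df["patient_id"].to_numpy()
        preds["truth"] = train_df["label"].to_numpy()
        rule = cl.get("aggregate", "any")
        patient_calls = preds.groupby("patient_id")["call"].apply(
            lambda c: aggregate_patient(c, rule)
        )
        patient_truth = (
            train_df.groupby("patient_id")["label"].first().loc[patient_calls.index]
        )
        roi_eval = evaluate(
            pd.Series(preds["call"].to_numpy(), index=preds["roi_id"]),
            pd.Series(preds["truth"].to_numpy(), index=preds["roi_id"]),
        )
        patient_eval = evaluate(patient_calls, patient_truth, aggregation_rule=rule)
        preds.to_csv(workdir / "predictions.csv", index=False)
        report["stages"]["classify"] = {
            "roi_level": roi_eval.to_dict(),
            "patient_level": patient_eval.to_dict(),
        }

        stage = "raterstats"
        rater_table = bundle.rater_table
        if rater_table is None:
            long = fio.read_rater_csv(sim_dir / "answers.csv")
            truth = fio.read_truth_csv(sim_dir / "truth.csv")
            rater_table = RaterTable.from_long(long, truth)
        report["stages"]["raterstats"] = build_report(rater_table)

        stage = "report"
        report_path = workdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
        report["report_path"] = str(report_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
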