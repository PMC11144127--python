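"""Synthetic ROI milestone datasets for classifier training and testing.

Builds multi-patient feature tables by simulating per-ROI kinetic curves
(no video rendering) and running them through the milestone extractor, so
classifier experiments stay fast while exercising the real feature path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curve_features import (
    FeatureConfig,
    extract_milestones,
    preprocess_curve,
    relative_features,
)
from .roi_tracking import TimeIntensityCurve
from .synthetic_data import KineticParams, simulate_kinetic_curve

__all__ = ["make_milestone_dataset", "DEFAULT_CLASS_KINETICS"]

DEFAULT_CLASS_KINETICS = {
    "normal": KineticParams(t0=8.0, alpha=4.0, beta=3.0, amplitude=600.0, baseline=120.0),
    "benign": KineticParams(t0=10.0, alpha=5.0, beta=3.6, amplitude=700.0, baseline=120.0),
    "malignant": KineticParams(t0=6.0, alpha=3.0, beta=2.2, amplitude=800.0, baseline=120.0),
}


def _jitter_params(
    base: KineticParams, rng: np.random.Generator, spread: float, noise_sd: float
) -> KineticParams:
    return KineticParams(
        # floor keeps the detected onset clear of the 2 s baseline window
        # even under heavy noise and smoothing blur
        t0=max(base.t0 + rng.normal(0.0, spread), 4.0),
        alpha=base.alpha * float(np.exp(rng.normal(0.0, spread / 10))),
        beta=base.beta * float(np.exp(rng.normal(0.0, spread / 10))),
        amplitude=base.amplitude * float(np.exp(rng.normal(0.0, spread / 5))),
        baseline=base.baseline,
        noise_sd=noise_sd,
    )


def make_milestone_dataset(
    n_patients: int = 16,
    rois_per_patient: int = 4,
    class_kinetics: dict[str, KineticParams] | None = None,
    noise_sd: float = 5.0,
    param_spread: float = 0.5,
    duration: float = 60.0,
    fps: float = 30.0,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Simulate a balanced per-patient lesion ROI feature table.

    Even-indexed patients carry benign lesions, odd-indexed malignant ones
    (labelled "cancer"); every patient also gets a normal-tissue reference
    ROI whose milestones supply the delta features. Kinetic parameters are
    jittered per ROI (``param_spread`` controls t0 shift in seconds and
    multiplicative spread of the shape parameters); curves carry Gaussian
    sensor noise ``noise_sd``.

    Returns a features frame with the standard feature-CSV columns.
    """
    kinetics = class_kinetics or DEFAULT_CLASS_KINETICS
    rng = np.random.default_rng(seed)
    times = np.arange(int(round(duration * fps))) / fps
    rows = []
    for p in range(n_patients):
        patient_id = f"patient{p + 1:03d}"
        lesion_class = "benign" if p % 2 == 0 else "malignant"
        label = "benign" if lesion_class == "benign" else "cancer"

        ref_params = _jitter_params(kinetics["normal"], rng, param_spread, noise_sd)
        ref_curve = TimeIntensityCurve(
            roi_id=f"{patient_id}_normal",
            label="normal",
            times=times,
            intensities=simulate_kinetic_curve(ref_params, times, rng=rng),
            fps=fps,
            patient_id=patient_id,
        )
        ref_feats = extract_milestones(
            preprocess_curve(ref_curve, feature_config), feature_config
        )

        for r in range(rois_per_patient):
            params = _jitter_params(kinetics[lesion_class], rng, param_spread, noise_sd)
            curve = TimeIntensityCurve(
                roi_id=f"{patient_id}_roi{r + 1}",
                label=label,
                times=times,
                intensities=simulate_kinetic_curve(params, times, rng=rng),
                fps=fps,
                patient_id=patient_id,
            )
            feats = relative_features(
                extract_milestones(preprocess_curve(curve, feature_config), feature_config),
                ref_feats,
            )
            rows.append(
                {
                    "roi_id": feats.roi_id,
                    "label": feats.label,
                    "patient_id": patient_id,
                    **feats.milestone_dict(),
                    **feats.delta_dict(),
                }
            )
    return pd.DataFrame(rows)
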