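"""Normalization and milestone extraction for time-fluorescence curves.

The five discriminant milestones are time to peak, upslope, downslope,
skew and centre of mass. Definitions (frozen in :class:`FeatureConfig`):

* ``time_to_peak``: argmax time of the smoothed normalized curve.
* ``upslope``: least-squares slope of the normalized curve between its
  10% and 90% crossing times on the rising limb (1/s).
* ``downslope``: least-squares slope from the peak to ``peak + 60 s``
  (or the end of the recording), expected <= 0 (1/s).
* ``center_of_mass``: intensity-weighted mean time over the post-onset
  window, with normalized intensities clipped at 0 (s).
* ``skew``: intensity-weighted third standardized moment of time about
  the centre of mass (unitless).

All milestones operate on the baseline-subtracted, peak-scaled curve, so
they are invariant to raw amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .roi_tracking import TimeIntensityCurve

__all__ = [
    "FeatureConfig",
    "NormalizedCurve",
    "CurveFeatures",
    "preprocess_curve",
    "extract_milestones",
    "relative_features",
    "MILESTONE_NAMES",
]

MILESTONE_NAMES = ("t_peak", "upslope", "downslope", "skew", "com")


class NoPerfusionEventError(ValueError):
    """The curve shows no rise above baseline: nothing to analyse."""


@dataclass(frozen=True)
class FeatureConfig:
    smoothing_window: int = 15       # frames; 0.5 s at 30 fps
    baseline_seconds: float = 2.0    # head window averaged for the baseline
    onset_threshold: float = 0.05    # normalized level defining onset
    onset_sustain_seconds: float = 0.5
    rise_low: float = 0.1            # upslope fit limits on the rising limb
    rise_high: float = 0.9
    washout_seconds: float = 60.0    # downslope fit horizon past the peak

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd frame count")
        if not 0 < self.rise_low < self.rise_high <= 1:
            raise ValueError("need 0 < rise_low < rise_high <= 1")
        if self.baseline_seconds <= 0 or self.washout_seconds <= 0:
            raise ValueError("baseline and washout windows must be positive")


@dataclass
class NormalizedCurve:
    """Baseline-subtracted, peak-scaled, smoothed curve."""

    roi_id: str
    label: str
    times: np.ndarray
    normalized: np.ndarray
    baseline: float
    peak: float
    onset_index: int
    fps: float
    smoothing_window: int
    patient_id: str = ""


@dataclass(frozen=True)
class CurveFeatures:
    """Milestones for one ROI, optionally with deltas vs a reference ROI."""

    roi_id: str
    label: str
    t_peak: float
    upslope: float
    downslope: float
    skew: float
    com: float
    patient_id: str = ""
    d_t_peak: float | None = None
    d_upslope: float | None = None
    d_downslope: float | None = None
    d_skew: float | None = None
    d_com: float | None = None

    def milestone_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MILESTONE_NAMES}

    def delta_dict(self) -> dict[str, float | None]:
        return {f"d_{name}": getattr(self, f"d_{name}") for name in MILESTONE_NAMES}


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def preprocess_curve(
    curve: TimeIntensityCurve, config: FeatureConfig | None = None
) -> NormalizedCurve:
    """Smooth, baseline-subtract and peak-scale a raw intensity curve.

    Baseline is the mean of the first ``baseline_seconds`` of the smoothed
    curve; onset is the first time the normalized curve stays above
    ``onset_threshold`` for ``onset_sustain_seconds``. Raises
    :class:`NoPerfusionEventError` for flat or decreasing curves, and
    ``ValueError`` if the detected onset falls inside the baseline window.
    """
    config = config or FeatureConfig()
    n_baseline = int(round(config.baseline_seconds * curve.fps))
    if curve.times.size < n_baseline + 10:
        raise ValueError(
            f"curve too short: {curve.times.size} samples, need >= {n_baseline + 10}"
        )

    smoothed = _moving_average(curve.intensities, config.smoothing_window)
    baseline = float(smoothed[:n_baseline].mean())
    peak = float(smoothed.max())
    if peak <= baseline:
        raise NoPerfusionEventError(
            f"ROI {curve.roi_id}: no perfusion event (peak {peak:.3g} <= baseline {baseline:.3g})"
        )
    normalized = (smoothed - baseline) / (peak - baseline)

    sustain = max(int(round(config.onset_sustain_seconds * curve.fps)), 1)
    above = normalized > config.onset_threshold
    onset_index = -1
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= sustain:
            onset_index = i - sustain + 1
            break
    if onset_index < 0:
        raise NoPerfusionEventError(
            f"ROI {curve.roi_id}: no perfusion event (no sustained rise above "
            f"{config.onset_threshold:g})"
        )
    if onset_index < n_baseline:
        raise ValueError(
            f"ROI {curve.roi_id}: onset at sample {onset_index} falls inside the "
            f"{n_baseline}-sample baseline window; shorten baseline_seconds"
        )

    return NormalizedCurve(
        roi_id=curve.roi_id,
        label=curve.label,
        times=curve.times.copy(),
        normalized=normalized,
        baseline=baseline,
        peak=peak,
        onset_index=onset_index,
        fps=curve.fps,
        smoothing_window=config.smoothing_window,
        patient_id=curve.patient_id,
    )


def _lstsq_slope(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 2:
        raise ValueError("need >= 2 points for a slope fit")
    t = t - t.mean()
    return float((t @ (y - y.mean())) / (t @ t))


def extract_milestones(
    nc: NormalizedCurve, config: FeatureConfig | None = None
) -> CurveFeatures:
    """Compute the five milestones from a normalized curve.

    Raises if the peak sits on the first or last sample (no interior
    maximum) or if the post-onset curve carries no positive mass.
    """
    config = config or FeatureConfig()
    y = nc.normalized
    t = nc.times
    peak_idx = int(np.argmax(y))
    if peak_idx in (0, y.size - 1):
        raise ValueError(
            f"ROI {nc.roi_id}: peak at sample {peak_idx} is not an interior maximum"
        )
    t_peak = float(t[peak_idx])

    # upslope: fit between the 10% and 90% crossings on the rising limb
    rise = y[: peak_idx + 1]
    i10 = int(np.argmax(rise >= config.rise_low))
    i90 = int(np.argmax(rise >= config.rise_high))
    if i90 <= i10:
        i10, i90 = max(peak_idx - 1, 0), peak_idx
    upslope = _lstsq_slope(t[i10 : i90 + 1], y[i10 : i90 + 1])

    # downslope: fit from the peak over the washout horizon
    end = min(y.size, peak_idx + int(round(config.washout_seconds * nc.fps)) + 1)
    downslope = _lstsq_slope(t[peak_idx:end], y[peak_idx:end])

    # weighted moments over the post-baseline window, negative noise clipped;
    # pre-onset samples carry ~zero clipped weight, so no hard truncation of
    # the rising limb biases the moments
    start = min(int(round(config.baseline_seconds * nc.fps)), nc.onset_index)
    w = np.clip(y[start:], 0.0, None)
    tw = t[start:]
    mass = float(w.sum())
    if mass <= 0:
        raise ValueError(f"ROI {nc.roi_id}: zero post-onset intensity mass")
    com = float((tw * w).sum() / mass)
    var = float(((tw - com) ** 2 * w).sum() / mass)
    if var <= 0:
        raise ValueError(f"ROI {nc.roi_id}: zero temporal variance")
    skew = float(((tw - com) ** 3 * w).sum() / mass / var**1.5)

    return CurveFeatures(
        roi_id=nc.roi_id,
        label=nc.label,
        t_peak=t_peak,
        upslope=upslope,
        downslope=downslope,
        skew=skew,
        com=com,
        patient_id=nc.patient_id,
    )


def relative_features(lesion: CurveFeatures, reference: CurveFeatures) -> CurveFeatures:
    """Attach lesion-minus-reference deltas for all five milestones.

    Both feature sets must come from the same recording (patient id);
    deltas are antisymmetric under argument swap.
    """
    if lesion.patient_id != reference.patient_id:
        raise ValueError(
            f"recording mismatch: lesion from {lesion.patient_id!r}, "
            f"reference from {reference.patient_id!r}"
        )
    deltas = {
        f"d_{name}": getattr(lesion, name) - getattr(reference, name)
        for name in MILESTONE_NAMES
    }
    return replace(lesion, **deltas)


def features_from_curves(
    curves,
    reference_label: str = "normal",
    config: FeatureConfig | None = None,
) -> "pd.DataFrame":
    """Milestone feature table for a set of curves from one or more recordings.

    Curves labelled ``reference_label`` supply per-recording reference
    milestones; all other curves get lesion-minus-reference deltas when a
    reference exists for their recording (NaN deltas otherwise).
    """
    import pandas as pd

    features = []
    references: dict[str, CurveFeatures] = {}
    for curve in curves:
        feats = extract_milestones(preprocess_curve(curve, config), config)
        if curve.label == reference_label:
            if curve.patient_id in references:
                raise ValueError(
                    f"multiple {reference_label!r} reference ROIs for recording "
                    f"{curve.patient_id!r}"
                )
            references[curve.patient_id] = feats
        features.append(feats)

    rows = []
    for feats in features:
        ref = references.get(feats.patient_id)
        if ref is not None and feats.label != reference_label:
            feats = relative_features(feats, ref)
        rows.append(
            {
                "roi_id": feats.roi_id,
                "label": feats.label,
                "patient_id": feats.patient_id,
                **feats.milestone_dict(),
                **{k: (np.nan if v is None else v) for k, v in feats.delta_dict().items()},
            }
        )
    return pd.DataFrame(rows)
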