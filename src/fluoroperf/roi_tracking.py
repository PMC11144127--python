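"""ROI tracking on the white-light channel and NIR curve extraction.

A frame-0 template for each ROI is matched by normalized cross-correlation
within a bounded search window around the previous position; the estimated
per-frame translation is then used to average NIR intensity over the
displaced ROI footprint, yielding a time-intensity curve at the stack's
frame rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .io import FrameStack

__all__ = [
    "ROISpec",
    "ROITrack",
    "TimeIntensityCurve",
    "TrackerConfig",
    "track_roi",
    "extract_curve",
    "curves_to_frame",
    "frame_to_curves",
]

MIN_ROI_AREA = 25


@dataclass(frozen=True)
class ROISpec:
    """A user/seed-specified region of interest in frame-0 coordinates."""

    id: str
    label: str = "unknown"
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # (r0, c0, r1, c1), half-open
    polygon: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"ROI {self.id}: degenerate bbox {self.bbox}")
        if (r1 - r0) * (c1 - c0) < MIN_ROI_AREA:
            raise ValueError(
                f"ROI {self.id}: area {(r1 - r0) * (c1 - c0)} px below minimum {MIN_ROI_AREA}"
            )
        if r0 < 0 or c0 < 0:
            raise ValueError(f"ROI {self.id}: bbox {self.bbox} has negative origin")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.bbox[2] - self.bbox[0], self.bbox[3] - self.bbox[1])

    def check_in_frame(self, frame_shape: tuple[int, int]) -> None:
        r0, c0, r1, c1 = self.bbox
        if r1 > frame_shape[0] or c1 > frame_shape[1]:
            raise ValueError(
                f"ROI {self.id}: bbox {self.bbox} outside frame {frame_shape}"
            )


@dataclass
class ROITrack:
    """Per-frame displacement of one ROI relative to frame 0."""

    roi_id: str
    displacements: np.ndarray  # (n_frames, 2) float (d_row, d_col)
    valid: np.ndarray          # (n_frames,) bool
    quality: np.ndarray        # (n_frames,) normalized correlation in [-1, 1]

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.quality = np.asarray(self.quality, dtype=float)
        n = self.displacements.shape[0]
        if self.displacements.shape != (n, 2):
            raise ValueError("displacements must be (n_frames, 2)")
        if self.valid.shape != (n,) or self.quality.shape != (n,):
            raise ValueError("valid/quality must have one entry per frame")
        if n and not np.allclose(self.displacements[0], 0.0):
            raise ValueError("frame-0 displacement must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.displacements.shape[0]


@dataclass
class TimeIntensityCurve:
    """Mean NIR intensity over a tracked ROI vs time."""

    roi_id: str
    label: str
    times: np.ndarray
    intensities: np.ndarray
    fps: float
    valid: np.ndarray | None = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must align")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class TrackerConfig:
    search_radius: int = 15       # px each side of the previous position
    min_correlation: float = 0.5  # below this the frame is flagged invalid
    subpixel: bool = False        # 1-D parabolic refinement per axis
    template_update: float | None = None  # exponential update weight, None = frame-0 template


def _parabolic_offset(c_minus: float, c0: float, c_plus: float) -> float:
    denom = c_minus - 2.0 * c0 + c_plus
    if denom >= 0 or abs(denom) < 1e-12:
        return 0.0
    off = 0.5 * (c_minus - c_plus) / denom
    return float(np.clip(off, -0.5, 0.5))


def track_roi(
    white: FrameStack, roi: ROISpec, config: TrackerConfig | None = None
) -> ROITrack:
    """Estimate per-frame ROI translation on the white-light channel.

    The frame-0 crop is the template. Each subsequent frame is searched in
    a window of ``search_radius`` px around the last valid position; the
    normalized-correlation peak gives the displacement and its height the
    quality score. Frames whose peak correlation falls below
    ``min_correlation`` (e.g. dropout frames) are flagged invalid and do
    not move the search window.
    """
    config = config or TrackerConfig()
    roi.check_in_frame(white.frame_shape)
    n = white.n_frames
    rows, cols = white.frame_shape
    r0, c0, r1, c1 = roi.bbox

    template = np.asarray(white.data[0], dtype=float)[r0:r1, c0:c1].copy()
    if float(template.std()) == 0.0:
        raise ValueError(f"ROI {roi.id}: frame-0 template has zero variance, cannot track")

    disp = np.zeros((n, 2), dtype=float)
    valid = np.ones(n, dtype=bool)
    quality = np.ones(n, dtype=float)

    prev = np.zeros(2, dtype=float)
    rad = config.search_radius
    for t in range(1, n):
        frame = np.asarray(white.data[t], dtype=float)
        pr, pc = int(round(prev[0])), int(round(prev[1]))
        sr0 = max(r0 + pr - rad, 0)
        sc0 = max(c0 + pc - rad, 0)
        sr1 = min(r1 + pr + rad, rows)
        sc1 = min(c1 + pc + rad, cols)
        search = frame[sr0:sr1, sc0:sc1]
        if search.shape[0] < template.shape[0] or search.shape[1] < template.shape[1]:
            valid[t] = False
            quality[t] = -1.0
            disp[t] = prev
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = match_template(search, template, pad_input=False)
        corr = np.nan_to_num(corr, nan=-1.0, posinf=-1.0, neginf=-1.0)
        peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
        score = float(corr[peak])
        dr = float(sr0 + peak[0] - r0)
        dc = float(sc0 + peak[1] - c0)
        if config.subpixel:
            pr_, pc_ = peak
            if 0 < pr_ < corr.shape[0] - 1:
                dr += _parabolic_offset(corr[pr_ - 1, pc_], corr[pr_, pc_], corr[pr_ + 1, pc_])
            if 0 < pc_ < corr.shape[1] - 1:
                dc += _parabolic_offset(corr[pr_, pc_ - 1], corr[pr_, pc_], corr[pr_, pc_ + 1])
        quality[t] = score
        if score < config.min_correlation:
            valid[t] = False
            disp[t] = prev  # hold position; curve extraction interpolates
            continue
        disp[t] = (dr, dc)
        prev = disp[t]
        if config.template_update is not None:
            w = config.template_update
            ri, ci = int(round(dr)), int(round(dc))
            patch = frame[r0 + ri:r1 + ri, c0 + ci:c1 + ci]
            if patch.shape == template.shape:
                template = (1 - w) * template + w * patch

    return ROITrack(roi_id=roi.id, displacements=disp, valid=valid, quality=quality)


def extract_curve(
    nir: FrameStack,
    track: ROITrack,
    roi: ROISpec,
    invalid_policy: str = "interpolate",
) -> TimeIntensityCurve:
    """Mean NIR intensity over the displaced ROI footprint per frame.

    Invalid frames are filled by linear interpolation between the nearest
    valid neighbours (endpoints hold the nearest valid value) under the
    default policy, or dropped to NaN with ``invalid_policy="drop"``.
    """
    if invalid_policy not in ("interpolate", "drop"):
        raise ValueError(f"unknown invalid_policy {invalid_policy!r}")
    if track.n_frames != nir.n_frames:
        raise ValueError(
            f"track has {track.n_frames} frames but NIR stack has {nir.n_frames}"
        )
    if not track.valid.any():
        raise ValueError(f"ROI {roi.id}: all frames invalid, no curve can be extracted")
    roi.check_in_frame(nir.frame_shape)

    rows, cols = nir.frame_shape
    r0, c0, r1, c1 = roi.bbox
    n = nir.n_frames
    values = np.full(n, np.nan)
    for t in range(n):
        if not track.valid[t]:
            continue
        dr, dc = np.round(track.displacements[t]).astype(int)
        rr0, cc0, rr1, cc1 = r0 + dr, c0 + dc, r1 + dr, c1 + dc
        if rr0 < 0 or cc0 < 0 or rr1 > rows or cc1 > cols:
            raise ValueError(
                f"ROI {roi.id}: displaced footprint outside frame at frame {t}"
            )
        values[t] = float(np.asarray(nir.data[t], dtype=float)[rr0:rr1, cc0:cc1].mean())

    if invalid_policy == "interpolate":
        idx = np.arange(n)
        good = ~np.isnan(values)
        values = np.interp(idx, idx[good], values[good])

    return TimeIntensityCurve(
        roi_id=roi.id,
        label=roi.label,
        times=np.arange(n) / nir.fps,
        intensities=np.maximum(values, 0.0) if invalid_policy == "interpolate" else values,
        fps=nir.fps,
        valid=track.valid.copy(),
    )


def curves_to_frame(curves: list[TimeIntensityCurve]) -> "pd.DataFrame":
    """Long-format curves table: ``roi_id, label, frame, time_s, intensity, valid``."""
    import pandas as pd

    frames = []
    for c in curves:
        n = c.times.size
        frames.append(
            pd.DataFrame(
                {
                    "roi_id": c.roi_id,
                    "label": c.label,
                    "frame": np.arange(n),
                    "time_s": c.times,
                    "intensity": c.intensities,
                    "valid": c.valid if c.valid is not None else np.ones(n, dtype=bool),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_curves(df, patient_id: str = "") -> list[TimeIntensityCurve]:
    """Inverse of :func:`curves_to_frame`; fps inferred from the time grid."""
    curves = []
    for roi_id, grp in df.groupby("roi_id", sort=False):
        grp = grp.sort_values("frame")
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size < 2:
            raise ValueError(f"ROI {roi_id}: need at least 2 samples")
        fps = 1.0 / float(np.median(np.diff(times)))
        curves.append(
            TimeIntensityCurve(
                roi_id=str(roi_id),
                label=str(grp["label"].iloc[0]),
                times=times,
                intensities=grp["intensity"].to_numpy(dtype=float),
                fps=fps,
                valid=grp["valid"].to_numpy(dtype=bool),
                patient_id=patient_id,
            )
        )
    return curves
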