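"""Readers and writers for the on-disk formats used across the pipeline.

Frame stacks are multi-page 16-bit grayscale TIFF (one file per channel,
suffixes ``_wl.tif`` / ``_nir.tif``), label masks are 8-bit TIFF, ROI seeds
are JSON, tabular artifacts are CSV, configs/manifests are YAML.

All writers round-trip bit-exactly through their readers for integer
payloads and to 1e-9 for floats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FrameStack",
    "SchemaError",
    "read_frame_stack",
    "write_frame_stack",
    "read_label_mask",
    "write_label_mask",
    "read_roi_json",
    "write_roi_json",
    "read_csv_checked",
    "write_curves_csv",
    "read_curves_csv",
    "write_features_csv",
    "read_features_csv",
    "write_rater_csv",
    "read_rater_csv",
    "write_truth_csv",
    "read_truth_csv",
    "read_yaml",
    "write_yaml",
]


class SchemaError(ValueError):
    """A tabular file does not match its expected column schema."""


@dataclass
class FrameStack:
    """One channel of a recording: ordered 2-D frames plus frame rate.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, rows, cols)``.
    fps
        Frames per second; frame ``i`` is at time ``i / fps`` seconds.
    """

    data: np.ndarray
    fps: float = 30.0
    channel: str = "nir"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"frame stack must be 3-D (frames, rows, cols), got shape {self.data.shape}"
            )
        if self.data.shape[0] == 0:
            raise ValueError("frame stack is empty")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.fps


def write_frame_stack(path: str | Path, stack: FrameStack) -> Path:
    """Write a stack as multi-page uint16 TIFF; float data is rounded and clipped."""
    path = Path(path)
    data = stack.data
    if not np.issubdtype(data.dtype, np.integer):
        data = np.round(data)
    data = np.clip(data, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"fps": stack.fps, "channel": stack.channel})
    return path


def read_frame_stack(path: str | Path, fps: float | None = None, channel: str | None = None) -> FrameStack:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, OSError) as exc:
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.size == 0 or data.ndim < 2:
        raise IOError(f"truncated or corrupt TIFF stack {path}")
    if data.ndim == 2:
        data = data[None]
    fps = fps if fps is not None else float(meta.get("fps", 30.0))
    channel = channel if channel is not None else str(meta.get("channel", "nir"))
    return FrameStack(data=data, fps=fps, channel=channel)


def write_label_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a label image (0 background, 1..k regions) as 8-bit TIFF."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("label mask values must fit uint8")
    tifffile.imwrite(Path(path), mask.astype(np.uint8))
    return Path(path)


def read_label_mask(path: str | Path) -> np.ndarray:
    try:
        return tifffile.imread(Path(path))
    except (tifffile.TiffFileError, OSError) as exc:
        raise IOError(f"cannot read mask TIFF {path}: {exc}") from exc


def write_roi_json(path: str | Path, rois: list[dict]) -> Path:
    """ROI seeds: list of ``{id, label, bbox: [r0, c0, r1, c1]}`` (half-open)."""
    for roi in rois:
        missing = {"id", "label", "bbox"} - roi.keys()
        if missing:
            raise SchemaError(f"ROI record missing keys {sorted(missing)}: {roi}")
    Path(path).write_text(json.dumps(rois, indent=2) + "\n")
    return Path(path)


def read_roi_json(path: str | Path) -> list[dict]:
    path = Path(path)
    try:
        rois = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise IOError(f"malformed ROI JSON {path}: {exc}") from exc
    if not isinstance(rois, list):
        raise SchemaError(f"{path}: expected a JSON list of ROI records")
    for i, roi in enumerate(rois):
        missing = {"id", "label", "bbox"} - set(roi)
        if missing:
            raise SchemaError(f"{path}: ROI record {i} missing keys {sorted(missing)}")
    return rois


def read_csv_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a CSV and fail with a named-column error if the header is wrong."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise IOError(f"cannot read CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


CURVE_COLUMNS = ["roi_id", "label", "frame", "time_s", "intensity", "valid"]
FEATURE_COLUMNS = [
    "roi_id", "label", "patient_id",
    "t_peak", "upslope", "downslope", "skew", "com",
    "d_t_peak", "d_upslope", "d_downslope", "d_skew", "d_com",
]
RATER_COLUMNS = ["rater_id", "grade", "polyp_id", "answer", "confidence"]
TRUTH_COLUMNS = ["polyp_id", "pathology", "size_mm"]


def write_curves_csv(path: str | Path, df: pd.DataFrame) -> Path:
    _check_columns(df, CURVE_COLUMNS, "curves")
    df.to_csv(Path(path), index=False)
    return Path(path)


def read_curves_csv(path: str | Path) -> pd.DataFrame:
    return read_csv_checked(path, CURVE_COLUMNS)


def write_features_csv(path: str | Path, df: pd.DataFrame) -> Path:
    _check_columns(df, FEATURE_COLUMNS[:8], "features")
    df.to_csv(Path(path), index=False)
    return Path(path)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return read_csv_checked(path, FEATURE_COLUMNS[:8])


def write_rater_csv(path: str | Path, df: pd.DataFrame) -> Path:
    _check_columns(df, RATER_COLUMNS, "rater table")
    df.to_csv(Path(path), index=False)
    return Path(path)


def read_rater_csv(path: str | Path) -> pd.DataFrame:
    return read_csv_checked(path, RATER_COLUMNS)


def write_truth_csv(path: str | Path, df: pd.DataFrame) -> Path:
    _check_columns(df, TRUTH_COLUMNS[:2], "truth table")
    df.to_csv(Path(path), index=False)
    return Path(path)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    return read_csv_checked(path, TRUTH_COLUMNS[:2])


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} frame missing required column(s) {missing}")


def write_yaml(path: str | Path, obj: dict) -> Path:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
    return Path(path)


def read_yaml(path: str | Path) -> dict:
    path = Path(path)
    try:
        obj = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise IOError(f"malformed YAML {path}: {exc}") from exc
    if not isinstance(obj, dict):
        raise SchemaError(f"{path}: expected a YAML mapping")
    return obj
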