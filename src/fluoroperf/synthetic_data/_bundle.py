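"""Self-describing on-disk fixture bundles for the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .. import io as fio
from ..rater_stats import RaterTable
from ._kinetics import KineticParams
from ._raters import RaterModelParams, simulate_rater_table
from ._video import JitterSpec, RegionSpec, RenderedScene, SceneSpec, render_video_pair

__all__ = ["FixtureBundle", "write_fixture_bundle", "read_fixture_bundle"]

MANIFEST_NAME = "manifest.yaml"


@dataclass
class FixtureBundle:
    """In-memory view of a written (or read-back) fixture bundle."""

    path: Path
    scene: SceneSpec
    rendered: RenderedScene
    rater_params: RaterModelParams | None
    rater_table: RaterTable | None


def _scene_to_dict(scene: SceneSpec) -> dict:
    return {
        "frame_shape": list(scene.frame_shape),
        "duration": scene.duration,
        "fps": scene.fps,
        "regions": [
            {"id": r.id, "label": r.label, "bbox": list(r.bbox)} for r in scene.regions
        ],
        "class_kinetics": {k: v.to_dict() for k, v in scene.class_kinetics.items()},
        "jitter": {
            "kind": scene.jitter.kind,
            "amplitude": scene.jitter.amplitude,
            "period_frames": scene.jitter.period_frames,
        },
        "noise_sd": scene.noise_sd,
        "wl_noise_sd": scene.wl_noise_sd,
        "background_intensity": scene.background_intensity,
        "texture_seed": scene.texture_seed,
        "seed": scene.seed,
        "icg_dose_mg_per_kg": scene.icg_dose_mg_per_kg,
    }


def _scene_from_dict(d: dict) -> SceneSpec:
    return SceneSpec(
        frame_shape=tuple(d["frame_shape"]),
        duration=d["duration"],
        fps=d["fps"],
        regions=[RegionSpec(r["id"], r["label"], tuple(r["bbox"])) for r in d["regions"]],
        class_kinetics={k: KineticParams(**v) for k, v in d["class_kinetics"].items()},
        jitter=JitterSpec(**d["jitter"]),
        noise_sd=d["noise_sd"],
        wl_noise_sd=d["wl_noise_sd"],
        background_intensity=d["background_intensity"],
        texture_seed=d["texture_seed"],
        seed=d["seed"],
        icg_dose_mg_per_kg=d["icg_dose_mg_per_kg"],
    )


def write_fixture_bundle(
    path: str | Path,
    scene: SceneSpec,
    rater_params: RaterModelParams | None = None,
    name: str = "scene",
) -> FixtureBundle:
    """Render a scene (and optionally a rater table) and write everything.

    Layout under ``path``: ``<name>_wl.tif`` / ``<name>_nir.tif`` (uint16
    multi-page), ``<name>_masks.tif`` (uint8 labels), ``rois.json``,
    ``displacements.csv``, ``answers.csv`` + ``truth.csv`` (if rater params
    given), and ``manifest.yaml`` holding every parameter and seed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rendered = render_video_pair(scene)
    fio.write_frame_stack(path / f"{name}_wl.tif", rendered.white)
    fio.write_frame_stack(path / f"{name}_nir.tif", rendered.nir)
    fio.write_label_mask(path / f"{name}_masks.tif", rendered.masks)
    fio.write_roi_json(
        path / "rois.json",
        [{"id": r.id, "label": r.label, "bbox": list(r.bbox)} for r in scene.regions],
    )
    pd.DataFrame(
        {
            "frame": np.arange(scene.n_frames),
            "d_row": rendered.displacements[:, 0],
            "d_col": rendered.displacements[:, 1],
        }
    ).to_csv(path / "displacements.csv", index=False)

    manifest = {
        "name": name,
        "scene": _scene_to_dict(scene),
        "n_frames": scene.n_frames,
        "files": {
            "white": f"{name}_wl.tif",
            "nir": f"{name}_nir.tif",
            "masks": f"{name}_masks.tif",
            "rois": "rois.json",
            "displacements": "displacements.csv",
        },
    }

    rater_table = None
    if rater_params is not None:
        rater_table = simulate_rater_table(rater_params)
        fio.write_rater_csv(path / "answers.csv", rater_table.to_long())
        truth = pd.DataFrame(
            {
                "polyp_id": rater_table.truth.index,
                "pathology": rater_table.truth.to_numpy(),
                "size_mm": np.nan,
            }
        )
        fio.write_truth_csv(path / "truth.csv", truth)
        manifest["rater_model"] = rater_params.to_dict()
        manifest["files"]["answers"] = "answers.csv"
        manifest["files"]["truth"] = "truth.csv"

    fio.write_yaml(path / MANIFEST_NAME, manifest)
    return FixtureBundle(
        path=path, scene=scene, rendered=rendered,
        rater_params=rater_params, rater_table=rater_table,
    )


def read_fixture_bundle(path: str | Path) -> FixtureBundle:
    """Read a bundle back; re-renders nothing, loads stacks from disk."""
    path = Path(path)
    manifest = fio.read_yaml(path / MANIFEST_NAME)
    scene = _scene_from_dict(manifest["scene"])
    files = manifest["files"]

    white = fio.read_frame_stack(path / files["white"])
    nir = fio.read_frame_stack(path / files["nir"])
    masks = fio.read_label_mask(path / files["masks"])
    disp_df = pd.read_csv(path / files["displacements"])
    disp = disp_df[["d_row", "d_col"]].to_numpy()

    rendered = RenderedScene(
        white=white, nir=nir, masks=masks, displacements=disp,
        region_curves={}, scene=scene,
    )
    rater_params = None
    rater_table = None
    if "rater_model" in manifest:
        d = dict(manifest["rater_model"])
        d["confidence_thresholds"] = tuple(d["confidence_thresholds"])
        rater_params = RaterModelParams(**d)
        long = fio.read_rater_csv(path / files["answers"])
        truth = fio.read_truth_csv(path / files["truth"])
        rater_table = RaterTable.from_long(long, truth)
    return FixtureBundle(
        path=path, scene=scene, rendered=rendered,
        rater_params=rater_params, rater_table=rater_table,
    )
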