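"""Synthetic dual-channel (white-light + NIR) endoscopy scene renderer.

The scene is a static textured canvas with rectangular tissue regions.
Camera jitter is a global integer 2-D translation per frame; the returned
displacement series is the exact translation applied, so downstream
trackers can be scored against ground truth. The white channel carries
the tracking texture; the NIR channel carries each region's kinetic curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..io import FrameStack
from ._kinetics import KineticParams, simulate_kinetic_curve

__all__ = ["RegionSpec", "JitterSpec", "SceneSpec", "RenderedScene", "render_video_pair"]

TISSUE_CLASSES = ("normal", "benign", "malignant")


@dataclass(frozen=True)
class RegionSpec:
    """A labelled rectangular tissue region in frame-0 coordinates.

    ``bbox`` is ``(r0, c0, r1, c1)`` half-open, 0-based.
    """

    id: str
    label: str
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if not (r1 > r0 and c1 > c0):
            raise ValueError(f"region {self.id}: degenerate bbox {self.bbox}")
        if self.label not in TISSUE_CLASSES:
            raise ValueError(
                f"region {self.id}: label {self.label!r} not in {TISSUE_CLASSES}"
            )

    @property
    def area(self) -> int:
        r0, c0, r1, c1 = self.bbox
        return (r1 - r0) * (c1 - c0)


@dataclass(frozen=True)
class JitterSpec:
    """Global per-frame camera translation model (integer pixels).

    kind "none": zero displacement; "sinusoid": rounded sinusoid with the
    given amplitude (px) and period (frames), row and column a quarter
    period out of phase; "random_walk": cumulative ±1 steps clipped to
    ±amplitude (seeded from the scene seed).
    """

    kind: str = "none"
    amplitude: float = 0.0
    period_frames: int = 60

    def __post_init__(self) -> None:
        if self.kind not in ("none", "sinusoid", "random_walk"):
            raise ValueError(f"unknown jitter kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("jitter amplitude must be >= 0")
        if self.period_frames <= 0:
            raise ValueError("jitter period must be positive")

    def displacements(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        """Integer ``(n_frames, 2)`` displacement series; frame 0 is (0, 0)."""
        if self.kind == "none" or self.amplitude == 0:
            return np.zeros((n_frames, 2), dtype=int)
        if self.kind == "sinusoid":
            t = np.arange(n_frames)
            phase = 2 * np.pi * t / self.period_frames
            d = np.stack(
                [self.amplitude * np.sin(phase), self.amplitude * np.sin(phase + np.pi / 2)],
                axis=1,
            )
            d = np.round(d).astype(int)
            d -= d[0]  # frame-0 displacement must be exactly zero
            return d
        steps = rng.integers(-1, 2, size=(n_frames, 2))
        steps[0] = 0
        walk = np.cumsum(steps, axis=0)
        amp = int(round(self.amplitude))
        return np.clip(walk, -amp, amp)


def _default_class_kinetics() -> dict[str, KineticParams]:
    # Separability defaults only: malignant = earlier, faster transit with
    # brisk washout; benign = later, broader. Not biological estimates.
    return {
        "normal": KineticParams(t0=8.0, alpha=4.0, beta=3.0, amplitude=600.0,
                                baseline=120.0, noise_sd=0.0),
        "benign": KineticParams(t0=10.0, alpha=5.0, beta=3.6, amplitude=700.0,
                                baseline=120.0, noise_sd=0.0),
        "malignant": KineticParams(t0=6.0, alpha=3.0, beta=2.2, amplitude=800.0,
                                   baseline=120.0, noise_sd=0.0),
    }


@dataclass
class SceneSpec:
    """Full specification of one synthetic dual-channel recording."""

    frame_shape: tuple[int, int] = (96, 128)
    duration: float = 120.0
    fps: float = 30.0
    regions: list[RegionSpec] = field(default_factory=list)
    class_kinetics: dict[str, KineticParams] = field(default_factory=_default_class_kinetics)
    jitter: JitterSpec = field(default_factory=JitterSpec)
    noise_sd: float = 0.0          # NIR additive sensor noise, a.u.
    wl_noise_sd: float = 0.0       # white-channel sensor noise, a.u.
    background_intensity: float = 60.0  # NIR value outside labelled regions
    texture_seed: int = 0
    seed: int = 0
    icg_dose_mg_per_kg: float = 0.25  # metadata only

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        n = self.duration * self.fps
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration*fps must be an integer frame count, got {n}"
            )
        rows, cols = self.frame_shape
        seen: set[str] = set()
        for reg in self.regions:
            if reg.id in seen:
                raise ValueError(f"duplicate region id {reg.id!r}")
            seen.add(reg.id)
            r0, c0, r1, c1 = reg.bbox
            if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
                raise ValueError(f"region {reg.id} bbox {reg.bbox} outside frame {self.frame_shape}")
            if reg.label not in self.class_kinetics:
                raise ValueError(f"region {reg.id}: no kinetics for class {reg.label!r}")
        used = {reg.label for reg in self.regions}
        for label in used:
            if self.class_kinetics[label].t0 > self.duration:
                raise ValueError(
                    f"kinetic t0 for class {label!r} outside the recording window"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class RenderedScene:
    """Render output: both channels plus exact ground truth."""

    white: FrameStack
    nir: FrameStack
    masks: np.ndarray              # (rows, cols) uint8 label image, frame-0 coords
    displacements: np.ndarray      # (n_frames, 2) int, the exact applied jitter
    region_curves: dict[str, np.ndarray]  # noise-free generating curve per region id
    scene: SceneSpec


def _texture(shape: tuple[int, int], seed: int) -> np.ndarray:
    """High-contrast smooth random texture in [2000, 40000] a.u."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(raw, sigma=2.0)
    lo, hi = smooth.min(), smooth.max()
    return 2000.0 + (smooth - lo) / (hi - lo) * 38000.0


def render_video_pair(scene: SceneSpec) -> RenderedScene:
    """Render white + NIR stacks with exact masks and displacement series.

    Frame ``t`` shows scene content translated by ``displacements[t]``:
    content at frame-0 position ``p`` appears at ``p + d_t``. Raises if the
    jitter would push any labelled region outside the frame.
    """
    rows, cols = scene.frame_shape
    n = scene.n_frames
    rng = np.random.default_rng(scene.seed)
    disp = scene.jitter.displacements(n, rng)

    for reg in scene.regions:
        r0, c0, r1, c1 = reg.bbox
        bad = np.flatnonzero(
            (r0 + disp[:, 0] < 0) | (r1 + disp[:, 0] > rows)
            | (c0 + disp[:, 1] < 0) | (c1 + disp[:, 1] > cols)
        )
        if bad.size:
            raise ValueError(
                f"jitter pushes region {reg.id} outside the frame at frame {bad[0]}"
            )

    margin = int(np.abs(disp).max()) if n else 0
    canvas_shape = (rows + 2 * margin, cols + 2 * margin)
    wl_canvas = _texture(canvas_shape, scene.texture_seed)

    masks = np.zeros((rows, cols), dtype=np.uint8)
    region_curves: dict[str, np.ndarray] = {}
    times = scene.times
    for k, reg in enumerate(scene.regions, start=1):
        r0, c0, r1, c1 = reg.bbox
        masks[r0:r1, c0:c1] = k
        params = scene.class_kinetics[reg.label]
        region_curves[reg.id] = simulate_kinetic_curve(
            params, times, rng=None, clip_negative=True
        )

    # NIR canvas value per frame = background outside regions, curve inside
    nir_canvas_base = np.full(canvas_shape, scene.background_intensity, dtype=np.float64)
    region_slices = []
    for reg in scene.regions:
        r0, c0, r1, c1 = reg.bbox
        region_slices.append(
            (reg.id, (slice(r0 + margin, r1 + margin), slice(c0 + margin, c1 + margin)))
        )

    white = np.empty((n, rows, cols), dtype=np.float64)
    nir = np.empty((n, rows, cols), dtype=np.float64)
    for t in range(n):
        dr, dc = disp[t]
        # frame pixel (r, c) samples canvas at (margin + r - dr, margin + c - dc)
        win = (slice(margin - dr, margin - dr + rows), slice(margin - dc, margin - dc + cols))
        white[t] = wl_canvas[win]
        nir_canvas = nir_canvas_base.copy()
        for reg_id, sl in region_slices:
            nir_canvas[sl] = region_curves[reg_id][t]
        nir[t] = nir_canvas[win]

    if scene.wl_noise_sd > 0:
        white += rng.normal(0.0, scene.wl_noise_sd, size=white.shape)
        np.maximum(white, 0.0, out=white)
    if scene.noise_sd > 0:
        nir += rng.normal(0.0, scene.noise_sd, size=nir.shape)
        np.maximum(nir, 0.0, out=nir)

    return RenderedScene(
        white=FrameStack(white, fps=scene.fps, channel="wl"),
        nir=FrameStack(nir, fps=scene.fps, channel="nir"),
        masks=masks,
        displacements=disp,
        region_curves=region_curves,
        scene=scene,
    )
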