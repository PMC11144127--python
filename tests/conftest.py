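import numpy as np
import pytest

from fluoroperf.roi_tracking import ROISpec, TimeIntensityCurve
from fluoroperf.synthetic_data import (
    JitterSpec,
    KineticParams,
    RegionSpec,
    SceneSpec,
    render_video_pair,
)

FPS = 30.0


@pytest.fixture(scope="session")
def long_times():
    """120 s of 30 fps timestamps."""
    return np.arange(3600) / FPS


@pytest.fixture
def gamma_params():
    return KineticParams(t0=5.0, alpha=4.0, beta=3.0, amplitude=500.0, baseline=100.0)


def make_curve(params, times, roi_id="roi1", label="benign", patient="p1", rng=None):
    from fluoroperf.synthetic_data import simulate_kinetic_curve

    return TimeIntensityCurve(
        roi_id=roi_id,
        label=label,
        times=times,
        intensities=simulate_kinetic_curve(params, times, rng=rng),
        fps=FPS,
        patient_id=patient,
    )


FAST_KINETICS = {
    "normal": KineticParams(t0=2.0, alpha=4.0, beta=0.6, amplitude=600.0, baseline=120.0),
    "benign": KineticParams(t0=2.5, alpha=5.0, beta=0.7, amplitude=700.0, baseline=120.0),
    "malignant": KineticParams(t0=1.5, alpha=3.0, beta=0.5, amplitude=800.0, baseline=120.0),
}


@pytest.fixture
def small_scene():
    """Short jittered two-region scene: fast enough for per-test rendering."""
    return SceneSpec(
        frame_shape=(64, 80),
        duration=6.0,
        fps=FPS,
        regions=[
            RegionSpec("lesion", "malignant", (10, 10, 26, 30)),
            RegionSpec("ref", "normal", (38, 50, 54, 70)),
        ],
        class_kinetics=dict(FAST_KINETICS),
        jitter=JitterSpec("sinusoid", 3.0, 45),
        noise_sd=4.0,
        wl_noise_sd=150.0,
        texture_seed=7,
        seed=3,
    )


@pytest.fixture
def rendered_small(small_scene):
    return render_video_pair(small_scene)


@pytest.fixture
def static_scene():
    """No jitter, no noise, one region."""
    return SceneSpec(
        frame_shape=(48, 60),
        duration=4.0,
        fps=FPS,
        regions=[RegionSpec("lesion", "malignant", (8, 8, 24, 28))],
        class_kinetics=dict(FAST_KINETICS),
        jitter=JitterSpec("none"),
        noise_sd=0.0,
        wl_noise_sd=0.0,
        texture_seed=11,
        seed=5,
    )


@pytest.fixture
def lesion_roi():
    return ROISpec(id="lesion", label="malignant", bbox=(10, 10, 26, 30))
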