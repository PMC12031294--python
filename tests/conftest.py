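import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from torsobaro.indices import compute_all
from torsobaro.phantom import PhantomParams, generate_phantom
from torsobaro.preprocess import preprocess_recording

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def clean_params(**kw) -> PhantomParams:
    """Noiseless, artifact-free phantom parameters for recovery tests."""
    base = dict(
        noise_sd=0.0,
        n_fold_artifacts=0,
        breathing_depth=0.0,
        n_motion_spikes=0,
        n_frames=3,
    )
    base.update(kw)
    return PhantomParams(**base)


def analyze_phantom(params: PhantomParams):
    """Phantom -> (ground truth, ROI frame, index set)."""
    rec, gt = generate_phantom(params)
    roi = preprocess_recording(rec)
    return gt, roi, compute_all(roi)


@pytest.fixture(scope="session")
def symmetric_roi():
    _, roi, _ = analyze_phantom(clean_params())
    return roi


@pytest.fixture(scope="session")
def scoliotic_case():
    """A moderately scoliotic phantom with every deformity switched on."""
    params = clean_params(
        bend_angle_deg=20.0,
        shoulder_offset_rows=3.0,
        waist_offset_rows=5.0,
        pelvic_obliquity_deg=3.0,
        hump_amplitude=0.3,
    )
    return analyze_phantom(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
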