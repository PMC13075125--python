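import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitmark as gm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_waveforms():
    return gm.make_gait_waveforms(gm.GaitWaveformConfig())


@pytest.fixture(scope="session")
def anthropometry():
    return gm.Anthropometry()


@pytest.fixture(scope="session")
def noiseless_series_30fps(default_waveforms, anthropometry):
    """5 gait cycles rendered noise-free at the study frame rate."""
    series, truth = gm.render_landmark_series(
        default_waveforms, anthropometry, gm.NoiseModel(seed=7), duration=5.5, fps=30.0
    )
    return series, truth


@pytest.fixture(scope="session")
def knee_angle_series(noiseless_series_30fps):
    series, _ = noiseless_series_30fps
    spec = gm.joint_spec_for("knee", "right", series.side_convention)
    return gm.to_anatomical(gm.joint_angle_series(series, spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
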