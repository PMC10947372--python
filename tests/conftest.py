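import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rbdmotion.synthetic import SceneConfig, default_cohort_spec, sample_cohort_features


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    """Quiet reduced-resolution scene: no noise, no respiration, full tracks."""
    return SceneConfig(
        frame_width=64,
        frame_height=53,
        noise_sigma=0.0,
        respiration_amplitude=0.0,
        track_dropout_prob=0.0,
    )


@pytest.fixture(scope="session")
def cohort_df():
    """One synthetic 53 vs 128 cohort, shared across classifier tests."""
    return sample_cohort_features(default_cohort_spec(), seed=11)
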