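import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prosport import ActivityModel, WindowSpec, generate_short_term
from prosport.calibration import _activity_feature_samples, calibrate_thresholds

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 12.5


@pytest.fixture(scope="session")
def short_term():
    """Default synthetic athlete's labelled calibration session."""
    return generate_short_term(seed=1)


@pytest.fixture(scope="session")
def mccv_result(short_term):
    """Full 50-iteration MCCV on the default synthetic athlete."""
    return ActivityModel(short_term).fit(n_iter=50, seed=1)


@pytest.fixture(scope="session")
def default_thresholds(short_term):
    """Thresholds calibrated on the whole session (no cross-validation)."""
    return calibrate_thresholds(short_term)


@pytest.fixture(scope="session")
def activity_features(short_term):
    """Per-activity window-feature samples of the session."""
    return _activity_feature_samples(short_term, WindowSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
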