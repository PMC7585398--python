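import numpy as np
import pytest

from cprnfl import NormativeModel
from cprnfl.grading import NormativeBands


@pytest.fixture(scope="session")
def flat80():
    """Constant 80 µm profile model, fully deterministic."""
    return NormativeModel(base_level=80.0, peak_params=(), vessel_params=(),
                          between_eye_sd=0.0, within_eye_profile_sd=0.0, g_retest_sd=0.0)


@pytest.fixture(scope="session")
def default_model():
    return NormativeModel()


@pytest.fixture(scope="session")
def quiet_model():
    """Realistic double-hump shape with all noise off."""
    return NormativeModel().zero_noise()


@pytest.fixture(scope="session")
def tight_model():
    """Double-hump shape with small between/within-eye variability, for
    detector ground-truth recovery tests where normative bands must sit
    close under the healthy mean."""
    return NormativeModel(between_eye_sd=0.5, within_eye_profile_sd=0.5, g_retest_sd=0.3)


@pytest.fixture(scope="session")
def tight_bands(tight_model):
    return NormativeBands.from_model(tight_model, n_eyes=800, seed=11)
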