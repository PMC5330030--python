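import warnings

import numpy as np
import pytest

from avpdtrack.phantom import make_phantom_study, make_training_matrix, mean_subject_params
from avpdtrack.prior import CurvePriorModel


@pytest.fixture(scope="session")
def prior_model() -> CurvePriorModel:
    """Curve prior trained on the default 40-subject synthetic training set."""
    return CurvePriorModel.train(make_training_matrix(seed=1))


@pytest.fixture(scope="session")
def mean_quantized_study():
    """Noise-free population-mean phantom with integer-pixel motion."""
    return make_phantom_study(seed=3, noise_sd=0.0, quantize_px=True,
                              subject_params=mean_subject_params())


@pytest.fixture(scope="session")
def mean_study():
    """Noise-free population-mean phantom with continuous motion."""
    return make_phantom_study(seed=3, noise_sd=0.0, subject_params=mean_subject_params())


@pytest.fixture(autouse=True)
def _silence_degenerate_curve_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
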