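import numpy as np
import pytest

from melcurve import MelatoninProfile, ModelParams, evaluate_mlt

SAMPLING = np.arange(0.0, 24.0, 3.0)


@pytest.fixture
def example_params() -> ModelParams:
    """A physiologically plausible parameter set used across tests."""
    return ModelParams(b1=5.0, b2=150.0, b3=3.5, b4=8.0)


@pytest.fixture
def noiseless_profile(example_params) -> MelatoninProfile:
    return MelatoninProfile(
        "noiseless", "test", SAMPLING, evaluate_mlt(example_params, SAMPLING)
    )


def random_params(rng: np.random.Generator) -> ModelParams:
    """Random valid parameters covering the admissible ranges broadly."""
    return ModelParams(
        b1=rng.uniform(0.0, 20.0),
        b2=rng.uniform(20.0, 500.0),
        b3=rng.uniform(0.0, 24.0),
        b4=rng.uniform(1.0, 20.0),
    )
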