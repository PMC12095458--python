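import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulmopet.synthetic import InputFunctionSpec, generate_input_function

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

GRID_1S = np.arange(0.0, 281.0)


@pytest.fixture(scope="session")
def unit_grid() -> np.ndarray:
    """The uniform 1 s analysis grid 0...280 (281 samples)."""
    return GRID_1S.copy()


@pytest.fixture(scope="session")
def clean_input(unit_grid):
    """A noiseless bolus input function on the 1 s grid."""
    return generate_input_function(InputFunctionSpec(noise_sd=0.0), unit_grid, seed=0)
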