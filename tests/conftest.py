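import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def quench_concentrations():
    """Ligand series at molar ratios 0-18x a 1 µM protein, the standard
    titration design."""
    return np.arange(0, 19, 2, dtype=float) * 1e-6
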