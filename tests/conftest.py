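import numpy as np
import pytest

from gatecal.channels import build_standard_channel
from gatecal.synthetic import (
    SINGLE_GATE_TRUTH,
    TWO_GATE_TRUTH,
    single_gate_channel,
    two_gate_channel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def single_gate():
    return single_gate_channel()


@pytest.fixture
def single_gate_truth():
    return dict(SINGLE_GATE_TRUTH)


@pytest.fixture
def two_gate():
    return two_gate_channel()


@pytest.fixture
def two_gate_truth():
    return dict(TWO_GATE_TRUTH)


@pytest.fixture
def plain_gate_channel():
    """Minimal one-gate channel with E = 0 for arithmetic-friendly checks."""
    return build_standard_channel(
        {"name": "toy", "gates": [{"name": "g", "role": "activating"}]}
    )
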