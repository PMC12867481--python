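import numpy as np
import pytest

from splitbelt.paradigm import build_protocol
from splitbelt.synthetic import GroundTruth, generate_participant

# modest adaptation length keeps per-test simulation cheap while leaving a
# clear plateau (tau1 = 322 strides decays to ~0.4 by stride 300)
TEST_ADAPT_STRIDES = 300


@pytest.fixture(scope="session")
def exp1_schedule():
    return build_protocol("exp1", adaptation_strides=TEST_ADAPT_STRIDES)


@pytest.fixture(scope="session")
def exp2_schedule():
    return build_protocol("exp2", adaptation_strides=TEST_ADAPT_STRIDES)


@pytest.fixture(scope="session")
def full_exp1_schedule():
    """Study-length protocol (750 adaptation strides)."""
    return build_protocol("exp1")


@pytest.fixture(scope="session")
def quiet_participant(exp1_schedule):
    """Noise-free memory-type participant with the default planted truth."""
    return generate_participant(GroundTruth(noise_sd=0.0), exp1_schedule)
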