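import numpy as np
import pytest

from rtcea.cohort import PatientRecord
from rtcea.qaly import TimingConfig


@pytest.fixture
def timing():
    return TimingConfig()


@pytest.fixture
def tiny_cohort():
    """Three hand-built patients across two arms."""
    return [
        PatientRecord("p1", "IMRT", "breast", 4000.0, 1000.0, (0.8, 0.6, 0.7)),
        PatientRecord("p2", "IMRT", "breast", 3200.0, 800.0, (0.9, 0.7, 0.8)),
        PatientRecord("p3", "VMAT", "lung", 7200.0, 1800.0, (0.7, 0.5, 0.6)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
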