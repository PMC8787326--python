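import numpy as np
import pytest

from pepnarx.codec import PeptideRecord
from pepnarx.simulate import SyntheticSpec, generate


@pytest.fixture(scope="session")
def fbm_records():
    """Default synthetic panel: 231 di/tripeptides, FBM-linked activities."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def monotone_records():
    """Classifiable regime: ln EC50 a noisy monotone function of ln code."""
    return generate(SyntheticSpec(seed=11, link="monotone_code"))


@pytest.fixture()
def tiny_records():
    return [
        PeptideRecord(id="p1", sequence="AC", ec50=float(np.e)),
        PeptideRecord(id="p2", sequence="A", ec50=1.0),
    ]
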