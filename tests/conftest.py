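import numpy as np
import pytest

from vcgpeaks.kors import kors_transform
from vcgpeaks.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def clean_record():
    """A clean 10-s synthetic 8-lead record with metronome rhythm."""
    return generate(SynthConfig(duration=10.0, rr_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def clean_vcg(clean_record):
    rec, ann = clean_record
    return kors_transform(rec), ann


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
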