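import numpy as np
import pytest

from znrfold.io import SequenceRecord
from znrfold.simulate import ZnRSimSpec, simulate_znr_structure

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, alphabet=AA):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


@pytest.fixture
def random_record(rng):
    return SequenceRecord(id="rnd", residues=random_sequence(rng, 60))


@pytest.fixture(params=["type1A", "type1B", "type2"])
def znr_model(request):
    return simulate_znr_structure(ZnRSimSpec(znr_type=request.param, noise_sd=0.0, seed=7)), request.param
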