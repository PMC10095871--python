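import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from ncrclass.folding import EnergyModel, ReferenceBackend
from ncrclass.seq_io import RnaSequence


@pytest.fixture(scope="session")
def model():
    return EnergyModel()  # e_gc=-3, e_au=-2, e_gu=-1, kT=0.6, min_loop=3


@pytest.fixture(scope="session")
def reference(model):
    return ReferenceBackend(model)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_rna(rng, length):
    return RnaSequence(f"r{length}", "".join(rng.choice(list("ACGU"), length)))


@pytest.fixture
def make_seq():
    return lambda residues, sid="s": RnaSequence(sid, residues)
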