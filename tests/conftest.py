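import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import mitocomp as mc


@pytest.fixture(scope="session")
def default_sim():
    """Default-configuration synthetic genome with planted truth."""
    return mc.generate_mitogenome(mc.SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Six-taxon cohort with per-gene alignments and truth record."""
    return mc.generate_cohort(6, mc.SimConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
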