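import numpy as np
import pytest

from ringscape import (
    ProteinSequence,
    load_brood_tables,
)
from ringscape.simulate import StructureConfig, gen_ring_structure

#: Residue numbers of the nine cysteines in the SPE-42 C-terminal domain
#: (eight zinc ligands plus the excluded upstream cysteine 678).
SPE42_CYSTEINES = (678, 681, 684, 700, 703, 708, 711, 718, 721)
SPE42_LIGANDS = (681, 684, 700, 703, 708, 711, 718, 721)
SPE42_OFFSET = 670


@pytest.fixture(scope="session")
def spe42_like_seq() -> ProteinSequence:
    """60-residue poly-alanine with cysteines at the printed positions."""
    letters = ["A"] * 60
    for p in SPE42_CYSTEINES:
        letters[p - SPE42_OFFSET] = "C"
    return ProteinSequence("spe42-cterm", "".join(letters), SPE42_OFFSET)


@pytest.fixture(scope="session")
def table1():
    return load_brood_tables(1)


@pytest.fixture(scope="session")
def table2():
    return load_brood_tables(2)


@pytest.fixture(scope="session")
def toy_structure():
    """Default two-zinc toy structure with planted contacts (no jitter)."""
    return gen_ring_structure(StructureConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
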