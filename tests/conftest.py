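import importlib.resources as ir

import numpy as np
import pytest

from fuzzbind import io as fio
from fuzzbind.cg import load_forcefield
from fuzzbind.sequences import BioSequence


@pytest.fixture(scope="session")
def forcefield():
    return load_forcefield()


@pytest.fixture(scope="session")
def serf():
    """Bundled synthetic stand-in for the 68-residue SERF protein."""
    path = ir.files("fuzzbind.data") / "serf_synthetic.fasta"
    return fio.read_fasta(str(path), kind="protein")[0]


@pytest.fixture(scope="session")
def tar():
    """The printed 29-nt TAR hairpin fragment."""
    path = ir.files("fuzzbind.data") / "tar.fasta"
    return fio.read_fasta(str(path), kind="rna")[0]


@pytest.fixture(scope="session")
def ru30():
    return BioSequence("rU30", "rna", "U" * 30)


@pytest.fixture(scope="session")
def ru29():
    return BioSequence("rU29", "rna", "U" * 29)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
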