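import numpy as np
import pytest

from oasisnet import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_pedigree():
    """Hand-built pedigree covering PO, full-sib, half-sib, grandparent and
    unrelated pairs (F1/F2 founders; C and D full sibs; E half sib via sire)."""
    return sd.Pedigree(
        (
            sd.Individual("F1", "F"),
            sd.Individual("F2", "M"),
            sd.Individual("F3", "F"),
            sd.Individual("F4", "F"),
            sd.Individual("C", "F", dam="F1", sire="F2"),
            sd.Individual("D", "M", dam="F1", sire="F2"),
            sd.Individual("E", "F", dam="F3", sire="F2"),
            sd.Individual("G", "M", dam="C", sire="E"),  # inbred-free grandchild of F1
        )
    )


@pytest.fixture(scope="session")
def default_landscape():
    return sd.make_landscape(rng=np.random.default_rng(42))
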