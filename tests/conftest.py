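import numpy as np
import pytest

from rdcrefine import synthetic as syn


TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  H   GLY A   2       3.887   0.713   0.123  1.00  0.00           H
ATOM      7  CA  GLY A   2       4.013   2.821   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.510   2.622   0.221  1.00  0.00           C
ATOM      9  O   GLY A   2       6.010   1.500   0.312  1.00  0.00           O
TER
END
"""


@pytest.fixture(scope="session")
def two_residue_pdb():
    return TWO_RESIDUE_PDB


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue alpha helix."""
    return syn.make_structure(syn.SyntheticSpec(segments=(("alpha", 20),)))


@pytest.fixture(scope="session")
def helix310():
    """Ideal 15-residue 3-10 helix."""
    return syn.make_structure(syn.SyntheticSpec(segments=(("three10", 15),)))


@pytest.fixture(scope="session")
def mixed_structure():
    """Helix-coil-strand toy with orientationally diverse N-H vectors."""
    return syn.make_structure(
        syn.SyntheticSpec(segments=(("alpha", 12), ("coil", 3), ("strand", 8)))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
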