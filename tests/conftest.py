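import numpy as np
import pytest

from metabind.synthetic import SyntheticSpec, make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-pocket benchmark shared across tests."""
    return make_benchmark(SyntheticSpec(n_proteins=12, n_molecules=40,
                                        residues_per_protein=(25, 40), seed=7))


TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  SER A   3      12.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  LEU B   1       0.000   8.000   0.000  1.00  0.00           C
ATOM      7  CA  VAL B   2       3.800   8.000   0.000  1.00  0.00           C
TER
HETATM    8  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       0.300   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA ASER A   3       7.600   0.000   0.000  0.50  0.00           C
ATOM      5  CA BSER A   3       7.900   0.000   0.000  0.50  0.00           C
END
"""


@pytest.fixture
def two_chain_pdb():
    return TWO_CHAIN_PDB


@pytest.fixture
def altloc_pdb():
    return ALTLOC_PDB
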