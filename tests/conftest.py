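import numpy as np
import pytest

from gaussdyn import (
    SyntheticSpec,
    make_chain,
    make_ground_truth,
)


@pytest.fixture(scope="session")
def chain30():
    return make_chain(30, seed=42)


@pytest.fixture(scope="session")
def spec_default():
    return SyntheticSpec(seed=42)


@pytest.fixture(scope="session")
def ground_truth30(chain30, spec_default):
    """(marginals, correlation, joint) for the session chain."""
    return make_ground_truth(chain30, spec_default)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, d=3, scale=1.0):
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d))


def random_correlation(rng, n):
    """Random SPD correlation matrix (standardized Wishart-like draw)."""
    A = rng.standard_normal((n, n + 3))
    C = A @ A.T + 0.5 * np.eye(n)
    s = np.sqrt(np.diag(C))
    C = C / np.outer(s, s)
    np.fill_diagonal(C, 1.0)
    return C


@pytest.fixture()
def spd_factory():
    return random_spd


@pytest.fixture()
def correlation_factory():
    return random_correlation


TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1      -0.570   1.340   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       1.900   2.500   0.300  1.00  0.00           N
ATOM      5  CA AGLY A   2       2.500   1.300   0.800  0.60  0.00           C
ATOM      6  CA BGLY A   2       2.700   1.100   0.900  0.40  0.00           C
ATOM      7  C   GLY A   2       3.900   1.000   0.300  1.00  0.00           C
ATOM      8  N   SER A   3       4.300   3.400   1.100  1.00  0.00           N
ATOM      9  CA  SER A   3       5.000   2.200   1.500  1.00  0.00           C
ATOM     10  C   SER A   3       6.400   2.100   0.900  1.00  0.00           C
TER
ATOM     11  N   LEU B   1       9.430  11.340  10.000  1.00  0.00           N
ATOM     12  CA  LEU B   1      10.000  10.000  10.000  1.00  0.00           C
ATOM     13  C   LEU B   1      11.520  10.000  10.000  1.00  0.00           C
ATOM     14  N   VAL B   2      11.900  12.500  10.300  1.00  0.00           N
ATOM     15  CA  VAL B   2      12.500  11.300  10.800  1.00  0.00           C
ATOM     16  C   VAL B   2      13.900  11.000  10.300  1.00  0.00           C
TER
END
"""


@pytest.fixture()
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path
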