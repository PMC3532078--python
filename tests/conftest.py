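"""Shared fixtures and independent numerical oracles for the test suite."""

import numpy as np
import pytest

import dtphylosim as dps

# The worked 5-taxon example tree used throughout the docs.
EXAMPLE_TREE = (
    "((species1:0.01,species2:0.2,species3:0.3):0.5,"
    "species4:0.4,species5:0.7);"
)
EXAMPLE_LENGTHS = (0.01, 0.2, 0.3, 0.4, 0.5, 0.7)


def det3(m):
    """3x3 determinant by the rule of Sarrus (plain Python floats)."""
    return (
        m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
        - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
        + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
    )


def det4_cofactor(M):
    """4x4 determinant by cofactor expansion along the first row.

    Deliberately independent of numpy.linalg: this is the oracle against
    which the package's determinant-based contracts are checked.
    """
    M = [[float(x) for x in row] for row in np.asarray(M)]
    total = 0.0
    for j in range(4):
        minor = [[M[i][k] for k in range(4) if k != j] for i in range(1, 4)]
        total += (-1.0) ** j * M[0][j] * det3(minor)
    return total


def logdet_len_oracle(M):
    """-1/4 ln det via the cofactor oracle."""
    import math

    return -0.25 * math.log(det4_cofactor(M))


@pytest.fixture
def example_tree():
    return dps.parse_newick(EXAMPLE_TREE)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
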