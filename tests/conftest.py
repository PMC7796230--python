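"""Shared fixtures: one default toy system per session plus small helpers."""

import numpy as np
import pytest

from grestlite.toy import ToySystem, build_two_domain_system


@pytest.fixture(scope="session")
def toy_system() -> ToySystem:
    """The default coarse-grained two-domain system."""
    return build_two_domain_system()


@pytest.fixture(scope="session")
def solute_atoms(toy_system):
    """The planted solute: all charged beads (0-based indices)."""
    return tuple(int(a) for a in np.flatnonzero(toy_system.charges != 0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_toy_configs(system, n, sigma=0.3, seed=0):
    """Random perturbations around both references."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ref = system.references["closed" if i % 2 == 0 else "open"]
        out.append(ref + rng.normal(0.0, sigma, ref.shape))
    return out


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.729   6.768  -4.123  1.00  0.00           C
ATOM      4  O   ALA A   1       9.580   7.103  -4.420  1.00  0.00           O
ATOM      5  N   ASP A   2      11.255   7.002  -2.915  1.00  0.00           N
ATOM      6  CA  ASP A   2      10.473   7.646  -1.865  1.00  0.00           C
ATOM      7  CB  ASP A   2      11.314   7.782  -0.595  1.00  0.00           C
ATOM      8  OD1 ASP A   2      12.514   8.096  -0.722  1.00  0.00           O
ATOM      9  N   LYS A   3       9.215   7.226  -1.681  1.00  0.00           N
ATOM     10  CA  LYS A   3       8.325   7.804  -0.670  1.00  0.00           C
ATOM     11  NZ  LYS A   3       7.019   7.073  -0.631  1.00  0.00           N
END
"""
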