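"""Shared fixtures: synthetic systems (built once per session) and helpers."""

import numpy as np
import pytest

from flexdock.fixtures import make_pocket_system
from flexdock.ga import GAConfig
from flexdock.params import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def open_pocket():
    return make_pocket_system("open-pocket", seed=1)


@pytest.fixture(scope="session")
def apo_clash():
    return make_pocket_system("apo-clash", seed=1)


@pytest.fixture(scope="session")
def two_flex():
    return make_pocket_system("two-flex", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def toy_ga_config(**overrides) -> GAConfig:
    """Small-population GA settings sized for the enumerable toy systems."""
    base = dict(population_size=30, n_runs=5, seed=11, max_generations=40,
                quick_steps=15)
    base.update(overrides)
    return GAConfig(**base)


# hand-written PDBQT ligand: pentane with two rotatable bonds
PENTANE_PDBQT = """\
ROOT
ATOM      1  C1  LIG L   1       0.000   0.000   0.000  1.00  0.00     0.000 C
ATOM      2  C2  LIG L   1       1.526   0.000   0.000  1.00  0.00     0.000 C
ENDROOT
BRANCH   2   3
ATOM      3  C3  LIG L   1       2.078   1.423   0.000  1.00  0.00     0.000 C
BRANCH   3   4
ATOM      4  C4  LIG L   1       3.604   1.423   0.060  1.00  0.00     0.000 C
ATOM      5  C5  LIG L   1       4.156   2.846   0.060  1.00  0.00     0.000 C
ENDBRANCH   3   4
ENDBRANCH   2   3
TORSDOF 2
"""

# rigid single-atom ligand
ATOM_PDBQT = """\
ROOT
ATOM      1  C1  LIG L   1       0.100  -0.200   0.300  1.00  0.00     0.100 C
ENDROOT
TORSDOF 0
"""
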