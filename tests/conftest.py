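"""Shared fixtures: simulated ensembles reused across test modules.

The Monte Carlo ensembles are session-scoped because they are by far the
most expensive objects in the suite; every test that needs an equilibrium
ensemble at a given temperature shares the same seeded run.
"""

import math

import pytest

from gqstack.geometry import InteractionParams
from gqstack.mc import MCSettings, simulate


def _ens(n, T_star, sweeps, seed, stride=5, initial_mode="stacked"):
    params = InteractionParams(T_star=T_star)
    settings = MCSettings(sweeps=sweeps, equilibration_sweeps=sweeps // 10,
                          snapshot_stride=stride, seed=seed)
    return simulate(n, params, settings, initial_mode=initial_mode)


@pytest.fixture(scope="session")
def dimer_free():
    """2-mer with attraction off (T* = +inf): beads-on-a-string reference."""
    return _ens(2, math.inf, 700_000, seed=9001, stride=2)


@pytest.fixture(scope="session")
def dimer_low():
    """2-mer deep in the stacked regime (T* = 0.050)."""
    return _ens(2, 0.050, 500_000, seed=9002)


@pytest.fixture(scope="session")
def dimer_mid():
    """2-mer at the SAXS-fitted effective temperature T* = 0.190."""
    return _ens(2, 0.190, 1_200_000, seed=9003)


@pytest.fixture(scope="session")
def dimer_warm():
    """2-mer at T* = 1.0 (weakly interacting)."""
    return _ens(2, 1.0, 300_000, seed=9004)


@pytest.fixture(scope="session")
def dimer_mid_extended():
    """Same state point as dimer_mid but started from an extended chain."""
    return _ens(2, 0.190, 400_000, seed=9007, initial_mode="extended")


@pytest.fixture(scope="session")
def trimer_mid():
    """3-mer at T* = 0.190."""
    return _ens(3, 0.190, 900_000, seed=9005)


@pytest.fixture(scope="session")
def tetramer_mid():
    """4-mer at T* = 0.190."""
    return _ens(4, 0.190, 700_000, seed=9006)
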