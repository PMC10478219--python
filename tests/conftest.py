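"""Shared fixtures: small deterministic lattices and the (expensive)
critical colony ensemble reused by several acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

import cpim
from cpim.core import LatticeState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_state_lattice(rng):
    """A 12x12 lattice with all four site codes present."""
    grid = rng.choice(np.array([0, 2, 1, -1], dtype=np.int8), size=(12, 12),
                      p=[0.2, 0.2, 0.3, 0.3])
    return LatticeState(grid)


@pytest.fixture(scope="session")
def critical_colony_ensemble():
    """Ferromagnetic colonies grown to full cover at the critical coupling.

    Twenty seeded runs at L=128, T=2.27, b=0.03, d=1e-5; shared across
    the spatial-correlation and cluster-statistics acceptance tests.
    """
    from cpim.protocols import grow_critical_colonies
    return grow_critical_colonies(n_colonies=20, L=128, seed=20260901)


@pytest.fixture(scope="session")
def ising_critical_snapshots():
    """Equilibrium pure-Ising snapshots at the critical temperature."""
    from cpim.protocols import ising_snapshot_ensemble
    return ising_snapshot_ensemble(n_runs=32, snapshots_per_run=1,
                                   L=128, T=2.269, seed=77)
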