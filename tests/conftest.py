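"""Shared fixtures: small synthetic sessions reused across test modules."""
import numpy as np
import pytest

import torusnav as tn


@pytest.fixture(scope="session")
def foraging_traj():
    """15-min foraging path on the 50-cm arena."""
    return tn.simulate_foraging_trajectory(900, arena_radius=25, seed=11)


@pytest.fixture(scope="session")
def big_arena_traj():
    """15-min foraging path on the 80-cm arena (room for 40-cm lattices)."""
    return tn.simulate_foraging_trajectory(900, arena_radius=40, seed=12)


@pytest.fixture(scope="session")
def grid_module():
    """Co-modular population with the default study geometry."""
    return tn.make_module(5, seed=21)


@pytest.fixture(scope="session")
def module_session(foraging_traj, grid_module):
    """(traj, spikes, ground_truth, geom) for a drift-free foraging session."""
    spikes, gt = tn.simulate_module_spikes(foraging_traj, grid_module, seed=31)
    return foraging_traj, spikes, gt, tn.module_geometry_of(grid_module)


@pytest.fixture(scope="session")
def geom():
    return tn.ModuleGeometry(0.0, np.pi / 3, 30.0, 30.0)
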