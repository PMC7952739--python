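"""Shared fixtures: the toy system and the expensive sampled ensembles.

Simulation-backed fixtures are session-scoped so the physics checks, the
screening tests and the end-to-end recovery test share one set of
trajectories.
"""

import numpy as np
import pytest

from cgsaxs.cg_builder import assign_charges, build_topology
from cgsaxs.cg_simulator import SimulationParams, run_langevin
from cgsaxs.synthetic_data import (ExperimentSpec, ToySpec, make_toy_protein,
                                   make_two_state_ensemble,
                                   synthesize_experiment)

OPEN_D = 60.0
CLOSED_D = 48.0


@pytest.fixture(scope="session")
def toy_system():
    """Toy protein at the crystal-like default geometry, charged, with topology."""
    structure, chain, definition = make_toy_protein(ToySpec())
    chain = assign_charges(chain)
    topology = build_topology(chain)
    return structure, chain, definition, topology


@pytest.fixture(scope="session")
def free_trajectory(toy_system):
    """Unrestrained 300 K Langevin run of the toy protein."""
    _, chain, _, topology = toy_system
    params = SimulationParams(n_steps=12000, save_interval=200, seed=4)
    return run_langevin(chain, topology, params)


@pytest.fixture(scope="session")
def two_state(toy_system):
    """Open/closed restrained ensembles of the edge-domain distance."""
    _, chain, _, topology = toy_system
    return make_two_state_ensemble(chain, topology, open_d=OPEN_D,
                                   closed_d=CLOSED_D, n_frames=60, seed=11)


@pytest.fixture(scope="session")
def experiments(toy_system, two_state):
    """Synthetic noisy, contaminated observations for both states."""
    _, chain, _, _ = toy_system
    traj_open, traj_closed = two_state
    out = {}
    for name, traj, seed in (("open", traj_open, 5), ("closed", traj_closed, 6)):
        observed, truth, mixture = synthesize_experiment(
            traj, chain, ExperimentSpec(seed=seed))
        out[name] = {"observed": observed, "truth": truth, "mixture": mixture,
                     "trajectory": traj}
    return out
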