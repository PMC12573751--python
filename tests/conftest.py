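"""Shared fixtures: synthetic oracle trajectories reused across test modules."""

import numpy as np
import pytest

import committor_lab as cl


@pytest.fixture(scope="session")
def dw_spec():
    return cl.DoubleWellSpec(barrier=3.0, D0=1.0, dt=1e-3, seed=11)


@pytest.fixture(scope="session")
def dw_traj(dw_spec):
    """One long equilibrium double-well trajectory (10^6 steps)."""
    return cl.simulate_double_well(dw_spec, 1_000_000)


@pytest.fixture(scope="session")
def dw_rc(dw_spec, dw_traj):
    """The trajectory projected on the analytic committor."""
    return cl.project_on_committor(dw_traj, dw_spec)


@pytest.fixture(scope="session")
def walk_spec():
    return cl.symmetric_walk_spec(5, seed=7)


@pytest.fixture(scope="session")
def walk_traj(walk_spec):
    return cl.simulate_chain(walk_spec, 1_000_000)


@pytest.fixture(scope="session")
def lattice_traj():
    """Small equilibrated lattice trajectory for CV/bookkeeping tests."""
    cfg = cl.LatticeConfig(L=20, N=12, xi=2.0, T=0.6, dt0=200,
                           n_steps=400_000, seed=9)
    return cl.run(cfg)
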