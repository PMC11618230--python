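"""Shared fixtures.

The heavier solver runs (Poiseuille recovery, coupled tube/sidewall runs)
are session-scoped so that unit checks and the acceptance checks measure
the same computation instead of re-running it.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from clotflow import (generate_tube_mesh, build_scenario,
                      FluidProperties, PorosityParams, FlowSolverConfig,
                      InflowBC, FlowSolver)
from clotflow.coupling import run_coupled


TUBE_D = 300e-6
TUBE_L = 3e-3
MEAN_V = 1.5e-2


@pytest.fixture(scope="session")
def tube_mesh_fine():
    """Device-free tube resolved well enough for Poiseuille recovery."""
    return generate_tube_mesh(TUBE_D, TUBE_L, 20e-6, target_h_axial=100e-6)


@pytest.fixture(scope="session")
def poiseuille(tube_mesh_fine):
    """Converged steady flow at the physiologic mean velocity."""
    solver = FlowSolver(tube_mesh_fine, None, FluidProperties(),
                       PorosityParams(), FlowSolverConfig())
    state = solver.solve(InflowBC(mean_velocity=MEAN_V))
    return solver, state


@pytest.fixture(scope="session")
def tube_mesh_coarse():
    """Small tube mesh for transport/stability unit tests."""
    return generate_tube_mesh(TUBE_D, TUBE_L, 45e-6, target_h_axial=135e-6)


def _run_tube(name: str, t_end: float, **kw):
    sc = build_scenario(name, target_h=60e-6, t_end=t_end, **kw)
    ccfg = replace(sc.coupling, checkpoint_path=None)
    log = []
    state = run_coupled(sc.model, ccfg, sc.flow_cfg, sc.transport_cfg,
                        trigger_log=log)
    return sc, state, log


@pytest.fixture(scope="session")
def tube90_run():
    """Coarse tube90 coupled run, long enough for several flow re-solves."""
    return _run_tube("tube90", 30.0)


@pytest.fixture(scope="session")
def tube150_run():
    """Coarse tube150 coupled run at the same simulated time as tube90."""
    return _run_tube("tube150", 30.0)


@pytest.fixture(scope="session")
def sidewall_run():
    """Coarse sidewall-plasma coupled run with periodic flow re-solves."""
    sc = build_scenario("sidewall_plasma", target_h=0.8e-3, t_end=20.0)
    ccfg = replace(sc.coupling, max_phase_time=5.0, min_phase_time=2.0,
                   resolve_each_phase=True)
    state = run_coupled(sc.model, ccfg, sc.flow_cfg, sc.transport_cfg)
    return sc, state
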