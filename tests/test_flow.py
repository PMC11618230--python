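"""Steady incompressible flow: Poiseuille recovery, Darcy feedback,
shear-stress evaluation and the residual split."""

import numpy as np
import pytest

from clotflow import generate_tube_mesh
from clotflow.flow import (FluidProperties, PorosityParams, FlowSolverConfig,
                           InflowBC, FlowSolver, darcy_force, shear_stress,
                           flow_residual_split, solve_steady)
from tests.conftest import TUBE_D, TUBE_L, MEAN_V

R = TUBE_D / 2


class TestPoiseuille:
    def test_centerline_velocity(self, tube_mesh_fine, poiseuille):
        m = tube_mesh_fine
        _, st = poiseuille
        mid = np.abs(m.nodes[:, 0] - TUBE_L / 2) < 6e-5
        core = mid & (np.linalg.norm(m.nodes[:, 1:], axis=1) < 0.15 * R)
        assert core.any()
        u_c = st.u[core, 0].max()
        assert abs(u_c - 2 * MEAN_V) / (2 * MEAN_V) < 0.05

    def test_parabolic_profile_rms(self, tube_mesh_fine, poiseuille):
        m = tube_mesh_fine
        _, st = poiseuille
        mid = np.abs(m.nodes[:, 0] - TUBE_L / 2) < 6e-5
        r = np.linalg.norm(m.nodes[mid, 1:], axis=1)
        u_ref = 2 * MEAN_V * (1 - (r / R) ** 2)
        rms = np.sqrt(np.mean((st.u[mid, 0] - u_ref) ** 2)) / (2 * MEAN_V)
        assert rms < 0.05

    def test_wall_shear(self, tube_mesh_fine, poiseuille):
        m = tube_mesh_fine
        _, st = poiseuille
        rc = np.linalg.norm(m.centroids[:, 1:], axis=1)
        mid = np.abs(m.centroids[:, 0] - TUBE_L / 2) < 3e-4
        wall_adj = mid & (rc > R - 24e-6)
        tau_wall = st.tau_elem[wall_adj].mean()
        ref = 4 * FluidProperties().mu * MEAN_V / R
        assert abs(tau_wall - ref) / ref < 0.10

    def test_mass_balance(self, poiseuille):
        solver, st = poiseuille
        q_in = -solver.boundary_flux(st.u, 1)
        q_out = solver.boundary_flux(st.u, 2)
        assert q_in > 0
        assert abs(q_in - q_out) / q_in < 1e-3

    def test_flow_rate_matches_request(self, poiseuille):
        solver, st = poiseuille
        q_in = -solver.boundary_flux(st.u, 1)
        q_ref = MEAN_V * np.pi * R * R
        assert abs(q_in - q_ref) / q_ref < 0.02   # discrete inlet disc area

    def test_axisymmetry(self, tube_mesh_fine, poiseuille):
        """Velocity depends on radius only, to discretisation error."""
        m = tube_mesh_fine
        _, st = poiseuille
        mid = np.abs(m.nodes[:, 0] - TUBE_L / 2) < 6e-5
        r = np.linalg.norm(m.nodes[mid, 1:], axis=1)
        band = (np.abs(r - 0.5 * R) < 0.1 * R)
        ux = st.u[mid][band, 0]
        assert ux.std() / ux.mean() < 0.05


class TestZeroAndDegenerate:
    def test_zero_inflow_gives_rest(self, tube_mesh_coarse):
        st = solve_steady(tube_mesh_coarse, None, None,
                          InflowBC(flow_rate=0.0), FluidProperties(),
                          PorosityParams(), FlowSolverConfig())
        assert np.all(st.u == 0.0)
        assert np.ptp(st.p) == 0.0

    def test_missing_outlet_rejected(self, tube_mesh_coarse):
        import copy
        m = copy.copy(tube_mesh_coarse)
        m.node_tag = np.where(m.node_tag == 2, 3, m.node_tag)
        with pytest.raises(ValueError):
            FlowSolver(m, None, FluidProperties(), PorosityParams(),
                       FlowSolverConfig())


class TestDarcy:
    def test_force_trivials(self):
        pp = PorosityParams(pi_coeff=1e7, Cfb0=1.0, n_hill=2)
        u = np.array([[1.0, 0.0, 0.0]])
        assert np.all(darcy_force(0.0, u, pp) == 0.0)
        np.testing.assert_allclose(darcy_force(1.0, u, pp),
                                   -0.5 * 1e7 * u, rtol=1e-12)
        np.testing.assert_allclose(darcy_force(2.0, u, pp),
                                   -0.8 * 1e7 * u, rtol=1e-12)

    def test_force_antiparallel(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=(50, 3))
        F = darcy_force(rng.uniform(0.1, 5, 50), u, PorosityParams())
        cos = np.einsum("ij,ij->i", F, u)
        assert np.all(cos <= 0)

    def test_occlusion_limit(self, tube_mesh_coarse):
        """A fully clotted tube under a fixed pressure head passes at least
        100x less flow than the open tube."""
        m = tube_mesh_coarse
        fp = FluidProperties()
        pp = PorosityParams(pi_coeff=1e9)
        cfg = FlowSolverConfig(eps1=1e-6)
        bc = InflowBC(pressure_drop=20.0)
        solver = FlowSolver(m, None, fp, pp, cfg)
        open_state = solver.solve(bc)
        solver.set_porosity(np.full(m.n_elements, 100.0 * pp.Cfb0))
        clotted = solver.solve(bc)
        interior = np.linalg.norm(m.nodes[:, 1:], axis=1) < R - 20e-6
        v0 = np.linalg.norm(open_state.u[interior], axis=1).max()
        v1 = np.linalg.norm(clotted.u[interior], axis=1).max()
        assert v0 / max(v1, 1e-300) >= 100.0

    def test_pressure_drop_monotone_in_clot(self, tube_mesh_coarse):
        """With a prescribed flow rate, uniform clotting raises the
        pressure drop monotonically."""
        m = tube_mesh_coarse
        solver = FlowSolver(m, None, FluidProperties(), PorosityParams(),
                            FlowSolverConfig())
        bc = InflowBC(mean_velocity=MEAN_V)
        drops = []
        for cfb in (0.0, 0.5, 1.0, 2.0):
            solver.set_porosity(np.full(m.n_elements, cfb))
            st = solver.solve(bc)
            drops.append(st.p[m.node_tag == 1].mean())
        assert all(b >= a for a, b in zip(drops, drops[1:]))


class TestShearStress:
    def test_rigid_translation_is_stress_free(self, tube_mesh_coarse):
        u = np.tile([0.1, -0.2, 0.05], (tube_mesh_coarse.n_nodes, 1))
        tau = shear_stress(u, tube_mesh_coarse, FluidProperties())
        assert np.abs(tau).max() < 1e-12

    def test_pure_shear_exact(self, tube_mesh_coarse):
        m = tube_mesh_coarse
        gdot = 123.0
        u = np.zeros((m.n_nodes, 3))
        u[:, 0] = gdot * m.nodes[:, 1]
        tau = shear_stress(u, m, FluidProperties())
        np.testing.assert_allclose(tau, FluidProperties().mu * gdot,
                                   rtol=1e-10)


class TestResidualSplit:
    def test_split_properties(self, tube_mesh_coarse):
        m = tube_mesh_coarse
        fp, pp = FluidProperties(), PorosityParams()
        solver = FlowSolver(m, None, fp, pp, FlowSolverConfig())
        st = solver.solve(InflowBC(mean_velocity=MEAN_V))
        R1, R2 = flow_residual_split(st, m, fp, pp, None)
        assert np.all(R2 == 0.0)
        cfb = np.full(m.n_elements, 1.0)
        _, R2a = flow_residual_split(st, m, fp, pp, cfb)
        pp2 = PorosityParams(pi_coeff=2 * pp.pi_coeff, Cfb0=pp.Cfb0)
        _, R2b = flow_residual_split(st, m, fp, pp2, cfb)
        np.testing.assert_allclose(R2b, 2.0 * R2a, rtol=1e-12)

    def test_converged_state_satisfies_steady_criterion(self,
                                                        tube_mesh_coarse):
        """At convergence the last velocity increment (= dt |R1+R2| in the
        scheme) is below the eps1 tolerance."""
        m = tube_mesh_coarse
        cfg = FlowSolverConfig()
        solver = FlowSolver(m, None, FluidProperties(), PorosityParams(), cfg)
        st = solver.solve(InflowBC(mean_velocity=MEAN_V))
        assert st.converged
        assert st.residual_history[-1] < cfg.eps1
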