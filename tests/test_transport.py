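"""Finite-volume transport: conservation, upwind monotonicity, TVD
accuracy, the stability bound, boundary fluxes and the neighbour average."""

import numpy as np
import pytest

from clotflow import generate_tube_mesh
from clotflow.mesh import TAG_WALL
from clotflow.reaction import ReactionParams
from clotflow.transport import (SpeciesField, TransportConfig,
                                TransportSolver, bounded_neighbor_average)

INLET = np.array([1.4, 2.41, 0.0, 7.0, 0.0, 0.0])


@pytest.fixture(scope="module")
def mesh():
    return generate_tube_mesh(200e-6, 4e-3, 40e-6, target_h_axial=40e-6)


def inert_params():
    return ReactionParams(Kwt=0, Kat=0, Kth=0, Kss=0, Kwa=0, Kb=0)


def make_solver(mesh, scheme="upwind1", fiber_length=0.0, params=None,
                courant=0.4):
    cfg = TransportConfig(scheme=scheme, fiber_length=fiber_length,
                          courant=courant)
    return TransportSolver(mesh, None, params or inert_params(), cfg)


def uniform_flow(mesh, speed):
    u = np.zeros((mesh.n_nodes, 3))
    u[:, 0] = speed
    return u


class TestConservation:
    def test_uniform_field_is_stationary(self, mesh):
        ts = make_solver(mesh)
        ts.set_flow(uniform_flow(mesh, 0.01), np.zeros(mesh.n_elements))
        f = SpeciesField.zeros(mesh.n_elements, inlet_values=INLET)
        f.C[:] = INLET[:, None]
        C0 = f.C.copy()
        for _ in range(30):
            ts.step(f)
        assert np.abs(f.C - C0).max() < 1e-13

    def test_closed_box_mass_constant(self, mesh):
        """No flow, no reactions: total mass of every species is conserved
        to machine precision each step (flux antisymmetry)."""
        ts = make_solver(mesh)
        ts.set_flow(np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_elements))
        rng = np.random.default_rng(1)
        f = SpeciesField(C=rng.random((6, mesh.n_elements)))
        tot0 = (f.C * mesh.volumes).sum(axis=1)
        for _ in range(20):
            ts.step(f, 1e-3)
        tot1 = (f.C * mesh.volumes).sum(axis=1)
        assert np.abs(tot1 / tot0 - 1).max() < 1e-12

    def test_fibrin_family_changes_only_by_boundary_flux(self, mesh):
        """Reactions move mass between Fg, Fn and Fb but never create or
        destroy the family total."""
        p = ReactionParams()
        ts = make_solver(mesh, params=p, fiber_length=60e-6)
        ts.set_flow(np.zeros((mesh.n_nodes, 3)), np.full(mesh.n_elements, 3.0))
        rng = np.random.default_rng(2)
        f = SpeciesField(C=rng.random((6, mesh.n_elements)))
        fam0 = ((f.C[3] + f.C[4] + f.C[5]) * mesh.volumes).sum()
        for _ in range(20):
            ts.step(f, 1e-3)
        fam1 = ((f.C[3] + f.C[4] + f.C[5]) * mesh.volumes).sum()
        assert abs(fam1 / fam0 - 1) < 1e-12

    def test_global_balance_identity(self, mesh):
        """d/dt sum C V decomposes exactly into boundary flux + divergence
        correction + reactions."""
        p = ReactionParams()
        ts = make_solver(mesh, params=p, fiber_length=60e-6)
        from clotflow.flow import (FlowSolver, FluidProperties,
                                   PorosityParams, FlowSolverConfig, InflowBC)
        solver = FlowSolver(mesh, None, FluidProperties(), PorosityParams(),
                            FlowSolverConfig())
        st = solver.solve(InflowBC(mean_velocity=0.01))
        ts.set_flow(st.u, st.tau_elem)
        rng = np.random.default_rng(3)
        f = SpeciesField(C=rng.random((6, mesh.n_elements)), inlet_values=INLET)
        bal = ts.global_balance(f)
        # recompute the boundary term directly from the face lists
        direct = np.zeros(6)
        C = f.C
        for j, a in enumerate(ts._in_k1):
            q = ts.q_in[j]
            for i in range(5):
                cu = C[i, a] if q > 0 else INLET[i]
                direct[i] -= cu * q
        for j, a in enumerate(ts._out_k1):
            for i in range(5):
                direct[i] -= C[i, a] * ts.q_out[j]
        scale = np.abs(bal["rate"]).max()
        assert np.abs(bal["boundary"] - direct).max() / scale < 1e-8


class TestUpwindMonotonicity:
    def advect_step_profile(self, mesh, scheme):
        ts = make_solver(mesh, scheme=scheme)
        ts.set_flow(uniform_flow(mesh, 0.01), np.zeros(mesh.n_elements))
        inlet = np.zeros(6)
        inlet[0] = 1.0            # continue the upstream state of the step
        f = SpeciesField.zeros(mesh.n_elements, inlet_values=inlet)
        f.D[:] = 0.0
        f.C[0] = (mesh.centroids[:, 0] < 1e-3).astype(float)
        tv0 = self.total_variation(mesh, f.C[0])
        ts.advance(f, 0.1)
        return f.C[0], tv0, ts

    @staticmethod
    def total_variation(mesh, c):
        """Axially projected 1D total variation (volume-weighted means per
        structured mesh layer); the quantity a monotone scheme keeps
        non-increasing for a 1D advection problem.  Bins must align with
        the layers or binning itself manufactures wiggles."""
        x = mesh.centroids[:, 0]
        L = mesh.metadata["length"]
        nb = int(round(L / 40e-6))
        idx = np.clip((x / (L / nb)).astype(int), 0, nb - 1)
        wsum = np.bincount(idx, weights=mesh.volumes, minlength=nb)
        csum = np.bincount(idx, weights=c * mesh.volumes, minlength=nb)
        sel = wsum > 0
        prof = csum[sel] / wsum[sel]
        return np.abs(np.diff(prof)).sum()

    def test_no_new_extrema(self, mesh):
        c, _, _ = self.advect_step_profile(mesh, "upwind1")
        assert c.min() >= -1e-14
        assert c.max() <= 1.0 + 1e-12

    def test_total_variation_non_increasing(self, mesh):
        c, tv0, _ = self.advect_step_profile(mesh, "upwind1")
        assert self.total_variation(mesh, c) <= tv0 + 1e-10

    def test_tvd_reduces_smooth_advection_error(self, mesh):
        """The MUSCL/minmod scheme beats first-order upwinding in L1 on a
        smooth advected profile."""
        x = mesh.centroids[:, 0]
        exact = np.exp(-(((x - 0.001) - 1e-3) / 0.3e-3) ** 2)
        errs = {}
        for scheme in ("upwind1", "tvd"):
            ts = make_solver(mesh, scheme=scheme)
            ts.set_flow(uniform_flow(mesh, 0.01), np.zeros(mesh.n_elements))
            f = SpeciesField.zeros(mesh.n_elements)
            f.D[:] = 0.0
            f.C[0] = np.exp(-((x - 1e-3) / 0.3e-3) ** 2)
            ts.advance(f, 0.1)
            errs[scheme] = np.sum(np.abs(f.C[0] - exact) * mesh.volumes)
        assert errs["tvd"] < errs["upwind1"]


class TestStableDt:
    def test_no_constraint_returns_cap(self, mesh):
        cfg = TransportConfig(courant=0.5, fiber_length=0.0, dt_max=0.25)
        ts = TransportSolver(mesh, None, inert_params(), cfg)
        ts.set_flow(np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_elements))
        f = SpeciesField.zeros(mesh.n_elements)
        f.D[:] = 0.0
        assert ts.stable_dt(f) == pytest.approx(0.5 * 0.25)

    def test_convection_bound(self, mesh):
        ts = make_solver(mesh, courant=0.5)
        ts.set_flow(uniform_flow(mesh, 0.01), np.zeros(mesh.n_elements))
        f = SpeciesField.zeros(mesh.n_elements)
        f.D[:] = 0.0
        dt = ts.stable_dt(f)
        hmin = mesh.h.min()
        # the divergence bound can only tighten the convection bound
        assert dt <= 0.5 * hmin / 0.01 + 1e-15
        assert dt >= 0.05 * hmin / 0.01

    def test_diffusion_bound_when_it_binds(self, mesh):
        ts = make_solver(mesh, courant=0.5)
        ts.set_flow(np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_elements))
        f = SpeciesField.zeros(mesh.n_elements)
        f.D[:] = 1e-8
        dt = ts.stable_dt(f)
        expected = 0.5 * (mesh.h.min() ** 2) / (2 * 1e-8)
        assert dt == pytest.approx(expected, rel=1e-12)

    def test_reaction_sink_bound(self, mesh):
        p = ReactionParams(Kwt=0, Kat=10.0, Kth=0, Kss=0, Kwa=0, Kb=0)
        ts = make_solver(mesh, params=p, courant=0.5)
        ts.set_flow(np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_elements))
        f = SpeciesField.zeros(mesh.n_elements)
        f.D[:] = 0.0
        f.C[1] = 2.0   # AT
        f.C[2] = 1.0   # Th -> sink rate Kat*C_AT = 20/s on Th
        dt = ts.stable_dt(f)
        assert dt == pytest.approx(0.5 / 20.0, rel=1e-9)


class TestBoundaryFluxes:
    def test_zero_inlet_concentration_no_influx(self, mesh):
        ts = make_solver(mesh)
        ts.set_flow(uniform_flow(mesh, 0.01), np.zeros(mesh.n_elements))
        f = SpeciesField.zeros(mesh.n_elements)   # inlet values all zero
        bal = ts.global_balance(f)
        assert np.abs(bal["boundary"]).max() == 0.0

    def test_steady_advection_outflux_equals_influx(self, mesh):
        ts = make_solver(mesh)
        ts.set_flow(uniform_flow(mesh, 0.01), np.zeros(mesh.n_elements))
        f = SpeciesField.zeros(mesh.n_elements, inlet_values=INLET)
        f.C[:] = INLET[:, None]        # steady state of pure advection
        f.D[:] = 0.0
        bal = ts.global_balance(f)
        # influx and outflux cancel exactly for the uniform steady state
        assert np.abs(bal["rate"]).max() < 1e-6 * np.abs(
            INLET[:, None] * ts.q_in.sum()).max()

    def test_wall_faces_contribute_nothing(self, mesh):
        ts = make_solver(mesh)
        # wall faces are excluded from every flux list
        wall = np.flatnonzero(mesh.face_tag == TAG_WALL)
        assert not np.isin(wall, ts._if).any()
        assert not np.isin(wall, ts._inf).any()
        assert not np.isin(wall, ts._outf).any()


class TestFaceFluxes:
    def test_matches_naive_reevaluation(self):
        """Per-face fluxes agree with a direct element-by-element
        re-evaluation of the upwind/central discretisation from the raw
        mesh arrays."""
        mesh = generate_tube_mesh(200e-6, 0.8e-3, 45e-6,
                                  target_h_axial=100e-6)
        ts = make_solver(mesh)
        from clotflow.flow import (FlowSolver, FluidProperties,
                                   PorosityParams, FlowSolverConfig, InflowBC)
        solver = FlowSolver(mesh, None, FluidProperties(), PorosityParams(),
                            FlowSolverConfig())
        st = solver.solve(InflowBC(mean_velocity=0.01))
        ts.set_flow(st.u, st.tau_elem)
        rng = np.random.default_rng(9)
        f = SpeciesField(C=rng.random((6, mesh.n_elements)))
        out = ts.face_fluxes(f)
        # naive oracle straight from mesh + nodal velocity
        for j_loc in rng.integers(0, len(out["faces"]), size=60):
            j = out["faces"][j_loc]
            a, b = mesh.face_elems[j]
            n, A = mesh.face_normal[j], mesh.face_area[j]
            uf = st.u[mesh.face_nodes[j]].mean(axis=0)
            q = uf @ n * A
            for i in range(5):
                cu = f.C[i, a] if q >= 0 else f.C[i, b]
                dflux = f.D[i] * (f.C[i, b] - f.C[i, a]) / \
                    mesh.face_ds[j] * A
                # abs floor: analytically-zero fluxes differ only by
                # summation order at the 1e-27 level
                assert out["convective"][i, j_loc] == pytest.approx(
                    cu * q, rel=1e-12, abs=1e-22)
                assert out["diffusive"][i, j_loc] == pytest.approx(
                    dflux, rel=1e-12, abs=1e-22)

class TestNeighborAverage:
    def test_uniform_is_fixed_point(self, mesh):
        c = np.full(mesh.n_elements, 3.3)
        out = bounded_neighbor_average(c, mesh, 60e-6)
        np.testing.assert_allclose(out, 3.3, rtol=1e-14)

    def test_zero_radius_is_identity(self, mesh):
        rng = np.random.default_rng(5)
        c = rng.random(mesh.n_elements)
        out = bounded_neighbor_average(c, mesh, 0.0)
        np.testing.assert_array_equal(out, c)

    def test_matches_brute_force(self, mesh):
        """Average equals a direct O(n^2) evaluation on a subsample."""
        rng = np.random.default_rng(6)
        c = rng.random(mesh.n_elements)
        fl = 70e-6
        out = bounded_neighbor_average(c, mesh, fl)
        cent = mesh.centroids
        for k in rng.integers(0, mesh.n_elements, size=40):
            d = np.linalg.norm(cent - cent[k], axis=1)
            sel = d <= fl
            assert out[k] == pytest.approx(c[sel].mean(), rel=1e-12)

    def test_isolated_source_spreads_to_neighbors(self, mesh):
        c = np.zeros(mesh.n_elements)
        c[1000] = 1.0
        out = bounded_neighbor_average(c, mesh, 70e-6)
        d = np.linalg.norm(mesh.centroids - mesh.centroids[1000], axis=1)
        near = (d <= 70e-6)
        assert (out[near] > 0).all()
        assert (out[~near] == 0).all()
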