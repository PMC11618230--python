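"""Quasi-steady incompressible flow with Darcy clot feedback.

Linear (P1) finite elements on tetrahedra, advanced to steady state with a
fractional-step scheme: an advective-diffusive velocity prediction with the
viscous and porous (Darcy) terms implicit, an incremental pressure-Poisson
solve, and a velocity correction projecting the field onto (discretely)
divergence-free states.  The accumulated bounded fibrin enters as a
momentum sink  F = -pi * phi(C_Fb/C_Fb0) * u  with phi a Hill step, so that
clotted regions behave as a low-permeability porous medium.

Boundary conditions: parabolic inlet velocity (mean-velocity or flow-rate
specified), traction-free outlet (pressure fixed to zero there), no-slip on
walls and on all immersed-boundary (wire) nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh, ImmersedBoundary, TAG_INLET, TAG_OUTLET, TAG_WALL
from .reaction import hill


class FlowNotConverged(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.residual_history = history


@dataclass
class FluidProperties:
    """Plasma density (kg/m^3) and dynamic viscosity (Pa s)."""
    rho: float = 1030.0
    mu: float = 1.3e-3

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


@dataclass
class PorosityParams:
    """Darcy clot feedback: F = -pi_coeff * phi(C_Fb / Cfb0) * u.

    pi_coeff is an inverse permeability scale (kg/(m^3 s)); Cfb0 (µM) is the
    bounded-fibrin threshold at which the switch reaches one half.
    """
    pi_coeff: float = 1e7
    Cfb0: float = 0.5
    n_hill: float = 4.0

    def __post_init__(self):
        if self.pi_coeff < 0 or self.Cfb0 <= 0:
            raise ValueError("pi_coeff >= 0 and Cfb0 > 0 required")


@dataclass
class FlowSolverConfig:
    courant: float = 0.8
    eps1: float = 1e-4          # steady-state tolerance on max |u^{n+1}-u^n| (m/s)
    max_iters: int = 4000
    lin_tol: float = 1e-10      # direct solves are used; kept for reference
    refresh_every: int = 25     # steps between dt / artificial-viscosity updates
    strict: bool = True         # raise FlowNotConverged instead of returning

    def __post_init__(self):
        if self.eps1 <= 0:
            raise ValueError("eps1 must be > 0")


@dataclass
class InflowBC:
    """Steady inflow specification.

    Either a parabolic velocity profile (``mean_velocity`` in m/s or
    ``flow_rate`` in m^3/s, rescaled to match Q exactly on the discrete
    inlet), or a pressure-driven mode (``pressure_drop`` in Pa between inlet
    and outlet) in which the inlet velocity is free and the flow rate is an
    outcome -- the mode in which clot growth can throttle the flow.
    """
    mean_velocity: Optional[float] = None
    flow_rate: Optional[float] = None
    pressure_drop: Optional[float] = None

    def __post_init__(self):
        n = sum(v is not None for v in
                (self.mean_velocity, self.flow_rate, self.pressure_drop))
        if n != 1:
            raise ValueError("specify exactly one of mean_velocity / "
                             "flow_rate / pressure_drop")


@dataclass
class FlowState:
    u: np.ndarray                # nodal velocity (Nn,3)
    p: np.ndarray                # nodal pressure (Nn,)
    tau_elem: np.ndarray         # per-element shear-stress magnitude (Pa)
    residual_history: list = field(default_factory=list)
    converged: bool = True


# --------------------------------------------------------------------------

def _p1_gradients(mesh: TetMesh):
    """Constant P1 basis gradients per element: b[e, a, :] = grad N_a."""
    x = mesh.nodes[mesh.tets]                      # (Nt,4,3)
    b = np.empty((mesh.n_elements, 4, 3))
    # grad of barycentric coords: rows of the inverse Jacobian
    d = x[:, 1:] - x[:, :1]                        # (Nt,3,3) edge matrix
    dinv = np.linalg.inv(d)                        # (Nt,3,3)
    b[:, 1:, :] = np.transpose(dinv, (0, 2, 1))
    b[:, 0, :] = -b[:, 1:, :].sum(axis=1)
    return b


class FlowSolver:
    """Fractional-step steady solver bound to one mesh + device.

    Reusable across coupled steps: the pressure-Poisson factorisation is
    built once; the momentum operator is refactorised whenever the porosity
    field, timestep or artificial viscosity change.
    """

    def __init__(self, mesh: TetMesh, ib: ImmersedBoundary | None,
                 fp: FluidProperties, pp: PorosityParams,
                 cfg: FlowSolverConfig):
        self.mesh, self.fp, self.pp, self.cfg = mesh, fp, pp, cfg
        nn = mesh.n_nodes
        self.b = _p1_gradients(mesh)
        V = mesh.volumes
        # element stiffness V * (b_a . b_b), reused for every coefficient field
        self.ke = np.einsum("eai,ebi->eab", self.b, self.b) * V[:, None, None]
        rows = np.repeat(mesh.tets, 4, axis=1).ravel()
        cols = np.tile(mesh.tets, (1, 4)).ravel()
        self._krc = (rows, cols)
        # lumped mass
        self.ML = np.zeros(nn)
        np.add.at(self.ML, mesh.tets.ravel(), np.repeat(V / 4, 4))
        # no-slip nodes: walls + immersed wires (inlet Dirichlet nodes are
        # added per-solve depending on the inflow mode)
        noslip = np.zeros(nn, dtype=bool)
        noslip[mesh.node_tag == TAG_WALL] = True
        if ib is not None and len(ib.ib_nodes):
            noslip[ib.ib_nodes] = True
        self._noslip = noslip
        out_nodes = np.flatnonzero(mesh.node_tag == TAG_OUTLET)
        if len(out_nodes) == 0:
            raise ValueError("no outlet: the pressure system would be singular")
        self.out_nodes = out_nodes
        self._K1 = self._assemble(np.ones(mesh.n_elements))
        self._lu_p_cache: dict = {}
        self.alpha = np.zeros(mesh.n_elements)     # pi * phi(Cfb/Cfb0)

    # -- assembly ----------------------------------------------------------

    def _assemble(self, coeff: np.ndarray) -> sp.csr_matrix:
        data = (self.ke * coeff[:, None, None]).ravel()
        return sp.coo_matrix((data, self._krc),
                             shape=(self.mesh.n_nodes,) * 2).tocsr()

    def set_porosity(self, Cfb: np.ndarray | None) -> None:
        """Update the element Darcy coefficient from bounded fibrin (µM)."""
        if Cfb is None:
            self.alpha = np.zeros(self.mesh.n_elements)
        else:
            self.alpha = self.pp.pi_coeff * hill(
                np.maximum(np.asarray(Cfb, float), 0.0) / self.pp.Cfb0,
                self.pp.n_hill)

    def darcy_force(self, Cfb: np.ndarray, u_elem: np.ndarray) -> np.ndarray:
        """Per-element porous force density F = -pi*phi(Cfb/Cfb0)*u (N/m^3)."""
        phi = hill(np.maximum(np.asarray(Cfb, float), 0.0) / self.pp.Cfb0,
                   self.pp.n_hill)
        return -(self.pp.pi_coeff * phi)[:, None] * u_elem

    # -- boundary conditions ----------------------------------------------

    def inlet_velocity(self, bc: InflowBC) -> np.ndarray:
        """Nodal velocity field holding the parabolic inlet profile.

        The profile 1-(r/R)^2 is evaluated from the inlet centroid; nodal
        values are rescaled so the discrete face-integrated flow rate equals
        the requested Q (or mean velocity x inlet area) exactly.
        """
        mesh = self.mesh
        u = np.zeros((mesh.n_nodes, 3))
        fids = mesh.boundary_faces(TAG_INLET)
        if len(fids) == 0:
            raise ValueError("mesh has no inlet faces")
        inlet_nodes = np.unique(mesh.face_nodes[fids].ravel())
        pure = inlet_nodes[mesh.node_tag[inlet_nodes] == TAG_INLET]
        area = mesh.face_area[fids].sum()
        # inward direction = average inward face normal
        nvec = -(mesh.face_normal[fids] * mesh.face_area[fids, None]).sum(axis=0)
        nvec /= np.linalg.norm(nvec)
        c = mesh.nodes[inlet_nodes].mean(axis=0)
        r = np.linalg.norm(mesh.nodes[pure] - c, axis=1)
        R = np.linalg.norm(mesh.nodes[inlet_nodes] - c, axis=1).max()
        prof = np.maximum(0.0, 1.0 - (r / max(R, 1e-300)) ** 2)
        u[pure] = prof[:, None] * nvec[None, :]
        Q_target = (bc.flow_rate if bc.flow_rate is not None
                    else bc.mean_velocity * area)
        Q_num = -self.boundary_flux(u, TAG_INLET)    # influx is negative outflux
        if Q_num <= 0:
            raise ValueError("degenerate inlet profile")
        u *= Q_target / Q_num
        return u

    def boundary_flux(self, u: np.ndarray, tag: int) -> float:
        """Outward volumetric flux through the tagged boundary (m^3/s)."""
        mesh = self.mesh
        fids = mesh.boundary_faces(tag)
        uf = u[mesh.face_nodes[fids]].mean(axis=1)
        return float(np.einsum("fi,fi,f->", uf, mesh.face_normal[fids],
                               mesh.face_area[fids]))

    # -- core operators ----------------------------------------------------

    def _convection(self, u: np.ndarray) -> np.ndarray:
        """Nodal Galerkin (lumped) convection vector int N_a rho (u.grad)u."""
        mesh = self.mesh
        ue = u[mesh.tets]                              # (Nt,4,3)
        ubar = ue.mean(axis=1)                         # (Nt,3)
        grad = np.einsum("eai,eaj->eij", self.b, ue)   # grad[i,j] = du_j/dx_i
        conv = np.einsum("ei,eij->ej", ubar, grad)     # (u.grad)u
        out = np.zeros_like(u)
        w = (self.fp.rho * mesh.volumes / 4.0)
        np.add.at(out, mesh.tets.ravel(),
                  np.repeat(conv * w[:, None], 4, axis=0).reshape(-1, 3))
        return out

    def _grad_nodal(self, p: np.ndarray) -> np.ndarray:
        """Lumped nodal gradient of a P1 scalar."""
        mesh = self.mesh
        ge = np.einsum("eai,ea->ei", self.b, p[mesh.tets])
        out = np.zeros((mesh.n_nodes, 3))
        w = mesh.volumes / 4.0
        np.add.at(out, mesh.tets.ravel(),
                  np.repeat(ge * w[:, None], 4, axis=0).reshape(-1, 3))
        return out / self.ML[:, None]

    def _weak_div(self, u: np.ndarray) -> np.ndarray:
        """int N_a div(u) dV per node (P1: elementwise-constant divergence)."""
        mesh = self.mesh
        div = np.einsum("eai,eai->e", self.b, u[mesh.tets])
        out = np.zeros(mesh.n_nodes)
        np.add.at(out, mesh.tets.ravel(), np.repeat(div * mesh.volumes / 4, 4))
        return out

    def element_velocity(self, u: np.ndarray) -> np.ndarray:
        return u[self.mesh.tets].mean(axis=1)

    def _mu_eff(self, u: np.ndarray) -> np.ndarray:
        """Element viscosity with a cell-Reynolds artificial contribution.

        nu_art = max(0, |u| h / 2 - nu) vanishes wherever the cell Reynolds
        number is below 2 (e.g. the whole Poiseuille tube) and stabilises
        the central convection operator on coarse high-Re meshes.
        """
        ubar = np.linalg.norm(self.element_velocity(u), axis=1)
        nu = self.fp.mu / self.fp.rho
        nu_art = np.maximum(0.0, 0.5 * ubar * self.mesh.h - nu)
        return self.fp.mu + self.fp.rho * nu_art

    def _dt(self, u: np.ndarray, u_ref: float) -> float:
        ubar = np.linalg.norm(self.element_velocity(u), axis=1)
        umax = max(float(ubar.max(initial=0.0)), u_ref, 1e-30)
        return self.cfg.courant * float(self.mesh.h.min()) / umax

    # -- residual split (convergence bookkeeping) --------------------------

    def residual_split(self, u: np.ndarray, p: np.ndarray,
                       Cfb: np.ndarray | None = None):
        """(R1, R2): Navier-Stokes residual without porosity, and the porous
        contribution -(pi/rho) phi u, both as nodal accelerations (m/s^2)."""
        Kmu = self._assemble(np.full(self.mesh.n_elements, self.fp.mu))
        R1 = -(self._convection(u) + Kmu @ u) / (self.fp.rho * self.ML[:, None]) \
            - self._grad_nodal(p) / self.fp.rho
        if Cfb is not None:
            alpha = self.pp.pi_coeff * hill(
                np.maximum(np.asarray(Cfb, float), 0.0) / self.pp.Cfb0,
                self.pp.n_hill)
        else:
            alpha = self.alpha
        Ma = np.zeros(self.mesh.n_nodes)
        np.add.at(Ma, self.mesh.tets.ravel(),
                  np.repeat(alpha * self.mesh.volumes / 4, 4))
        R2 = -(Ma[:, None] * u) / (self.fp.rho * self.ML[:, None])
        return R1, R2

    # -- main loop ---------------------------------------------------------

    def _pressure_lu(self, free_p: np.ndarray, mode: str):
        if mode not in self._lu_p_cache:
            self._lu_p_cache[mode] = spla.splu(
                self._K1[free_p][:, free_p].tocsc())
        return self._lu_p_cache[mode]

    def solve(self, bc: InflowBC, u0: np.ndarray | None = None,
              p0: np.ndarray | None = None) -> FlowState:
        mesh, cfg, fp = self.mesh, self.cfg, self.fp
        fixed = self._noslip.copy()
        p_init = np.zeros(mesh.n_nodes)
        if bc.pressure_drop is None:
            mode = "vel"
            u_bc = self.inlet_velocity(bc)
            fixed[mesh.node_tag == TAG_INLET] = True
            free_p = np.flatnonzero(mesh.node_tag != TAG_OUTLET)
            u_ref = float(np.linalg.norm(u_bc, axis=1).max())
        else:
            mode = "pres"
            u_bc = np.zeros((mesh.n_nodes, 3))
            free_p = np.flatnonzero((mesh.node_tag != TAG_OUTLET)
                                    & (mesh.node_tag != TAG_INLET))
            p_init[mesh.node_tag == TAG_INLET] = bc.pressure_drop
            # crude Poiseuille scale for the initial advective timestep
            ext = max(float(np.ptp(mesh.nodes[:, 0])), 1e-12)
            fids = mesh.boundary_faces(TAG_INLET)
            R_in = np.sqrt(mesh.face_area[fids].sum() / np.pi)
            u_ref = abs(bc.pressure_drop) * R_in ** 2 / (8 * fp.mu * ext)
        if u_ref == 0.0:
            tau = shear_stress(np.zeros((mesh.n_nodes, 3)), mesh, fp)
            return FlowState(np.zeros((mesh.n_nodes, 3)), p_init, tau,
                             [0.0], True)
        lu_p = self._pressure_lu(free_p, mode)
        fr = np.flatnonzero(~fixed)
        self.fixed_u = fixed
        u = u_bc.copy() if u0 is None else u0.copy()
        u[fixed] = u_bc[fixed]
        p = p_init if p0 is None else p0.copy()
        p[self.out_nodes] = 0.0

        history = []
        lu_m = None
        dt = mu_eff = None
        for it in range(cfg.max_iters):
            if it % cfg.refresh_every == 0:
                dt_new = self._dt(u, u_ref)
                mu_new = self._mu_eff(u)
                if (lu_m is None or abs(dt_new - dt) > 0.2 * dt
                        or np.max(np.abs(mu_new - mu_eff)) > 0.2 * np.max(mu_eff)):
                    dt, mu_eff = dt_new, mu_new
                    Kmu = self._assemble(mu_eff)
                    Ma = np.zeros(mesh.n_nodes)
                    np.add.at(Ma, mesh.tets.ravel(),
                              np.repeat(self.alpha * mesh.volumes / 4, 4))
                    A = Kmu + sp.diags(fp.rho / dt * self.ML + Ma)
                    lu_m = spla.splu(A[fr][:, fr].tocsc())
                    self._Kmu, self._Ma = Kmu, Ma
            # predictor: A (u* - u^n) = -rho u.grad u - grad p - Kmu u - Ma u
            rhs = (-self._convection(u) - self._grad_nodal(p) * self.ML[:, None]
                   - self._Kmu @ u - self._Ma[:, None] * u)
            du = np.zeros_like(u)
            for k in range(3):
                du[fr, k] = lu_m.solve(rhs[fr, k])
            ustar = u + du
            # pressure correction: K dp = -(rho/dt) int N div u*
            rhs_p = -(fp.rho / dt) * self._weak_div(ustar)
            dp = np.zeros(mesh.n_nodes)
            dp[free_p] = lu_p.solve(rhs_p[free_p])
            # velocity correction + BCs
            unew = ustar - (dt / fp.rho) * self._grad_nodal(dp)
            unew[fixed] = u_bc[fixed]
            p = p + dp
            res = float(np.max(np.abs(unew - u)))
            history.append(res)
            u = unew
            if res < cfg.eps1:
                tau = shear_stress(u, mesh, fp)
                return FlowState(u, p, tau, history, True)
        if cfg.strict:
            raise FlowNotConverged(
                f"flow not converged in {cfg.max_iters} iterations "
                f"(last residual {history[-1]:.3e})", history)
        tau = shear_stress(u, mesh, fp)
        return FlowState(u, p, tau, history, False)


# --------------------------------------------------------------------------
# module-level operations
# --------------------------------------------------------------------------

def darcy_force(Cfb, u_elem, pp: PorosityParams):
    """F = -pi * phi(Cfb/Cfb0) * u per element (N/m^3)."""
    phi = hill(np.maximum(np.asarray(Cfb, float), 0.0) / pp.Cfb0, pp.n_hill)
    u_elem = np.asarray(u_elem, dtype=float)
    return -np.atleast_1d(phi)[:, None] * pp.pi_coeff * np.atleast_2d(u_elem)


def solve_steady(mesh: TetMesh, ib: ImmersedBoundary | None,
                 Cfb: np.ndarray | None, bc: InflowBC,
                 fp: FluidProperties, pp: PorosityParams,
                 cfg: FlowSolverConfig) -> FlowState:
    """One-shot steady solve (see FlowSolver for the reusable interface)."""
    solver = FlowSolver(mesh, ib, fp, pp, cfg)
    solver.set_porosity(Cfb)
    return solver.solve(bc)


def shear_stress(u: np.ndarray, mesh: TetMesh, fp: FluidProperties) -> np.ndarray:
    """Per-element shear-stress magnitude tau = mu * sqrt(2 e_ij e_ij) (Pa)."""
    b = _p1_gradients(mesh)
    grad = np.einsum("eai,eaj->eij", b, u[mesh.tets])   # du_j/dx_i
    e = 0.5 * (grad + np.transpose(grad, (0, 2, 1)))
    gdot = np.sqrt(2.0 * np.einsum("eij,eij->e", e, e))
    return fp.mu * gdot


def flow_residual_split(state: FlowState, mesh: TetMesh, fp: FluidProperties,
                        pp: PorosityParams, Cfb: np.ndarray | None):
    """(R1, R2) nodal residual split used by the coupling driver."""
    solver = FlowSolver.__new__(FlowSolver)
    # lightweight: rebuild only what residual_split needs
    solver.mesh, solver.fp, solver.pp = mesh, fp, pp
    solver.b = _p1_gradients(mesh)
    V = mesh.volumes
    solver.ke = np.einsum("eai,ebi->eab", solver.b, solver.b) * V[:, None, None]
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    solver._krc = (rows, cols)
    solver.ML = np.zeros(mesh.n_nodes)
    np.add.at(solver.ML, mesh.tets.ravel(), np.repeat(V / 4, 4))
    solver.alpha = np.zeros(mesh.n_elements)
    return solver.residual_split(state.u, state.p, Cfb)
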