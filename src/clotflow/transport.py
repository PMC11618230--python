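"""Cell-centred finite-volume transport of the six coagulation species.

Concentrations are piecewise constant per tetrahedron.  Convective fluxes
use first-order upwinding by default, or an optional TVD (MUSCL/minmod)
variable extrapolation; diffusive fluxes are central.  A divergence source
C_k*Q_k compensates for the small residual non-solenoidality of the frozen
finite-element velocity field.  The bounded species (Fb) carries no
convective or diffusive fluxes; its adhesion reaction sees a neighbour
average of bounded fibrin over a fibre-length radius, which is the only
mechanism by which attached fibrin spreads.

Because the flow is frozen between coupled steps, the upwind element of
every face is fixed for a whole transport phase; faces are compressed into
interior/inlet/outlet lists with precomputed upwind indices, and a whole
Runge-Kutta step (fluxes, divergence correction, reactions, clipping) runs
as one numba call on element-major (n_elements, 6) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .mesh import TetMesh, ImmersedBoundary, TAG_INLET, TAG_OUTLET, TAG_WALL
from .reaction import ReactionParams, hill, wire_proximity_switch, IFB

N_SPECIES = 6
N_TRANSPORTED = 5            # all but bounded fibrin


@dataclass
class SpeciesField:
    """Per-element concentrations (µM) plus per-species constants."""

    C: np.ndarray                            # (6, Nt)
    D: np.ndarray = field(default_factory=lambda: np.full(6, 5e-11))
    inlet_values: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self):
        self.C = np.ascontiguousarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.inlet_values = np.asarray(self.inlet_values, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != N_SPECIES:
            raise ValueError("C must have shape (6, n_elements)")
        if self.inlet_values[IFB] != 0.0:
            raise ValueError("bounded fibrin cannot enter through the inlet")

    @classmethod
    def zeros(cls, n_elements: int, **kw) -> "SpeciesField":
        return cls(C=np.zeros((N_SPECIES, n_elements)), **kw)


@dataclass
class TransportConfig:
    courant: float = 0.8
    scheme: str = "upwind1"                  # or "tvd"
    rk_stages: int = 2
    fiber_length: float = 40e-6              # neighbour-average radius (m)
    dt_max: float = 0.5                      # cap when no constraint binds (s)
    freeze_flow: bool = True

    def __post_init__(self):
        if not (0 < self.courant < 1):
            raise ValueError("courant must lie in (0, 1)")
        if self.scheme not in ("upwind1", "tvd"):
            raise ValueError("scheme must be 'upwind1' or 'tvd'")


# --------------------------------------------------------------------------
# numba kernels (element-major layout: C[k, i])
# --------------------------------------------------------------------------

@njit(cache=True)
def _neighbor_average(x, indptr, indices, out):
    for k in range(x.shape[0]):
        s = 0.0
        lo, hi = indptr[k], indptr[k + 1]
        for j in range(lo, hi):
            s += x[indices[j]]
        out[k] = s / (hi - lo)


@njit(cache=True)
def _gradients(C, k1, k2, nvecA, bk1, bnvecA, vol, grad):
    """Green-Gauss gradients of the transported species."""
    grad[:] = 0.0
    for j in range(k1.shape[0]):
        a, b = k1[j], k2[j]
        for i in range(N_TRANSPORTED):
            cf = 0.5 * (C[a, i] + C[b, i])
            for d in range(3):
                grad[a, i, d] += cf * nvecA[j, d]
                grad[b, i, d] -= cf * nvecA[j, d]
    for j in range(bk1.shape[0]):
        a = bk1[j]
        for i in range(N_TRANSPORTED):
            for d in range(3):
                grad[a, i, d] += C[a, i] * bnvecA[j, d]
    for k in range(vol.shape[0]):
        vi = 1.0 / vol[k]
        for i in range(N_TRANSPORTED):
            for d in range(3):
                grad[k, i, d] *= vi


@njit(cache=True)
def _rhs(C, out, use_tvd, grad, cent,
         k1, k2, up, dn, q, dAds,
         in_k1, q_in, inlet_values, out_k1, q_out,
         V, Qk, w, phi_tau, avg, D,
         Kwt, Kat, Kth, Km, Kss, Kwa, Kb):
    """dC/dt (µM/s), all species, element-major."""
    out[:] = 0.0
    # interior faces: convection (upwind or MUSCL/minmod) + central diffusion
    for j in range(q.shape[0]):
        a, b, u, d_ = k1[j], k2[j], up[j], dn[j]
        qq = q[j]
        if use_tvd:
            dx = cent[d_, 0] - cent[u, 0]
            dy = cent[d_, 1] - cent[u, 1]
            dz = cent[d_, 2] - cent[u, 2]
        for i in range(N_TRANSPORTED):
            cu = C[u, i]
            if use_tvd:
                dC = C[d_, i] - cu
                if dC != 0.0:
                    gd = (grad[u, i, 0] * dx + grad[u, i, 1] * dy
                          + grad[u, i, 2] * dz)
                    r = (2.0 * gd - dC) / dC
                    psi = min(1.0, r)
                    if psi > 0.0:
                        cu += 0.5 * psi * dC
            conv = cu * qq
            diff = D[i] * dAds[j] * (C[b, i] - C[a, i])
            out[a, i] += -conv + diff
            out[b, i] += conv - diff
    # inlet: convective flux only, prescribed upstream value on inflow
    for j in range(in_k1.shape[0]):
        a = in_k1[j]
        qq = q_in[j]
        for i in range(N_TRANSPORTED):
            cu = C[a, i] if qq > 0 else inlet_values[i]
            out[a, i] -= cu * qq
    # outlet: convective flux with the interior upstream concentration
    for j in range(out_k1.shape[0]):
        a = out_k1[j]
        qq = q_out[j]
        for i in range(N_TRANSPORTED):
            out[a, i] -= C[a, i] * qq
    # volume scaling, divergence correction, reactions
    for k in range(C.shape[0]):
        vi = 1.0 / V[k]
        corr = Qk[k] * vi
        for i in range(N_TRANSPORTED):
            out[k, i] = out[k, i] * vi + C[k, i] * corr
        out[k, 5] = 0.0
        prod_th = Kwt * w[k] * C[k, 0]
        inhib = Kat * C[k, 1] * C[k, 2]
        th_path = Kth * C[k, 2] * C[k, 3] / (Km + C[k, 3])
        ss_path = Kss * phi_tau[k] * C[k, 3]
        adhere = (Kwa * w[k] + Kb * avg[k]) * C[k, 4]
        out[k, 0] += -prod_th
        out[k, 1] += -inhib
        out[k, 2] += prod_th - inhib
        out[k, 3] += -th_path - ss_path
        out[k, 4] += th_path + ss_path - adhere
        out[k, 5] += adhere


@njit(cache=True)
def _axpy_clip(C, R, a, out, V):
    """out = max(C + a*R, 0); returns the clipped mass (µM m^3)."""
    clipped = 0.0
    for k in range(C.shape[0]):
        for i in range(N_SPECIES):
            v = C[k, i] + a * R[k, i]
            if v < 0.0:
                clipped -= v * V[k]
                v = 0.0
            out[k, i] = v
    return clipped


@njit(cache=True)
def _step_rk(C, Ck, R, grad, dt, stages, use_tvd, cent,
             k1, k2, up, dn, q, dAds, nvecA_i, bk1, bnvecA,
             in_k1, q_in, inlet_values, out_k1, q_out,
             V, Qk, w, phi_tau, avg, indptr, indices, D,
             Kwt, Kat, Kth, Km, Kss, Kwa, Kb):
    """One explicit RK step of ``stages`` stages with clipping; C updated
    in place; returns the cumulative clipped mass."""
    clipped = 0.0
    Ck[:] = C
    # the neighbour average feeds only the slow Kb adhesion term; evaluating
    # it once per step (not per stage) leaves the scheme conservative and
    # halves the gather traffic
    _neighbor_average(np.ascontiguousarray(C[:, 5]), indptr, indices, avg)
    for s in range(stages, 0, -1):
        if use_tvd:
            _gradients(Ck, k1, k2, nvecA_i, bk1, bnvecA, V, grad)
        _rhs(Ck, R, use_tvd, grad, cent, k1, k2, up, dn, q, dAds,
             in_k1, q_in, inlet_values, out_k1, q_out,
             V, Qk, w, phi_tau, avg, D, Kwt, Kat, Kth, Km, Kss, Kwa, Kb)
        clipped += _axpy_clip(C, R, dt / s, Ck, V)
    C[:] = Ck
    return clipped


# --------------------------------------------------------------------------

def bounded_neighbor_average(Cfb: np.ndarray, mesh: TetMesh,
                             fiber_length: float) -> np.ndarray:
    """Mean of bounded fibrin over each element and its neighbours whose
    centroids lie within ``fiber_length``; the identity map when no
    neighbour is in range (or the radius is zero)."""
    Cfb = np.ascontiguousarray(Cfb, dtype=float)
    if fiber_length <= 0:
        return Cfb.copy()
    indptr, indices = _neighbor_lists(mesh, fiber_length)
    out = np.empty_like(Cfb)
    _neighbor_average(Cfb, indptr, indices, out)
    return out


def _neighbor_lists(mesh: TetMesh, fiber_length: float):
    key = ("_nbr", float(fiber_length))
    cached = mesh.metadata.get(key)
    if cached is not None:
        return cached
    tree = cKDTree(mesh.centroids)
    lists = tree.query_ball_point(mesh.centroids, r=fiber_length)
    indptr = np.zeros(mesh.n_elements + 1, dtype=np.int64)
    for k, l in enumerate(lists):
        indptr[k + 1] = indptr[k] + len(l)
    indices = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
    mesh.metadata[key] = (indptr, indices)
    return indptr, indices


class TransportSolver:
    """Finite-volume transport-reaction integrator on a frozen flow field."""

    def __init__(self, mesh: TetMesh, ib: ImmersedBoundary | None,
                 params: ReactionParams, cfg: TransportConfig):
        self.mesh, self.params, self.cfg = mesh, params, cfg
        self.ib = ib
        nt = mesh.n_elements
        # faces touching a wire interior carry no flux at all
        if ib is not None and np.isfinite(ib.node_dist).any():
            nd = ib.node_dist[mesh.face_nodes]
            self.blocked = (nd.min(axis=1) < 0)
        else:
            self.blocked = np.zeros(len(mesh.face_area), dtype=bool)
        interior = (mesh.face_elems[:, 1] >= 0) & ~self.blocked
        self._if = np.flatnonzero(interior)
        self._inf = np.flatnonzero((mesh.face_tag == TAG_INLET)
                                   & ~self.blocked)
        self._outf = np.flatnonzero((mesh.face_tag == TAG_OUTLET)
                                    & ~self.blocked)
        self.k1 = np.ascontiguousarray(mesh.face_elems[self._if, 0])
        self.k2 = np.ascontiguousarray(mesh.face_elems[self._if, 1])
        self.dAds = np.ascontiguousarray(
            mesh.face_area[self._if] / mesh.face_ds[self._if])
        self.nvecA_i = np.ascontiguousarray(
            mesh.face_normal[self._if] * mesh.face_area[self._if, None])
        self._in_k1 = np.ascontiguousarray(mesh.face_elems[self._inf, 0])
        self._out_k1 = np.ascontiguousarray(mesh.face_elems[self._outf, 0])
        self._bnd_faces = np.flatnonzero((mesh.face_elems[:, 1] < 0)
                                         & ~self.blocked)
        self._bk1 = np.ascontiguousarray(mesh.face_elems[self._bnd_faces, 0])
        self._bnvecA = np.ascontiguousarray(
            mesh.face_normal[self._bnd_faces]
            * mesh.face_area[self._bnd_faces, None])
        # static reaction switches
        r = ib.r_field if ib is not None else np.full(nt, np.inf)
        self.wire_switch = np.ascontiguousarray(wire_proximity_switch(
            r, params.r0, params.n_hill, params.literal_wire_switch))
        self.phi_tau = np.zeros(nt)
        self._nbr = None
        if cfg.fiber_length > 0:
            self._nbr = _neighbor_lists(mesh, cfg.fiber_length)
        else:
            self._nbr = (np.arange(nt + 1, dtype=np.int64),
                         np.arange(nt, dtype=np.int64))
        self.clipped_mass = 0.0
        # frozen-flow data (set_flow)
        self.q_i = np.zeros(len(self._if))
        self.up = self.k1.copy()
        self.dn = self.k2.copy()
        self.q_in = np.zeros(len(self._inf))
        self.q_out = np.zeros(len(self._outf))
        self.Qk = np.zeros(nt)
        self.u_mag = np.zeros(nt)
        # work buffers (element-major)
        self._Ct = np.zeros((nt, 6))
        self._Ck = np.zeros((nt, 6))
        self._R = np.zeros((nt, 6))
        self._avg = np.zeros(nt)
        self._grad = np.zeros((nt, N_TRANSPORTED, 3))
        self._static_dt = None

    # -- frozen flow -------------------------------------------------------

    def set_flow(self, u: np.ndarray, tau_elem: np.ndarray) -> None:
        """Freeze a nodal velocity field and element shear stresses.

        Face-normal volume fluxes are the mean of the three face-node
        velocities dotted with the face normal times the area; the element
        divergence source Q_k is accumulated from the same face fluxes, so
        the divergence correction absorbs exactly the discrete residual.
        Wire-cut and wall faces carry no flux at all.  Upwind/downwind
        element indices are fixed here for the whole phase.
        """
        mesh = self.mesh
        uf = u[mesh.face_nodes].mean(axis=1)
        flux_all = np.einsum("fi,fi->f", uf,
                             mesh.face_normal * mesh.face_area[:, None])
        flux_all[self.blocked | (mesh.face_tag == TAG_WALL)] = 0.0
        self.q_i = np.ascontiguousarray(flux_all[self._if])
        pos = self.q_i >= 0
        self.up = np.ascontiguousarray(np.where(pos, self.k1, self.k2))
        self.dn = np.ascontiguousarray(np.where(pos, self.k2, self.k1))
        self.q_in = np.ascontiguousarray(flux_all[self._inf])
        self.q_out = np.ascontiguousarray(flux_all[self._outf])
        Qk = np.zeros(mesh.n_elements)
        np.add.at(Qk, self.k1, self.q_i)
        np.add.at(Qk, self.k2, -self.q_i)
        np.add.at(Qk, self._bk1, flux_all[self._bnd_faces])
        self.Qk = Qk
        self.u_mag = np.linalg.norm(u[mesh.tets].mean(axis=1), axis=1)
        self.phi_tau = np.ascontiguousarray(
            hill(np.maximum(tau_elem, 0.0) / self.params.tau0,
                 self.params.n_hill))
        self._static_dt = None

    # -- reactions ---------------------------------------------------------

    def neighbor_average(self, Cfb: np.ndarray) -> np.ndarray:
        out = np.empty_like(Cfb)
        _neighbor_average(np.ascontiguousarray(Cfb), self._nbr[0],
                          self._nbr[1], out)
        return out

    def reaction_sources(self, C: np.ndarray) -> np.ndarray:
        """Source terms (µM/s), species-major (6, Nt); the Kb adhesion
        terms see the neighbour-averaged bounded fibrin."""
        p = self.params
        w = self.wire_switch
        avg = self.neighbor_average(C[IFB])
        prod_th = p.Kwt * w * C[0]
        inhib = p.Kat * C[1] * C[2]
        th_path = p.Kth * C[2] * C[3] / (p.Km + C[3])
        ss_path = p.Kss * self.phi_tau * C[3]
        adhere = (p.Kwa * w + p.Kb * avg) * C[4]
        return np.stack([-prod_th, -inhib, prod_th - inhib,
                         -th_path - ss_path,
                         th_path + ss_path - adhere, adhere])

    # -- right-hand side (diagnostics path) --------------------------------

    def face_fluxes(self, fields: SpeciesField, C: np.ndarray | None = None):
        """Per-face convective and diffusive fluxes (µM·m³/s) of every
        transported species over the active interior faces, positive from
        k1 to k2.  Diagnostic counterpart of the fused step kernel.
        """
        C = fields.C if C is None else C
        conv = np.empty((N_TRANSPORTED, len(self._if)))
        diff = np.empty_like(conv)
        for i in range(N_TRANSPORTED):
            conv[i] = C[i, self.up] * self.q_i
            diff[i] = fields.D[i] * self.dAds * (C[i, self.k2]
                                                 - C[i, self.k1])
        return {"faces": self._if, "k1": self.k1, "k2": self.k2,
                "convective": conv, "diffusive": diff}

    def rhs(self, fields: SpeciesField, C: np.ndarray | None = None) -> np.ndarray:
        """dC/dt (µM/s) for all species, species-major (6, Nt)."""
        p = self.params
        Ct = np.ascontiguousarray((fields.C if C is None else C).T)
        if self.cfg.scheme == "tvd":
            _gradients(Ct, self.k1, self.k2, self.nvecA_i, self._bk1,
                       self._bnvecA, self.mesh.volumes, self._grad)
        _neighbor_average(np.ascontiguousarray(Ct[:, 5]), self._nbr[0],
                          self._nbr[1], self._avg)
        out = np.zeros_like(Ct)
        _rhs(Ct, out, self.cfg.scheme == "tvd", self._grad,
             self.mesh.centroids, self.k1, self.k2, self.up, self.dn,
             self.q_i, self.dAds, self._in_k1, self.q_in,
             fields.inlet_values, self._out_k1, self.q_out,
             self.mesh.volumes, self.Qk, self.wire_switch, self.phi_tau,
             self._avg, fields.D,
             p.Kwt, p.Kat, p.Kth, p.Km, p.Kss, p.Kwa, p.Kb)
        return np.ascontiguousarray(out.T)

    # -- timestep ----------------------------------------------------------

    def stable_dt(self, fields: SpeciesField,
                  S: np.ndarray | None = None) -> float:
        """Cou * min over elements/species of the convection, diffusion,
        divergence and reaction stability bounds."""
        mesh, cfg = self.mesh, self.cfg
        if self._static_dt is None:
            h, V = mesh.h, mesh.volumes
            dt = cfg.dt_max
            with np.errstate(divide="ignore"):
                conv = np.where(self.u_mag > 0, h / self.u_mag, np.inf)
            dt = min(dt, float(conv.min()))
            Dmax = float(fields.D[:IFB].max())
            if Dmax > 0:
                dt = min(dt, float((h * h).min()) / (2 * Dmax))
            pos = self.Qk > 0
            if pos.any():
                dt = min(dt, float((V[pos] / self.Qk[pos]).min()))
            self._static_dt = dt
        dt = self._static_dt
        # only sinks constrain explicit stability (a production term cannot
        # drive its own species negative)
        if S is None:
            S = self.reaction_sources(fields.C)
        mask = (S < -1e-30) & (fields.C > 1e-12)
        if mask.any():
            dt = min(dt, float((fields.C[mask] / -S[mask]).min()))
        return cfg.courant * dt

    # -- time stepping -----------------------------------------------------

    def step(self, fields: SpeciesField, dt: float | None = None) -> float:
        """One explicit RK step (2-stage midpoint by default); returns dt."""
        if dt is None:
            dt = self.stable_dt(fields)
        p = self.params
        Ct = self._Ct
        Ct[:] = fields.C.T
        use_tvd = self.cfg.scheme == "tvd"
        clipped = _step_rk(
            Ct, self._Ck, self._R, self._grad, dt, self.cfg.rk_stages,
            use_tvd, self.mesh.centroids,
            self.k1, self.k2, self.up, self.dn, self.q_i, self.dAds,
            self.nvecA_i, self._bk1, self._bnvecA,
            self._in_k1, self.q_in, fields.inlet_values,
            self._out_k1, self.q_out,
            self.mesh.volumes, self.Qk, self.wire_switch, self.phi_tau,
            self._avg, self._nbr[0], self._nbr[1], fields.D,
            p.Kwt, p.Kat, p.Kth, p.Km, p.Kss, p.Kwa, p.Kb)
        self.clipped_mass += clipped
        if not np.all(np.isfinite(Ct)):
            bad = np.argwhere(~np.isfinite(Ct))
            raise FloatingPointError(
                f"transport blow-up: element {bad[0][0]} species {bad[0][1]}")
        fields.C[:] = Ct.T
        return dt

    def advance(self, fields: SpeciesField, t_target: float,
                callback=None, max_steps: int = 10 ** 9,
                dt_every: int = 10) -> float:
        """Advance until t accumulates to t_target; returns elapsed time.

        The stability bound is re-evaluated every ``dt_every`` steps (the
        Courant safety factor absorbs its slow drift between updates).
        """
        t = 0.0
        dt0 = None
        for k in range(max_steps):
            if t >= t_target - 1e-15:
                break
            if dt0 is None or k % dt_every == 0:
                dt0 = self.stable_dt(fields)
            dt = min(dt0, t_target - t)
            self.step(fields, dt)
            t += dt
            if callback is not None and callback(t, fields, dt0):
                break
        return t

    # -- diagnostics -------------------------------------------------------

    def global_balance(self, fields: SpeciesField) -> dict:
        """Integrated budget of d/dt sum C V against its flux/source parts."""
        C = fields.C
        V = self.mesh.volumes
        rate = (self.rhs(fields) * V[None, :]).sum(axis=1)
        S = (self.reaction_sources(C) * V[None, :]).sum(axis=1)
        corr = np.zeros(N_SPECIES)
        corr[:IFB] = (C[:IFB] * self.Qk[None, :]).sum(axis=1)
        return {"rate": rate, "reaction": S, "divergence": corr,
                "boundary": rate - S - corr}
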