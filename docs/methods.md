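# Methods

`clotflow` simulates how fibrin is produced, transported and deposited on
the braided wires of a flow-diverting (FD) stent in idealised vessel and
aneurysm geometries, and how the growing clot in turn throttles the flow.
This note records the model, the numerical choices and their rationale, and
what the desk-scale test problems do and do not demonstrate.

## Model

**Flow.** Plasma is an incompressible Newtonian fluid (ρ = 1030 kg/m³,
μ = 1.3 mPa·s by default — standard plasma values; both configurable),

∂u/∂t + u·∇u = −∇p/ρ + ν∇²u + F/ρ,  ∇·u = 0,

with a Darcy (porous) body force representing the accumulated clot:

F = −π φ(C_Fb / C_Fb0) u,

where π is an inverse permeability scale, C_Fb the concentration of
*bounded* (wire-attached) fibrin, C_Fb0 a threshold, and
φ(x) = xⁿ/(1+xⁿ) a smooth Hill step.  Fully clotted elements behave as a
low-permeability porous medium.  The shear-stress magnitude is
τ = μ√(2 e:e) with e the strain-rate tensor.

**Species.** Six advected–diffusing–reacting scalar fields (µM):
prothrombin (PT), antithrombin (AT), thrombin (Th), fibrinogen (Fg), free
fibrin (Fn) and bounded fibrin (Fb).  The reduced network is:

- Th is produced from PT near thrombogenic metal (rate K_wt, gated by a
  wire-proximity switch) and neutralised by AT (rate K_at·C_AT·C_Th);
- Fg is cleaved to Fn by Th (Michaelis form K_th·C_Th·C_Fg/(K_m+C_Fg)) and
  by supra-threshold shear stress (K_ss·φ(τ/τ0)·C_Fg) — the latter pathway
  is motivated by flow-loop experiments with fibrinogen concentrate in
  which fibrin formed with flow and not without it;
- Fn adheres to nearby wires (K_wa, wire-gated) and to already-bounded
  fibrin (K_b·C̄_Fb·C_Fn), becoming Fb.  There is no detachment, so the Fb
  inventory is non-decreasing.

Two exact identities follow and are enforced to machine precision:
S_Fg + S_Fn + S_Fb = 0 (the fibrin family is only converted) and
S_PT + S_Th = S_AT (thrombin bookkeeping).

**Wire switch orientation.** The wire gate is implemented as
1 − φ(r/r0) — ≈1 on the wire surface, →0 away from it — matching the
stated mechanism (production *stimulated by nearby wires*, adhesion *below
a distance threshold*).  A `literal_wire_switch` flag evaluates the
increasing form φ(r/r0) instead for anyone wanting the literal printed
formula.

**Saturation constant.** K_m enters as K_m + C_Fg in the denominator of
the thrombin pathway, i.e. it is treated as a fibrinogen saturation
constant, exactly as the source equations are printed.

## Numerics

**Mesh.** Structured, Kuhn-triangulated tetrahedral meshes.  The tube is a
mapped-square cross-section extruded along the axis; the sidewall model
clips a Cartesian grid against the implicit union (vessel cylinder ∪
cylindrical neck ∪ spherical sac) in a straight configuration and bends it
to the prescribed centreline curvature (the sac sits normal to the bending
plane, preserving its volume to O((size/R_c)²)).  Any conforming tet mesh
satisfying the face invariants would do; structured generation keeps the
artifact dependency-free and exactly reproducible.

**Device.** Wires are analytic polylines on the deployment cylinder — two
helix families at ±(braid angle)/2 from the device axis, so larger braid
angles give denser coverage and smaller pores — resampled into overlapping
spheres (spacing = half the wire radius).  The tube scenarios use a flat
crossed-wire screen at the midplane with the stated cell angles (90°/150°).
Mesh edges straddling a wire surface are *cut*; nodes inside wires and the
nearer endpoint of each cut edge carry no-slip.  The per-element distance
to the nearest wire surface, r, is exact (KD-tree candidate pruning +
point-to-segment distances).

**Local refinement** splits an edge at its midpoint in *every* incident
tetrahedron simultaneously, which is conforming by construction; one level
performs three longest-edge sweeps over wire-cut elements, so their volume
drops by ≥8× and h halves.  It is off by default at desk scale (see
*resolution consistency* below).

**Flow solver.** P1 finite elements, fractional-step pseudo-time marching
to steady state: implicit viscous+Darcy prediction (one sparse LU
factorisation reused across steps), incremental pressure-Poisson projection
(factorised once per mesh), explicit convection with a cell-Reynolds
artificial viscosity ν_art = max(0, |u|h/2 − ν) that vanishes on resolved
meshes (the whole Poiseuille tube) and stabilises coarse high-Re runs.
Convergence: max nodal |u^{n+1}−u^n| < ε₁ (default 10⁻⁴ m/s).  Inflow is a
parabolic profile rescaled to match the requested flow rate exactly on the
discrete inlet; the outlet is traction-free (p = 0); a pressure-driven mode
(fixed inlet–outlet pressure drop, free inlet velocity) exists because a
prescribed-flow-rate inlet cannot, by continuity, show the flow *reduction*
of a fully clotted lumen.

**Transport solver.** Cell-centred finite volumes on the frozen flow.
Convection: first-order upwind (default) or MUSCL/minmod TVD extrapolation;
diffusion: central with adjacent-centroid spacing; a divergence source
C_k Q_k absorbs the (small) non-solenoidality of the interpolated face
velocities.  Wall and wire-cut faces carry no flux at all — in both the
species fluxes *and* Q_k; an inconsistency there acts as a spurious
exponential source.  Inlets impose convective flux with the prescribed
upstream concentration (no diffusive flux); outlets convect the interior
value.  Explicit RK2 (midpoint) with negative-concentration clipping (the
clipped mass is tracked and is ~10⁻¹⁶ of inventory in practice).  The
timestep takes the minimum of the convection (h/|u|), diffusion (h²/2D),
divergence (V/Q) and reaction bounds times a Courant factor (0.8).  The
reaction bound uses C_i/|S_i| over *sinks only*: a production term cannot
drive its own species negative, and including productions collapses the
timestep by ~10 orders of magnitude when species grow from zero.

**Bounded fibrin** has no convective or diffusive fluxes.  Its adhesion
kinetics see the *neighbour average* of C_Fb over elements whose centroids
lie within a fibre length (default 40 µm, floored at ~1.5 local cells),
which is the only mechanism by which the attached clot front propagates.
The average is evaluated once per RK step (not per stage); it feeds only
the slow K_b coupling term and this halves the gather traffic.

**Coupling.** Quasi-steady staggering: solve flow to ε₁, freeze (u, τ),
advance transport, and re-solve flow (warm-started) once the porosity-force
change would let the frozen-flow residual grow by ε₂: the trigger fires
when Δt·δF ≥ ε₂ with δF = max_k |π Δφ_k u_k| / ρ (max norm — the most
conservative choice, re-solving earliest; the norm is a package choice).
Defaults ε₁ = 10⁻⁴, ε₂ = 10⁻³.  Between re-solves the residual therefore
never grows beyond ε₂; after each re-solve it is below ε₁.  A
`min_phase_time` runtime control can suppress trigger checks early in a
phase for very coarse demonstration runs (the ε₂ guarantee holds only when
it is zero, which is the default).  All state checkpoints to HDF5 and
restarts are bit-identical (there is no randomness anywhere in the
pipeline).

## Parameters

The kinetic constants of this class of reduced models are not identifiable
from first principles; published values are themselves tuned to reproduce
in-vitro deposition patterns.  The defaults here were chosen once, with two
constraints: (i) preserve the qualitative ordering of the pathways
(wire-stimulated thrombin production slower than cleavage; adhesion fast
once fibrin exists; inhibition weak on the run timescale), and (ii) let the
full occlusion sequence — thrombin build-up at wires, fibrin production,
adhesion, Darcy flow reduction — complete on O(100 s) of simulated time,
which is what single-CPU desk-scale runs (10³–10⁴ elements, transport
Δt ≈ 10⁻⁴ s) can integrate.  Real deposition takes tens of minutes; the
model is linear in this time-scaling and the trends reported by the tests
(denser braids accumulate more fibrin; accumulation starts distally;
inflow falls as coverage grows) are invariant under it.

| symbol | meaning | default | units |
|---|---|---|---|
| K_wt | wire-stimulated thrombin production | 0.2 | 1/s |
| K_at | antithrombin inhibition | 0.1 | 1/(µM·s) |
| K_th | thrombin-driven fibrin production | 2.0 | 1/s |
| K_m  | fibrinogen saturation | 1.0 | µM |
| K_ss | shear-driven fibrin production | 0.05 | 1/s |
| K_wa | wire adhesion | 2.0 | 1/s |
| K_b  | fibrin–fibrin adhesion | 0.5 | 1/(µM·s) |
| τ0   | shear threshold | 1.0 | Pa |
| r0   | wire-distance threshold | wire radius (see below) | m |
| n    | Hill exponent | 4 | – |
| π    | inverse permeability | 10⁷ | kg/(m³·s) |
| C_Fb0| clot-switch threshold | 0.5 | µM |
| D_i  | protein diffusivities | 5×10⁻¹¹ | m²/s |

**Resolution consistency.** The wires (20–32 µm) are 10–100× thinner than
desk-scale elements, so two kinetic lengths are floored at the local cell
size near the wires: r0 = max(wire radius, 0.8·h_local) — a cell-centred
scheme cannot see a source narrower than one cell — and the fibre length =
max(40 µm, 1.5·h_local), so the clot front can reach neighbouring cells.
Both revert to their physical values when the mesh resolves them (e.g.
after `refine_near_wires`).  Similarly, no-slip is imposed only on mesh
entities the wires actually cut; on coarse sidewall meshes the wires cut
almost nothing and the *entire* device effect is carried by the Darcy term,
which is the dominant occlusion mechanism of the model in any case.

## What the desk-scale runs show — and what they don't

The test problems run minutes on one CPU: the Poiseuille tube at h = 20 µm
(~4×10⁴ elements), the coupled tube90/tube150 pair at h = 60 µm for 30 s
simulated, and the sidewall model at h = 0.8 mm for 20 s simulated with
2-second coupling phases.  At these sizes the tests demonstrate the
*mechanisms*: analytic flow recovery, exact conservation and monotone
transport, the residual-budget coupling contract, denser screens collecting
more fibrin, distal-first neck coverage and monotone inflow reduction.
They do not demonstrate grid-converged fields, quantitative deposition
rates (the constants are scaled, see above), wire-scale boundary layers, or
pulsatile effects (out of scope).  Aneurysm inflow is measured as
∫ max(u·n, 0) dA over the analytic neck disc, sampled on an equal-area
polar grid with piecewise-constant element velocities; its step-to-step
noise floor is set by ε₁ and the re-solve warm starts (~0.3 %), which is
the tolerance the monotonicity checks use.

## Known limitations

- No platelets, erythrocytes, or fibrin detachment (deliberately excluded
  from the model); no pulsatile mode (the stored-cycle interpolation is a
  stub interface only).
- The voxel-clipped sidewall wall is a staircase; wall shear there is
  O(h)-accurate and only used through a saturating Hill switch.
- P1/P1 projection with lumped mass is an approximate projection: discrete
  divergence is driven to the linear-solver tolerance, not to zero.
- First-order upwinding is diffusive; the TVD option reduces but does not
  eliminate smearing, and its limiter is not strictly bound-preserving on
  tetrahedra (overshoots ≤0.5 % were observed on step profiles).
- The 0-D integrator and the transport reaction update clip negative
  concentrations; the clipped mass is tracked and negligible in all runs.
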