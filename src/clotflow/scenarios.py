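"""Reconstructions of the reference experiments at desk-scale resolution.

Four scenarios are provided:

``tube90`` / ``tube150``
    A 300 µm x 3 mm straight tube perfused with plasma-like medium at a
    mean velocity of 1.5 cm/s, with a braided screen of 20 µm wires placed
    perpendicular to the flow at the midplane, with pore-cell internal
    angles of 90 and 150 degrees respectively.  Inlet concentrations are
    physiologic: C_PT = 1.4 µM, C_AT = 2.41 µM, C_Fg = 7.0 µM.

``sidewall_plasma``
    An 8 mm spherical sidewall aneurysm on a 4 mm parent vessel with 4 cm
    radius of curvature, crossed by a 48-wire, 30 µm, 90-degree braided
    flow diverter, perfused at 4 cc/s.

``sidewall_fibrinogen_only``
    The transparent (glass) variant: 5 cm curvature, a 4.75 mm x 20 mm
    device of 48 x 32 µm wires, fibrinogen concentrate only (330 mg/dl ~
    9.7 µM at 340 kDa): the thrombin pathway is disabled (Kwt = Kth = 0) so
    fibrin is produced exclusively by the shear-stress pathway.

Two kinetic length scales are tied to the mesh resolution: the wire
proximity threshold r0 is floored at a fraction of the local element size
near the wires (an immersed-boundary source must span at least one cell to
be seen by a cell-centred scheme), and the fibre-length neighbour radius is
floored at ~1.5 local cells so bounded fibrin can propagate.  Both revert
to their physical values (wire radius, 40 µm) when the mesh resolves them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .mesh import (generate_tube_mesh, generate_sidewall_aneurysm_mesh,
                   build_braided_device, build_screen_device,
                   compute_immersed_boundary, refine_near_wires, _bend_map)
from .reaction import ReactionParams
from .flow import FluidProperties, PorosityParams, FlowSolverConfig, InflowBC
from .transport import TransportConfig
from .coupling import CoupledModel, CouplingConfig

#: molecular weight used to convert fibrinogen mass concentration to molar
FIBRINOGEN_MW = 340e3        # g/mol
SCENARIO_NAMES = ("tube90", "tube150", "sidewall_plasma",
                  "sidewall_fibrinogen_only")


def _mgdl_to_uM(mg_per_dl: float, mw: float = FIBRINOGEN_MW) -> float:
    """330 mg/dl of fibrinogen ~ 9.7 µM at 340 kDa."""
    return mg_per_dl * 1e-2 / mw * 1e6          # mg/dl -> g/L -> mol/L -> µM


@dataclass
class Scenario:
    name: str
    model: CoupledModel
    coupling: CouplingConfig
    flow_cfg: FlowSolverConfig
    transport_cfg: TransportConfig


def _resolution_scales(mesh, ib, wire_radius: float,
                       fiber_length: float | None):
    """Resolution-consistent r0 and fibre length near the wires."""
    if ib is not None and len(ib.cut_edges):
        cut_tets = np.flatnonzero(np.isfinite(ib.r_field)
                                  & (ib.r_field < 2 * np.median(mesh.h)))
        h_loc = float(np.median(mesh.h[cut_tets])) if len(cut_tets) \
            else float(np.median(mesh.h))
    else:
        h_loc = float(np.median(mesh.h))
    r0 = max(wire_radius, 0.8 * h_loc)
    fl = fiber_length if fiber_length is not None else max(40e-6, 1.5 * h_loc)
    return r0, fl


def build_scenario(name: str, *, target_h: Optional[float] = None,
                   t_end: Optional[float] = None,
                   refine_levels: int = 0,
                   scheme: str = "upwind1",
                   fiber_length: Optional[float] = None,
                   reaction_overrides: dict | None = None) -> Scenario:
    """Assemble mesh, device, immersed boundary and parameters for a named
    scenario; ``target_h`` and ``t_end`` override the default resolution and
    simulated end time."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario '{name}'; "
                         f"choose from {SCENARIO_NAMES}")
    fluid = FluidProperties()
    porosity = PorosityParams()
    diffus = np.full(6, 5e-11)

    if name.startswith("tube"):
        angle = 90.0 if name == "tube90" else 150.0
        D, L = 300e-6, 3e-3
        h = target_h or 25e-6
        mesh = generate_tube_mesh(D, L, h, target_h_axial=3 * h)
        wires = build_screen_device(D / 2, 20e-6, angle, pitch=100e-6,
                                    x_center=L / 2)
        bc = InflowBC(mean_velocity=1.5e-2)
        inlet = np.array([1.4, 2.41, 0.0, 7.0, 0.0, 0.0])
        rx_kwargs = {}
        end = t_end if t_end is not None else 1200.0
    elif name == "sidewall_plasma":
        h = target_h or 0.5e-3
        mesh = generate_sidewall_aneurysm_mesh(4e-3, 8e-3, 4e-2, 4e-3, h,
                                               vessel_length=20e-3)
        Rdep = 0.93 * 2e-3
        wires = build_braided_device(48, 30e-6, 90.0, Rdep, 12e-3,
                                     x_center=10e-3)
        wires = wires.transform(lambda p: _bend_map(p, 4e-2))
        bc = InflowBC(flow_rate=4e-6)
        inlet = np.array([1.4, 2.41, 0.0, 7.0, 0.0, 0.0])
        rx_kwargs = {}
        end = t_end if t_end is not None else 600.0
    else:  # sidewall_fibrinogen_only
        h = target_h or 0.5e-3
        mesh = generate_sidewall_aneurysm_mesh(4e-3, 8e-3, 5e-2, 4e-3, h,
                                               vessel_length=20e-3)
        Rdep = min(4.75e-3 / 2, 0.93 * 2e-3)
        wires = build_braided_device(48, 32e-6, 90.0, Rdep, 20e-3,
                                     x_center=10e-3)
        wires = wires.transform(lambda p: _bend_map(p, 5e-2))
        bc = InflowBC(flow_rate=4e-6)
        cfg_uM = _mgdl_to_uM(330.0)
        inlet = np.array([0.0, 0.0, 0.0, cfg_uM, 0.0, 0.0])
        rx_kwargs = {"Kwt": 0.0, "Kth": 0.0}   # shear pathway only
        end = t_end if t_end is not None else 600.0

    ib = compute_immersed_boundary(mesh, wires)
    if refine_levels > 0:
        mesh = refine_near_wires(mesh, ib, refine_levels, wires=wires)
        ib = compute_immersed_boundary(mesh, wires)

    r0, fl = _resolution_scales(mesh, ib, wires.wire_radius, fiber_length)
    rx_kwargs.setdefault("r0", r0)
    if reaction_overrides:
        rx_kwargs.update(reaction_overrides)
    reaction = ReactionParams(**rx_kwargs)

    model = CoupledModel(mesh=mesh, ib=ib, wires=wires, reaction=reaction,
                         fluid=fluid, porosity=porosity, bc=bc,
                         inlet_values=inlet, diffusivities=diffus)
    coupling = CouplingConfig(total_time_target=end)
    flow_cfg = FlowSolverConfig(eps1=coupling.eps1)
    transport_cfg = TransportConfig(scheme=scheme, fiber_length=fl)
    return Scenario(name, model, coupling, flow_cfg, transport_cfg)


def scenario_from_config(cfg) -> Scenario:
    """Build a Scenario from a validated RunConfig (see io.RunConfig)."""
    from .io import RunConfig
    assert isinstance(cfg, RunConfig)
    if cfg.scenario:
        sc = build_scenario(cfg.scenario,
                            t_end=cfg.coupling.total_time_target,
                            scheme=cfg.transport.scheme,
                            fiber_length=cfg.transport.fiber_length)
        sc.coupling = replace(sc.coupling,
                              eps1=cfg.coupling.eps1, eps2=cfg.coupling.eps2,
                              max_coupled_steps=cfg.coupling.max_coupled_steps,
                              check_every=cfg.coupling.check_every)
        return sc
    # explicit geometry/device blocks
    g, d = cfg.geometry, cfg.device
    if g.kind == "tube":
        mesh = generate_tube_mesh(g.diameter, g.length, g.target_h,
                                  target_h_axial=g.target_h_axial)
        if d.screen:
            wires = build_screen_device(g.diameter / 2, d.wire_diameter,
                                        d.braid_angle, pitch=d.pitch,
                                        x_center=g.length / 2)
        else:
            wires = build_braided_device(d.n_wires, d.wire_diameter,
                                         d.braid_angle, 0.93 * g.diameter / 2,
                                         d.length, x_center=g.length / 2)
    elif g.kind == "sidewall":
        mesh = generate_sidewall_aneurysm_mesh(
            g.vessel_d, g.aneurysm_d, g.curvature_radius, g.neck_d, g.target_h)
        L = mesh.metadata["vessel_length"]
        wires = build_braided_device(d.n_wires, d.wire_diameter, d.braid_angle,
                                     0.93 * g.vessel_d / 2, d.length,
                                     x_center=L / 2)
        if g.curvature_radius and np.isfinite(g.curvature_radius):
            wires = wires.transform(
                lambda p: _bend_map(p, g.curvature_radius))
    else:
        raise ValueError(f"unknown geometry kind '{g.kind}'")
    ib = compute_immersed_boundary(mesh, wires)
    if d.refine_levels:
        mesh = refine_near_wires(mesh, ib, d.refine_levels, wires=wires)
        ib = compute_immersed_boundary(mesh, wires)
    r0, fl = _resolution_scales(mesh, ib, wires.wire_radius,
                                cfg.transport.fiber_length)
    rx = cfg.reaction
    reaction = ReactionParams(Kwt=rx.Kwt, Kat=rx.Kat, Kth=rx.Kth, Km=rx.Km,
                              Kss=rx.Kss, Kwa=rx.Kwa, Kb=rx.Kb, tau0=rx.tau0,
                              r0=max(rx.r0, r0), n_hill=rx.n,
                              literal_wire_switch=rx.literal_wire_switch)
    from .reaction import SPECIES
    inlet = np.array([cfg.species.inlet.get(s, 0.0) for s in SPECIES])
    diffus = np.array([cfg.species.diffusivity.get(s, 5e-11) for s in SPECIES])
    model = CoupledModel(
        mesh=mesh, ib=ib, wires=wires, reaction=reaction,
        fluid=FluidProperties(rho=cfg.fluid.rho, mu=cfg.fluid.mu),
        porosity=PorosityParams(pi_coeff=cfg.porosity.pi,
                                Cfb0=cfg.porosity.Cfb0,
                                n_hill=cfg.porosity.n),
        bc=cfg.inflow.to_bc(), inlet_values=inlet, diffusivities=diffus)
    coupling = CouplingConfig(
        eps1=cfg.coupling.eps1, eps2=cfg.coupling.eps2,
        max_coupled_steps=cfg.coupling.max_coupled_steps,
        total_time_target=cfg.coupling.total_time_target,
        check_every=cfg.coupling.check_every)
    flow_cfg = FlowSolverConfig(courant=cfg.flow.courant, eps1=cfg.flow.eps1,
                                max_iters=cfg.flow.max_iters)
    transport_cfg = TransportConfig(courant=cfg.transport.courant,
                                    scheme=cfg.transport.scheme,
                                    rk_stages=cfg.transport.rk_stages,
                                    fiber_length=fl,
                                    dt_max=cfg.transport.dt_max)
    return Scenario(cfg.scenario or g.kind, model, coupling, flow_cfg,
                    transport_cfg)
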