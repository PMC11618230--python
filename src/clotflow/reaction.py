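"""Reduced coagulation kinetics for fibrin accumulation on device wires.

The network couples six plasma species: prothrombin (PT) is converted to
thrombin (Th) at thrombogenic metallic wires; antithrombin (AT) neutralises
thrombin; thrombin and high shear stress both cleave fibrinogen (Fg) into
free fibrin (Fn); free fibrin adheres to nearby wires and to already-bound
fibrin, becoming bounded fibrin (Fb).  All switching (wire proximity, shear
threshold, clot density) is done with a smooth Hill step function.

Concentrations are expressed in µM throughout; lengths, times and stresses
are SI (m, s, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical species ordering used by every field array in the package
SPECIES = ("PT", "AT", "Th", "Fg", "Fn", "Fb")
IPT, IAT, ITH, IFG, IFN, IFB = range(6)


@dataclass
class ReactionParams:
    """Rate constants and thresholds of the reduced coagulation network.

    The published model does not fix numeric values (they were tuned against
    in-vitro experiments); the defaults below are order-of-magnitude values
    consistent with the cited literature and can all be overridden from the
    parameter file.

    Attributes
    ----------
    Kwt : float
        Wire-stimulated thrombin production rate (1/s).
    Kat : float
        Antithrombin inhibition rate (1/(µM·s)).
    Kth : float
        Thrombin-stimulated fibrin production rate (1/s).
    Km : float
        Michaelis-type fibrinogen saturation constant (µM); appears as
        Km + C_Fg in the denominator of the thrombin pathway.
    Kss : float
        Shear-stimulated fibrin production rate (1/s).
    Kwa : float
        Wire-adhesion rate of free fibrin (1/s).
    Kb : float
        Fibrin–fibrin adhesion rate (1/(µM·s)).
    tau0 : float
        Shear-stress threshold (Pa).
    r0 : float
        Wire-distance threshold (m); of the order of the wire radius.
    n_hill : float
        Hill exponent controlling switch steepness (≥ 1).
    literal_wire_switch : bool
        If True, use the literal printed form φ(r/r0) for the wire switch
        (increasing with distance); the default uses 1 − φ(r/r0), which is
        ≈1 on the wire, matching the stated physical intent.
    """

    Kwt: float = 0.2
    Kat: float = 0.1
    Kth: float = 2.0
    Km: float = 1.0
    Kss: float = 0.05
    Kwa: float = 2.0
    Kb: float = 0.5
    tau0: float = 1.0
    r0: float = 15e-6
    n_hill: float = 4.0
    literal_wire_switch: bool = False

    def __post_init__(self) -> None:
        for name in ("Kwt", "Kat", "Kth", "Kss", "Kwa", "Kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        for name in ("Km", "tau0", "r0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")


@dataclass
class SpeciesState:
    """Well-mixed concentrations (µM) indexed (PT, AT, Th, Fg, Fn, Fb)."""

    C: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (6,):
            raise ValueError("SpeciesState.C must be a 6-vector")
        if np.any(self.C < 0):
            raise ValueError("concentrations must be non-negative")


def hill(x, n):
    """Smooth Hill step φ(x) = xⁿ/(1+xⁿ), defined for x ≥ 0.

    Strictly increasing, φ(0)=0, φ(1)=1/2, φ→1 as x→∞.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill() requires x >= 0")
    # evaluate in a form safe for large x
    xn = np.power(x, n)
    with np.errstate(over="ignore"):
        out = np.where(np.isfinite(xn), xn / (1.0 + xn), 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def wire_proximity_switch(r, r0, n, literal: bool = False):
    """Switch that is ≈1 on a wire surface and →0 far from it.

    ``r`` is the distance to the nearest wire surface (m).  The default
    implements 1 − φ(r/r0); ``literal=True`` evaluates the increasing form
    φ(r/r0) instead.
    """
    r = np.asarray(r, dtype=float)
    # +inf sentinel (no wires) maps to switch 0 (or 1 in literal mode)
    phi = hill(np.where(np.isfinite(r), r, 1e30) / r0, n)
    return phi if literal else 1.0 - phi


def source_terms(s, tau, r, Cfb_avg, p: ReactionParams):
    """Reaction source vector (S_PT, S_AT, S_Th, S_Fg, S_Fn, S_Fb) in µM/s.

    ``Cfb_avg`` is the neighbour-averaged bounded-fibrin concentration,
    which replaces the local value wherever it multiplies the fibrin–fibrin
    adhesion rate Kb.  Identities by construction:
    S_Fg + S_Fn + S_Fb = 0 and S_PT + S_Th = S_AT.
    """
    C = s.C if isinstance(s, SpeciesState) else np.asarray(s, dtype=float)
    w = wire_proximity_switch(r, p.r0, p.n_hill, p.literal_wire_switch)
    phi_tau = hill(np.asarray(tau, dtype=float) / p.tau0, p.n_hill)

    prod_th = p.Kwt * w * C[IPT]
    inhib = p.Kat * C[IAT] * C[ITH]
    th_path = p.Kth * C[ITH] * C[IFG] / (p.Km + C[IFG])
    ss_path = p.Kss * phi_tau * C[IFG]
    adhere_wire = p.Kwa * w * C[IFN]
    adhere_fb = p.Kb * Cfb_avg * C[IFN]

    return np.array([
        -prod_th,                                  # S_PT
        -inhib,                                    # S_AT
        prod_th - inhib,                           # S_Th
        -th_path - ss_path,                        # S_Fg
        th_path + ss_path - adhere_wire - adhere_fb,  # S_Fn
        adhere_wire + adhere_fb,                   # S_Fb
    ])


def integrate_batch(s0, tau, r, p: ReactionParams, t_end, dt,
                    clip_negative: bool = True):
    """0-D (well-mixed) explicit RK2 integration of dC/dt = S(C).

    Used as a transport-free oracle for the source terms: the shear stress
    ``tau`` and wire distance ``r`` are held constant, and the bounded-fibrin
    neighbour average degenerates to the local value.  Returns
    ``(times, states, clipped_mass)`` where ``states`` has one row per output
    time and ``clipped_mass`` is the cumulative concentration removed by the
    negative-concentration clipping policy.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    C = (s0.C if isinstance(s0, SpeciesState) else np.asarray(s0, float)).copy()
    nsteps = int(np.ceil(t_end / dt - 1e-12))
    times = np.empty(nsteps + 1)
    states = np.empty((nsteps + 1, 6))
    times[0], states[0] = 0.0, C
    clipped = 0.0
    t = 0.0
    for k in range(nsteps):
        h = min(dt, t_end - t)
        k1 = source_terms(C, tau, r, C[IFB], p)
        mid = C + 0.5 * h * k1
        if clip_negative:
            neg = mid < 0
            clipped += -mid[neg].sum()
            mid[neg] = 0.0
        k2 = source_terms(mid, tau, r, mid[IFB], p)
        C = C + h * k2
        if clip_negative:
            neg = C < 0
            clipped += -C[neg].sum()
            C[neg] = 0.0
        t += h
        times[k + 1], states[k + 1] = t, C
    return times, states, clipped
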