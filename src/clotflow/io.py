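"""File formats and configuration plumbing.

VTK XML writers (VTU for meshes + fields, VTP for wire polylines) are
implemented directly in the ASCII XML dialect so results open in any VTK
tool; a matching minimal reader supports round-trip tests.  STL surfaces
are read through trimesh.  Run state is checkpointed to HDF5.  The run
configuration is a strict pydantic schema: unknown keys are rejected with
their location.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .mesh import TetMesh, WireSet


# --------------------------------------------------------------------------
# VTU / VTP
# --------------------------------------------------------------------------

def _ascii(a: np.ndarray) -> str:
    return " ".join(repr(x) if isinstance(x, float) else str(x)
                    for x in np.asarray(a).ravel().tolist())


def write_vtu(mesh: TetMesh, fields: dict | None, path) -> None:
    """Write mesh + fields as XML VTU (ASCII).

    ``fields`` maps names to arrays: per-node arrays (Nn,) or (Nn,3) become
    point data, per-element arrays (Nt,) or (Nt,3) cell data.  Float data is
    written with full repr precision so round trips preserve values.
    """
    fields = fields or {}
    nn, nt = mesh.n_nodes, mesh.n_elements
    pdata, cdata = [], []
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape[0] == nn and nn != nt:
            pdata.append((name, arr))
        elif arr.shape[0] == nt:
            cdata.append((name, arr))
        elif arr.shape[0] == nn:
            pdata.append((name, arr))
        else:
            raise ValueError(f"field '{name}' matches neither nodes nor cells")

    def da(name, arr, ncomp):
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
                f"{_ascii(arr.astype(float))}</DataArray>")

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{nn}" NumberOfCells="{nt}">',
             "<Points>", da("Points", mesh.nodes, 3), "</Points>",
             "<Cells>",
             f'<DataArray type="Int64" Name="connectivity" format="ascii">'
             f"{_ascii(mesh.tets)}</DataArray>",
             f'<DataArray type="Int64" Name="offsets" format="ascii">'
             f"{_ascii(4 * np.arange(1, nt + 1))}</DataArray>",
             f'<DataArray type="UInt8" Name="types" format="ascii">'
             f"{_ascii(np.full(nt, 10, dtype=np.uint8))}</DataArray>",
             "</Cells>"]
    parts.append("<PointData>")
    for name, arr in pdata:
        parts.append(da(name, arr, arr.shape[1] if arr.ndim > 1 else 1))
    parts.append("</PointData><CellData>")
    for name, arr in cdata:
        parts.append(da(name, arr, arr.shape[1] if arr.ndim > 1 else 1))
    parts.append("</CellData></Piece></UnstructuredGrid></VTKFile>")
    Path(path).write_text("\n".join(parts))


def read_vtu(path):
    """Minimal VTU (ASCII) reader: returns (nodes, tets, point_data, cell_data)."""
    root = ElementTree.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    nn = int(piece.get("NumberOfPoints"))
    nt = int(piece.get("NumberOfCells"))

    def parse(el, dtype=float):
        return np.fromstring(el.text, sep=" ", dtype=dtype)

    nodes = parse(piece.find("./Points/DataArray")).reshape(nn, 3)
    conn = None
    for el in piece.findall("./Cells/DataArray"):
        if el.get("Name") == "connectivity":
            conn = parse(el, dtype=float).astype(np.int64).reshape(nt, 4)
    pdata, cdata = {}, {}
    for section, out, count in (("PointData", pdata, nn),
                                ("CellData", cdata, nt)):
        sec = piece.find(f"./{section}")
        if sec is None:
            continue
        for el in sec.findall("DataArray"):
            arr = parse(el)
            ncomp = int(el.get("NumberOfComponents", "1"))
            if ncomp > 1:
                arr = arr.reshape(count, ncomp)
            out[el.get("Name")] = arr
    return nodes, conn, pdata, cdata


def write_vtp(wires: WireSet, path) -> None:
    """Write wire polylines as XML VTP for inspection."""
    pts = (np.concatenate([np.asarray(w) for w in wires.wires])
           if wires.wires else np.zeros((0, 3)))
    offsets, conn, start = [], [], 0
    for w in wires.wires:
        n = len(w)
        conn.extend(range(start, start + n))
        start += n
        offsets.append(start)
    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="PolyData" version="0.1" '
             'byte_order="LittleEndian">',
             "<PolyData>",
             f'<Piece NumberOfPoints="{len(pts)}" '
             f'NumberOfLines="{len(wires.wires)}">',
             "<Points>",
             f'<DataArray type="Float64" NumberOfComponents="3" '
             f'format="ascii">{_ascii(pts)}</DataArray>',
             "</Points><Lines>",
             f'<DataArray type="Int64" Name="connectivity" format="ascii">'
             f"{_ascii(np.asarray(conn))}</DataArray>",
             f'<DataArray type="Int64" Name="offsets" format="ascii">'
             f"{_ascii(np.asarray(offsets))}</DataArray>",
             "</Lines></Piece></PolyData></VTKFile>"]
    Path(path).write_text("\n".join(parts))


# --------------------------------------------------------------------------
# STL
# --------------------------------------------------------------------------

class STLError(ValueError):
    pass


def read_stl(path):
    """Read an STL surface (binary or ASCII) and report watertightness.

    Returns a dict with vertices, faces, total area, ``watertight`` flag and
    the number of open (boundary) edges.  Truncated binary files raise
    STLError with the offending byte offset.
    """
    import trimesh
    p = Path(path)
    raw = p.read_bytes()
    if len(raw) < 15:
        raise STLError(f"{p}: not an STL file (only {len(raw)} bytes)")
    if not raw.lstrip()[:5].lower() == b"solid":
        # binary: 80-byte header + uint32 count + 50 bytes per facet
        if len(raw) < 84:
            raise STLError(f"{p}: truncated binary STL at byte {len(raw)} "
                           "(header incomplete)")
        (n,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * n
        if len(raw) < expected:
            raise STLError(f"{p}: truncated binary STL at byte {len(raw)} "
                           f"(expected {expected})")
    try:
        # STL duplicates vertices per facet: merge them so watertightness
        # and open-edge counts refer to the actual surface topology
        m = trimesh.load(str(p), file_type="stl", force="mesh", process=True)
    except Exception as exc:                       # malformed ASCII etc.
        raise STLError(f"{p}: cannot parse STL: {exc}") from exc
    if m.faces.shape[0] == 0:
        raise STLError(f"{p}: STL contains no facets")
    edges = np.sort(m.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    open_edges = int(np.sum(counts == 1))
    return {"vertices": np.asarray(m.vertices), "faces": np.asarray(m.faces),
            "area": float(m.area), "watertight": bool(m.is_watertight),
            "open_edges": open_edges}


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, state) -> None:
    """Persist a RunState (fields + bookkeeping) to HDF5."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=state.flow.u)
        f.create_dataset("p", data=state.flow.p)
        f.create_dataset("tau", data=state.flow.tau_elem)
        f.create_dataset("C", data=state.fields.C)
        f.create_dataset("D", data=state.fields.D)
        f.create_dataset("inlet_values", data=state.fields.inlet_values)
        f.create_dataset("Cfb_ref", data=state.Cfb_ref)
        f.attrs["global_time"] = state.global_time
        f.attrs["coupled_step"] = state.coupled_step
        f.attrs["n_flow_solves"] = state.n_flow_solves
        f.attrs["metrics"] = json.dumps(state.metrics)


def load_checkpoint(path, model=None):
    """Restore a RunState saved by :func:`save_checkpoint`."""
    import h5py
    from .flow import FlowState
    from .transport import SpeciesField
    from .coupling import RunState
    with h5py.File(path, "r") as f:
        flow = FlowState(u=f["u"][...], p=f["p"][...], tau_elem=f["tau"][...])
        fields = SpeciesField(C=f["C"][...], D=f["D"][...],
                              inlet_values=f["inlet_values"][...])
        state = RunState(
            global_time=float(f.attrs["global_time"]),
            coupled_step=int(f.attrs["coupled_step"]),
            flow=flow, fields=fields, Cfb_ref=f["Cfb_ref"][...],
            metrics=json.loads(f.attrs["metrics"]))
        state.n_flow_solves = int(f.attrs["n_flow_solves"])
    return state


def write_metrics_csv(metrics: list, path) -> None:
    if not metrics:
        Path(path).write_text("")
        return
    keys = list(metrics[0].keys())
    lines = [",".join(keys)]
    for row in metrics:
        lines.append(",".join(repr(row[k]) if isinstance(row[k], float)
                              else str(row[k]) for k in keys))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# configuration schema
# --------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReactionConfig(_Strict):
    """Rate constants keyed by their conventional symbols (µM / Pa / m / s)."""
    Kwt: float = 0.2
    Kat: float = 0.1
    Kth: float = 2.0
    Km: float = 1.0
    Kss: float = 0.05
    Kwa: float = 2.0
    Kb: float = 0.5
    tau0: float = 1.0
    r0: float = 15e-6
    n: float = 4.0
    literal_wire_switch: bool = False


class FluidConfig(_Strict):
    rho: float = 1030.0
    mu: float = 1.3e-3


class PorosityConfig(_Strict):
    pi: float = 1e7
    Cfb0: float = 0.5
    n: float = 4.0


class SpeciesConfig(_Strict):
    """Per-species diffusivity (m^2/s) and inlet concentration (µM)."""
    diffusivity: dict[str, float] = Field(default_factory=dict)
    inlet: dict[str, float] = Field(default_factory=dict)


class GeometryConfig(_Strict):
    kind: str = "tube"                      # tube | sidewall
    diameter: float = 300e-6
    length: float = 3e-3
    vessel_d: float = 4e-3
    aneurysm_d: float = 8e-3
    neck_d: float = 4e-3
    curvature_radius: Optional[float] = 4e-2
    target_h: float = 30e-6
    target_h_axial: Optional[float] = None


class DeviceConfig(_Strict):
    n_wires: int = 48
    wire_diameter: float = 30e-6
    braid_angle: float = 90.0
    length: float = 12e-3
    screen: bool = False
    pitch: float = 100e-6
    refine_levels: int = 0


class InflowConfig(_Strict):
    mean_velocity: Optional[float] = None       # m/s
    mean_velocity_cms: Optional[float] = None   # cm/s convenience
    flow_rate: Optional[float] = None           # m^3/s
    pressure_drop: Optional[float] = None       # Pa

    def to_bc(self):
        from .flow import InflowBC
        if self.mean_velocity_cms is not None:
            return InflowBC(mean_velocity=self.mean_velocity_cms * 1e-2)
        return InflowBC(mean_velocity=self.mean_velocity,
                        flow_rate=self.flow_rate,
                        pressure_drop=self.pressure_drop)


class FlowNumericsConfig(_Strict):
    courant: float = 0.8
    eps1: float = 1e-4
    max_iters: int = 4000


class TransportNumericsConfig(_Strict):
    courant: float = 0.5
    scheme: str = "upwind1"
    rk_stages: int = 2
    fiber_length: Optional[float] = None    # None: resolution-matched default
    dt_max: float = 0.5


class CouplingNumericsConfig(_Strict):
    eps1: float = 1e-4
    eps2: float = 1e-3
    max_coupled_steps: int = 200
    total_time_target: float = 60.0
    check_every: int = 10


class OutputConfig(_Strict):
    directory: str = "out"
    vtu_every: int = 1                      # coupled steps between VTU dumps


class RunConfig(_Strict):
    scenario: Optional[str] = None
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    device: DeviceConfig = Field(default_factory=DeviceConfig)
    reaction: ReactionConfig = Field(default_factory=ReactionConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    porosity: PorosityConfig = Field(default_factory=PorosityConfig)
    species: SpeciesConfig = Field(default_factory=SpeciesConfig)
    inflow: InflowConfig = Field(default_factory=InflowConfig)
    flow: FlowNumericsConfig = Field(default_factory=FlowNumericsConfig)
    transport: TransportNumericsConfig = Field(
        default_factory=TransportNumericsConfig)
    coupling: CouplingNumericsConfig = Field(
        default_factory=CouplingNumericsConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
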