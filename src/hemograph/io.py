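"""Trajectory I/O: VTU series (+PVD collection), one-file HDF5, and XDMF.

All formats are plain text or HDF5 and round-trip losslessly: floats are
written with 17 significant digits in the ASCII formats and natively in HDF5.

HDF5 layout::

    /mesh/positions     (N, 3) float64
    /mesh/tets          (M, 4) int64
    /mesh/node_type     (N,)   int64        (optional)
    /mesh/wall_normals  (N, 3) float64      (optional)
    /frames/velocity    (T, N, 3) float64
    /frames/pressure    (T, N)    float64   (optional)
    attrs: dt, t0
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, StructuralError
from .mesh import FlowFrame, Trajectory, VolumetricMesh

_FMT = "%.17g"
_VTK_TETRA = 10


def _ascii(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(_FMT % v for v in flat)


def _data_array(name: str | None, arr: np.ndarray, ncomp: int | None = None) -> ET.Element:
    arr = np.asarray(arr)
    vtype = {"f": "Float64", "i": "Int64", "u": "UInt8"}[arr.dtype.kind]
    el = ET.Element("DataArray", type=vtype, format="ascii")
    if name:
        el.set("Name", name)
    if ncomp:
        el.set("NumberOfComponents", str(ncomp))
    el.text = _ascii(arr)
    return el


# ---------------------------------------------------------------------------
# VTU
# ---------------------------------------------------------------------------

def write_vtu(path: str | Path, mesh: VolumetricMesh, frame: FlowFrame) -> None:
    """One unstructured-grid VTU file (ASCII) with point data
    "velocity" (3), optional "pressure", "node_type" and "wall_normals"."""
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(mesh.n_nodes),
                          NumberOfCells=str(mesh.n_cells))
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array(None, mesh.positions, ncomp=3))
    cells = ET.SubElement(piece, "Cells")
    cells.append(_data_array("connectivity", mesh.tetrahedra))
    cells.append(_data_array("offsets", 4 * np.arange(1, mesh.n_cells + 1, dtype=np.int64)))
    cells.append(_data_array("types", np.full(mesh.n_cells, _VTK_TETRA, dtype=np.uint8)))
    pdata = ET.SubElement(piece, "PointData")
    pdata.append(_data_array("velocity", frame.velocity, ncomp=3))
    if frame.pressure is not None:
        pdata.append(_data_array("pressure", frame.pressure))
    if mesh.node_type is not None:
        pdata.append(_data_array("node_type", mesh.node_type))
    if mesh.wall_normals is not None:
        pdata.append(_data_array("wall_normals", mesh.wall_normals, ncomp=3))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="ascii")


def _parse_data_array(el: ET.Element, path) -> np.ndarray:
    if el.get("format", "ascii") != "ascii":
        raise FormatError(f"{path}: only ascii-format VTU is supported")
    dtype = np.float64 if el.get("type", "").startswith("Float") else np.int64
    text = el.text or ""
    arr = np.array(text.split(), dtype=np.float64).astype(dtype)
    ncomp = el.get("NumberOfComponents")
    if ncomp:
        arr = arr.reshape(-1, int(ncomp))
    return arr


def read_vtu(
    path: str | Path,
    velocity_name: str = "velocity",
    pressure_name: str = "pressure",
) -> tuple[VolumetricMesh, FlowFrame]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise FormatError(f"{path}: not parseable VTU XML ({e})") from e
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise FormatError(f"{path}: no UnstructuredGrid/Piece element")
    pos = _parse_data_array(piece.find("./Points/DataArray"), path)
    arrays = {}
    for el in piece.findall("./Cells/DataArray"):
        arrays[el.get("Name")] = _parse_data_array(el, path)
    types = arrays.get("types")
    if types is None or not np.all(types == _VTK_TETRA):
        raise FormatError(f"{path}: only tetrahedral (type 10) cells are supported")
    tets = arrays["connectivity"].reshape(-1, 4)
    pdata = {}
    for el in piece.findall("./PointData/DataArray"):
        pdata[el.get("Name")] = _parse_data_array(el, path)
    if velocity_name not in pdata:
        raise FormatError(f"{path}: point-data field '{velocity_name}' not found")
    mesh = VolumetricMesh(
        positions=pos,
        tetrahedra=tets,
        node_type=pdata.get("node_type"),
        wall_normals=pdata.get("wall_normals"),
    ).orient()
    frame = FlowFrame(
        time=0.0,
        velocity=pdata[velocity_name].reshape(-1, 3),
        pressure=pdata.get(pressure_name),
    )
    return mesh, frame


def _write_vtu_series(base: Path, traj: Trajectory) -> None:
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name[: -len(".pvd")] if base.name.endswith(".pvd") else base.name
    root = ET.Element("VTKFile", type="Collection", version="0.1")
    coll = ET.SubElement(root, "Collection")
    for k, f in enumerate(traj.frames):
        fname = f"{stem}_{k:04d}.vtu"
        write_vtu(base.parent / fname, traj.mesh, f)
        ET.SubElement(coll, "DataSet", timestep=_FMT % f.time, part="0", file=fname)
    ET.ElementTree(root).write(base.parent / f"{stem}.pvd",
                               xml_declaration=True, encoding="ascii")


def _read_vtu_series(path: Path, velocity_name: str, pressure_name: str) -> Trajectory:
    if path.is_dir():
        pvds = sorted(path.glob("*.pvd"))
        if not pvds:
            raise FormatError(f"{path}: no .pvd collection found")
        path = pvds[0]
    root = ET.parse(path).getroot()
    entries = root.findall("./Collection/DataSet")
    if not entries:
        raise FormatError(f"{path}: empty PVD collection")
    mesh = None
    frames = []
    for ds in entries:
        fpath = path.parent / ds.get("file")
        m, fr = read_vtu(fpath, velocity_name, pressure_name)
        fr.time = float(ds.get("timestep"))
        if mesh is None:
            mesh = m
        elif m.n_nodes != mesh.n_nodes or not np.array_equal(m.tetrahedra, mesh.tetrahedra):
            raise StructuralError(f"{fpath}: node count/connectivity changed across frames")
        frames.append(fr)
    times = np.array([f.time for f in frames])
    dt = float(np.median(np.diff(times))) if len(frames) > 1 else 0.0
    return Trajectory(mesh=mesh, frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def _write_hdf5(path: Path, traj: Trajectory) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        g = h5.create_group("mesh")
        g.create_dataset("positions", data=traj.mesh.positions)
        g.create_dataset("tets", data=traj.mesh.tetrahedra)
        if traj.mesh.node_type is not None:
            g.create_dataset("node_type", data=traj.mesh.node_type)
        if traj.mesh.wall_normals is not None:
            g.create_dataset("wall_normals", data=traj.mesh.wall_normals)
        fr = h5.create_group("frames")
        fr.create_dataset("velocity", data=traj.velocities())
        if traj.frames[0].pressure is not None:
            fr.create_dataset("pressure",
                              data=np.stack([f.pressure for f in traj.frames]))
        h5.attrs["dt"] = traj.dt
        h5.attrs["t0"] = traj.frames[0].time


def _read_hdf5(path: Path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        if "frames/velocity" not in h5:
            raise FormatError(f"{path}: dataset /frames/velocity not found")
        mesh = VolumetricMesh(
            positions=h5["mesh/positions"][()],
            tetrahedra=h5["mesh/tets"][()],
            node_type=h5["mesh/node_type"][()] if "mesh/node_type" in h5 else None,
            wall_normals=h5["mesh/wall_normals"][()] if "mesh/wall_normals" in h5 else None,
        )
        vel = h5["frames/velocity"][()]
        pres = h5["frames/pressure"][()] if "frames/pressure" in h5 else None
        dt = float(h5.attrs["dt"])
        t0 = float(h5.attrs["t0"])
    frames = [
        FlowFrame(time=t0 + k * dt, velocity=vel[k],
                  pressure=pres[k] if pres is not None else None)
        for k in range(vel.shape[0])
    ]
    return Trajectory(mesh=mesh, frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# XDMF (time series referencing an HDF5 heavy file)
# ---------------------------------------------------------------------------

def _write_xdmf(path: Path, traj: Trajectory) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    heavy = path.with_suffix(".h5")
    _write_hdf5(heavy, traj)
    root = ET.Element("Xdmf", Version="3.0")
    dom = ET.SubElement(root, "Domain")
    coll = ET.SubElement(dom, "Grid", Name="trajectory", GridType="Collection",
                         CollectionType="Temporal")
    hname = heavy.name
    n, m = traj.mesh.n_nodes, traj.mesh.n_cells
    for k, f in enumerate(traj.frames):
        grid = ET.SubElement(coll, "Grid", Name=f"frame{k}", GridType="Uniform")
        ET.SubElement(grid, "Time", Value=_FMT % f.time)
        topo = ET.SubElement(grid, "Topology", TopologyType="Tetrahedron",
                             NumberOfElements=str(m))
        di = ET.SubElement(topo, "DataItem", Dimensions=f"{m} 4",
                           NumberType="Int", Format="HDF")
        di.text = f"{hname}:/mesh/tets"
        geom = ET.SubElement(grid, "Geometry", GeometryType="XYZ")
        di = ET.SubElement(geom, "DataItem", Dimensions=f"{n} 3", Format="HDF")
        di.text = f"{hname}:/mesh/positions"
        attr = ET.SubElement(grid, "Attribute", Name="velocity",
                             AttributeType="Vector", Center="Node")
        sel = ET.SubElement(attr, "DataItem", ItemType="HyperSlab",
                            Dimensions=f"{n} 3")
        dims = ET.SubElement(sel, "DataItem", Dimensions="3 3", Format="XML")
        dims.text = f"{k} 0 0 1 1 1 1 {n} 3"
        di = ET.SubElement(sel, "DataItem",
                           Dimensions=f"{traj.n_frames} {n} 3", Format="HDF")
        di.text = f"{hname}:/frames/velocity"
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="ascii")


def _read_xdmf(path: Path) -> Trajectory:
    root = ET.parse(path).getroot()
    grids = root.findall("./Domain/Grid/Grid")
    if not grids:
        raise FormatError(f"{path}: no temporal grid collection found")
    heavy_ref = grids[0].find("./Geometry/DataItem")
    if heavy_ref is None or ":" not in (heavy_ref.text or ""):
        raise FormatError(f"{path}: geometry does not reference an HDF5 dataset")
    hname = heavy_ref.text.strip().split(":")[0]
    traj = _read_hdf5(path.parent / hname)
    times = [float(g.find("Time").get("Value")) for g in grids]
    for f, t in zip(traj.frames, times):
        f.time = t
    return traj


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

FORMATS = ("vtu-series", "hdf5", "xdmf")


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "hdf5") -> None:
    """Write a trajectory; bit-stable given identical input.

    ``vtu-series`` writes one ASCII VTU per frame plus a PVD collection,
    ``hdf5`` the one-file container, ``xdmf`` an XML index plus HDF5 heavy data.
    """
    if not traj.frames:
        raise StructuralError("cannot write a trajectory with no frames")
    path = Path(path)
    if format == "vtu-series":
        _write_vtu_series(path, traj)
    elif format == "hdf5":
        _write_hdf5(path, traj)
    elif format == "xdmf":
        _write_xdmf(path, traj)
    else:
        raise FormatError(f"unknown trajectory format '{format}'; use one of {FORMATS}")


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    velocity_name: str = "velocity",
    pressure_name: str = "pressure",
) -> Trajectory:
    """Read a trajectory; the format is inferred from the suffix when not given."""
    path = Path(path)
    if not os.path.exists(path):
        raise FormatError(f"{path}: no such file or directory")
    if format is None:
        format = {".pvd": "vtu-series", ".h5": "hdf5", ".hdf5": "hdf5",
                  ".xdmf": "xdmf"}.get(path.suffix, "vtu-series" if path.is_dir() else None)
        if format is None:
            raise FormatError(f"{path}: cannot infer format; pass format=")
    if format == "vtu-series":
        traj = _read_vtu_series(path, velocity_name, pressure_name)
    elif format == "hdf5":
        traj = _read_hdf5(path)
    elif format == "xdmf":
        traj = _read_xdmf(path)
    else:
        raise FormatError(f"unknown trajectory format '{format}'; use one of {FORMATS}")
    traj.mesh.validate()
    return traj
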