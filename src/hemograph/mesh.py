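"""Tetrahedral mesh and flow-field containers, connectivity, and geometry.

Units are fixed package-wide: positions in mm, velocity in mm/s, time in s,
pressure in Pa.  With these choices velocity gradients are in 1/s and wall
shear stress comes out in Pa with no conversion factor; volumetric flow is
reported in mL/s (= 1000 mm^3/s).

Node labels
-----------
Each node carries exactly one of four labels: ``INLET``, ``WALL``,
``INTERIOR``, ``OUTLET``.  Boundary nodes (nodes on a surface triangle that
belongs to a single tetrahedron) must be inlet, wall or outlet; everything
else is interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DomainError,
    EmptySliceError,
    GeometryError,
    StructuralError,
)

INLET, WALL, INTERIOR, OUTLET = 0, 1, 2, 3
NODE_TYPE_NAMES = ("inlet", "wall", "interior", "outlet")
N_NODE_TYPES = 4

_TET_EDGES = np.array([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
_TET_FACES = np.array([(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VolumetricMesh:
    """Unstructured tetrahedral mesh with per-node boundary labels.

    Attributes
    ----------
    positions : (N, 3) float64, mm
    tetrahedra : (M, 4) int64, node indices with positive signed volume
    node_type : (N,) int, one of INLET / WALL / INTERIOR / OUTLET
    wall_normals : (N, 3) float64 — outward unit normals, defined (non-zero)
        only on wall nodes; zero rows elsewhere.
    """

    positions: np.ndarray
    tetrahedra: np.ndarray
    node_type: np.ndarray | None = None
    wall_normals: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.tetrahedra = np.ascontiguousarray(self.tetrahedra, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise StructuralError("positions must be (N, 3)")
        if self.tetrahedra.ndim != 2 or self.tetrahedra.shape[1] != 4:
            raise StructuralError("tetrahedra must be (M, 4)")
        if self.node_type is not None:
            self.node_type = np.asarray(self.node_type, dtype=np.int64)
        if self.wall_normals is not None:
            self.wall_normals = np.asarray(self.wall_normals, dtype=np.float64)

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tetrahedra.shape[0]

    def cell_volumes(self) -> np.ndarray:
        """Signed volumes of all tetrahedra (positive when oriented)."""
        p = self.positions[self.tetrahedra]
        return np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0

    def orient(self) -> "VolumetricMesh":
        """Swap node order of negatively-oriented tets so volumes are > 0."""
        vol = self.cell_volumes()
        flip = vol < 0
        if flip.any():
            t = self.tetrahedra.copy()
            t[flip, 2], t[flip, 3] = self.tetrahedra[flip, 3], self.tetrahedra[flip, 2]
            self.tetrahedra = t
        return self

    def validate(self) -> None:
        if self.tetrahedra.size and (
            self.tetrahedra.min() < 0 or self.tetrahedra.max() >= self.n_nodes
        ):
            raise StructuralError("tetrahedron index out of range")
        if np.any(self.cell_volumes() <= 0):
            raise StructuralError("non-positive tetrahedron volume (degenerate or inverted cell)")
        if self.node_type is not None:
            if self.node_type.shape != (self.n_nodes,):
                raise StructuralError("node_type length mismatch")
            if not np.isin(self.node_type, [INLET, WALL, INTERIOR, OUTLET]).all():
                raise StructuralError("unknown node label")
            bnodes = boundary_nodes(self)
            if np.any(self.node_type[bnodes] == INTERIOR):
                raise StructuralError("boundary node labeled interior")
        if self.wall_normals is not None and self.node_type is not None:
            wall = self.node_type == WALL
            norms = np.linalg.norm(self.wall_normals[wall], axis=1)
            if wall.any() and np.any(np.abs(norms - 1.0) > 1e-9):
                raise StructuralError("wall normals are not unit vectors")


@dataclass
class FlowFrame:
    """Nodal velocity (and optional pressure) at one instant."""

    time: float
    velocity: np.ndarray  # (N, 3) mm/s
    pressure: np.ndarray | None = None  # (N,) Pa

    def __post_init__(self):
        self.velocity = np.ascontiguousarray(self.velocity, dtype=np.float64)
        if self.pressure is not None:
            self.pressure = np.ascontiguousarray(self.pressure, dtype=np.float64)
        if self.time < 0:
            raise StructuralError("frame time must be >= 0")


@dataclass
class Trajectory:
    """Time-ordered flow frames on a single mesh with uniform step dt."""

    mesh: VolumetricMesh
    frames: list[FlowFrame]
    dt: float

    def __post_init__(self):
        n = self.mesh.n_nodes
        for k, f in enumerate(self.frames):
            if f.velocity.shape != (n, 3):
                raise StructuralError(
                    f"frame {k}: velocity shape {f.velocity.shape} != ({n}, 3)"
                )
        t0 = self.frames[0].time if self.frames else 0.0
        for k, f in enumerate(self.frames):
            if abs(f.time - (t0 + k * self.dt)) > 1e-9:
                raise StructuralError(f"frame {k} time {f.time} off the uniform grid")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def velocities(self) -> np.ndarray:
        """(T, N, 3) stacked velocity fields."""
        return np.stack([f.velocity for f in self.frames])


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def extract_edges(mesh: VolumetricMesh) -> np.ndarray:
    """Unique undirected mesh edges as an (E, 2) array with e[:,0] < e[:,1].

    Every unordered node pair sharing a tetrahedron appears exactly once.
    """
    tets = mesh.tetrahedra
    if tets.shape[0] < 1:
        raise StructuralError("mesh has no tetrahedra")
    for a in range(4):
        for b in range(a + 1, 4):
            if np.any(tets[:, a] == tets[:, b]):
                raise StructuralError("degenerate tetrahedron with repeated node index")
    pairs = tets[:, _TET_EDGES].reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def boundary_faces(mesh: VolumetricMesh) -> tuple[np.ndarray, np.ndarray]:
    """Surface triangles (faces belonging to exactly one tet).

    Returns
    -------
    faces : (F, 3) node indices, outward-oriented (right-hand normal points
        away from the fluid).
    cells : (F,) index of the owning tetrahedron.
    """
    tets = mesh.tetrahedra
    faces = tets[:, _TET_FACES].reshape(-1, 3)  # outward for positive tets
    owner = np.repeat(np.arange(tets.shape[0]), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_surface = counts[inv] == 1
    return faces[on_surface], owner[on_surface]


def boundary_nodes(mesh: VolumetricMesh) -> np.ndarray:
    faces, _ = boundary_faces(mesh)
    return np.unique(faces)


# ---------------------------------------------------------------------------
# node classification
# ---------------------------------------------------------------------------

@dataclass
class DiscSpec:
    """Planar disc used to mark inlet/outlet patches on the boundary.

    A boundary node is inside the disc when its distance to the plane is
    below ``tol`` and its in-plane distance from the center is at most
    ``radius + tol``.
    """

    center: np.ndarray
    normal: np.ndarray
    radius: float
    tol: float = 1e-6

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        n = np.asarray(self.normal, dtype=np.float64)
        self.normal = n / np.linalg.norm(n)

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - self.center
        off = d @ self.normal
        inplane = np.linalg.norm(d - np.outer(off, self.normal), axis=1)
        return (np.abs(off) <= self.tol) & (inplane <= self.radius + self.tol)


def classify_nodes(
    mesh: VolumetricMesh, inlet_spec: DiscSpec, outlet_spec: DiscSpec
) -> np.ndarray:
    """Label every node inlet/wall/interior/outlet from two disc descriptors."""
    labels = np.full(mesh.n_nodes, INTERIOR, dtype=np.int64)
    bnodes = boundary_nodes(mesh)
    pts = mesh.positions[bnodes]
    is_in = inlet_spec.contains(pts)
    is_out = outlet_spec.contains(pts)
    if np.any(is_in & is_out):
        raise ConfigurationError("inlet and outlet discs overlap")
    labels[bnodes] = WALL
    labels[bnodes[is_in]] = INLET
    labels[bnodes[is_out]] = OUTLET
    mesh.node_type = labels
    return labels


def wall_normals(mesh: VolumetricMesh) -> np.ndarray:
    """Outward unit normals at wall nodes.

    Area-weighted average of the incident surface-triangle outward normals,
    renormalized.  Outward orientation is verified against the adjacent
    tetrahedron centroid.  Non-wall rows are zero.
    """
    if mesh.node_type is None:
        raise StructuralError("mesh must be classified before computing wall normals")
    faces, owners = boundary_faces(mesh)
    p = mesh.positions
    fn = np.cross(p[faces[:, 1]] - p[faces[:, 0]], p[faces[:, 2]] - p[faces[:, 0]])
    areas = 0.5 * np.linalg.norm(fn, axis=1)
    if np.any(areas <= 0):
        raise StructuralError("zero-area boundary face: outward orientation ambiguous")
    # orientation check: face normal must point away from the owning tet
    cent_t = p[mesh.tetrahedra[owners]].mean(axis=1)
    cent_f = p[faces].mean(axis=1)
    wrong = np.einsum("ij,ij->i", fn, cent_f - cent_t) < 0
    fn[wrong] *= -1.0

    normals = np.zeros((mesh.n_nodes, 3))
    for k in range(3):
        np.add.at(normals, faces[:, k], fn / 2.0)  # fn/2 has magnitude = area
    wall = mesh.node_type == WALL
    wall_on_surface = np.zeros(mesh.n_nodes, dtype=bool)
    wall_on_surface[np.unique(faces)] = True
    if np.any(wall & ~wall_on_surface):
        raise StructuralError("wall node incident to no boundary face")
    norms = np.linalg.norm(normals[wall], axis=1)
    out = np.zeros_like(normals)
    out[wall] = normals[wall] / norms[:, None]
    mesh.wall_normals = out
    return out


def node_areas(mesh: VolumetricMesh) -> np.ndarray:
    """Per-node boundary area weights: one third of incident surface-triangle
    areas.  Zero for nodes off the boundary surface."""
    faces, _ = boundary_faces(mesh)
    p = mesh.positions
    fn = np.cross(p[faces[:, 1]] - p[faces[:, 0]], p[faces[:, 2]] - p[faces[:, 0]])
    areas = 0.5 * np.linalg.norm(fn, axis=1)
    w = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(w, faces[:, k], areas / 3.0)
    return w


# ---------------------------------------------------------------------------
# point location and interpolation
# ---------------------------------------------------------------------------

class _TetLocator:
    """Locates query points in a tetrahedral mesh via a centroid KD-tree."""

    def __init__(self, mesh: VolumetricMesh):
        self.mesh = mesh
        p = mesh.positions[mesh.tetrahedra]
        self.centroids = p.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        # per-tet inverse of the edge matrix for barycentric coordinates
        self.origin = p[:, 0]
        T = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))  # (M, 3, 3)
        self.Tinv = np.linalg.inv(T)

    def bary(self, tet_ids: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Barycentric coordinates (K, 4) of points w.r.t. the given tets."""
        lam = np.einsum(
            "kij,kj->ki", self.Tinv[tet_ids], points - self.origin[tet_ids]
        )
        return np.concatenate([1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1)

    def locate(self, points: np.ndarray, tol: float = 1e-6):
        """For each point: (containing tet, barycentric coords, outside flag).

        Points not inside any nearby tet fall back to the candidate tet whose
        barycentric coordinates violate the simplex least; their coordinates
        are clamped to the simplex (nearest-element projection) and the point
        is flagged.
        """
        n = points.shape[0]
        tet_of = np.full(n, -1, dtype=np.int64)
        lam_of = np.zeros((n, 4))
        outside = np.zeros(n, dtype=bool)
        pending = np.arange(n)
        best_viol = np.full(n, np.inf)
        best_tet = np.zeros(n, dtype=np.int64)
        best_lam = np.zeros((n, 4))
        k = min(8, self.centroids.shape[0])
        while pending.size:
            _, cand = self.tree.query(points[pending], k=k)
            cand = np.atleast_2d(cand)
            for col in range(cand.shape[1]):
                lam = self.bary(cand[:, col], points[pending])
                viol = np.maximum(0.0, -lam.min(axis=1))
                better = viol < best_viol[pending]
                idx = pending[better]
                best_viol[idx] = viol[better]
                best_tet[idx] = cand[better, col]
                best_lam[idx] = lam[better]
            done = best_viol[pending] <= tol
            hit = pending[done]
            tet_of[hit] = best_tet[hit]
            lam_of[hit] = best_lam[hit]
            pending = pending[~done]
            if k >= min(256, self.centroids.shape[0]):
                break
            k = min(k * 4, self.centroids.shape[0])
        if pending.size:  # nearest-element projection fallback
            tet_of[pending] = best_tet[pending]
            lam = np.clip(best_lam[pending], 0.0, None)
            lam_of[pending] = lam / lam.sum(axis=1, keepdims=True)
            outside[pending] = True
        return tet_of, lam_of, outside

    def sample(self, tet_of, lam_of, nodal: np.ndarray) -> np.ndarray:
        verts = self.mesh.tetrahedra[tet_of]  # (K, 4)
        vals = nodal[verts]  # (K, 4, C) or (K, 4)
        if vals.ndim == 2:
            return np.einsum("kv,kv->k", lam_of, vals)
        return np.einsum("kv,kvc->kc", lam_of, vals)


@dataclass
class InterpolationReport:
    n_points: int
    n_outside: int
    tolerance: float


def interpolate_fields(
    src: Trajectory, dst_mesh: VolumetricMesh, tol: float = 1e-6
) -> tuple[Trajectory, InterpolationReport]:
    """Transfer all frames of ``src`` onto ``dst_mesh`` by barycentric-linear
    interpolation inside the containing source tetrahedron.

    Destination nodes outside the source domain by more than ``tol`` (mm) are
    projected onto the nearest candidate element and counted in the report.
    """
    loc = _TetLocator(src.mesh)
    tet_of, lam_of, outside = loc.locate(dst_mesh.positions, tol=tol)
    if outside.all() and dst_mesh.n_nodes > 0:
        raise DomainError("destination mesh lies entirely outside the source domain")
    frames = []
    for f in src.frames:
        vel = loc.sample(tet_of, lam_of, f.velocity)
        pres = loc.sample(tet_of, lam_of, f.pressure) if f.pressure is not None else None
        frames.append(FlowFrame(time=f.time, velocity=vel, pressure=pres))
    report = InterpolationReport(
        n_points=dst_mesh.n_nodes, n_outside=int(outside.sum()), tolerance=tol
    )
    return Trajectory(mesh=dst_mesh, frames=frames, dt=src.dt), report


def probe_values(traj: Trajectory, points: np.ndarray) -> np.ndarray:
    """Velocity time series at fixed spatial probes: (T, P, 3).

    Raises :class:`DomainError` if any probe lies outside the mesh.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    loc = _TetLocator(traj.mesh)
    tet_of, lam_of, outside = loc.locate(points, tol=1e-6)
    if outside.any():
        raise DomainError(f"{int(outside.sum())} probe point(s) outside the domain")
    return np.stack([loc.sample(tet_of, lam_of, f.velocity) for f in traj.frames])


# ---------------------------------------------------------------------------
# plane slicing
# ---------------------------------------------------------------------------

@dataclass
class PlaneSlice:
    """Triangulated cross-section of the mesh with interpolated velocity."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (K, 3)
    velocity: np.ndarray  # (V, 3)
    normal: np.ndarray  # unit plane normal

    @property
    def area(self) -> float:
        p = self.vertices[self.triangles]
        return float(
            0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1).sum()
        )


def plane_slice(
    mesh: VolumetricMesh, frame: FlowFrame, point: np.ndarray, normal: np.ndarray
) -> PlaneSlice:
    """Intersect the tet mesh with a plane (marching tetrahedra) and linearly
    interpolate the frame velocity onto the section vertices."""
    point = np.asarray(point, dtype=np.float64)
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    d = (mesh.positions - point) @ normal
    span = np.abs(d).max() if d.size else 1.0
    # nudge nodes exactly on the plane to avoid degenerate polygons
    eps = 1e-12 * max(span, 1.0)
    d = np.where(np.abs(d) < eps, eps, d)

    tets = mesh.tetrahedra
    dt_ = d[tets]  # (M, 4)
    cut = (dt_.min(axis=1) < 0) & (dt_.max(axis=1) > 0)
    if not cut.any():
        raise EmptySliceError("plane does not intersect the mesh")
    verts, tris, vels = [], [], []
    pos = mesh.positions
    vel = frame.velocity
    for tet, dv in zip(tets[cut], dt_[cut]):
        pts, uvals = [], []
        for a, b in _TET_EDGES:
            if dv[a] * dv[b] < 0:
                t = dv[a] / (dv[a] - dv[b])
                pts.append(pos[tet[a]] + t * (pos[tet[b]] - pos[tet[a]]))
                uvals.append(vel[tet[a]] + t * (vel[tet[b]] - vel[tet[a]]))
        pts = np.array(pts)
        uvals = np.array(uvals)
        base = len(verts)
        if len(pts) == 3:
            order = [0, 1, 2]
            local_tris = [[0, 1, 2]]
        elif len(pts) == 4:
            # order quad vertices by angle around their centroid in-plane
            c = pts.mean(axis=0)
            ref = pts[0] - c
            ref /= np.linalg.norm(ref)
            t2 = np.cross(normal, ref)
            ang = np.arctan2((pts - c) @ t2, (pts - c) @ ref)
            order = list(np.argsort(ang))
            local_tris = [[0, 1, 2], [0, 2, 3]]
        else:  # pragma: no cover - excluded by the eps nudge
            continue
        for o in order:
            verts.append(pts[o])
            vels.append(uvals[o])
        for tri in local_tris:
            tris.append([base + t for t in tri])
    sl = PlaneSlice(
        vertices=np.array(verts),
        triangles=np.array(tris, dtype=np.int64),
        velocity=np.array(vels),
        normal=normal,
    )
    if sl.area <= 0:
        raise EmptySliceError("slice has zero area")
    return sl
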