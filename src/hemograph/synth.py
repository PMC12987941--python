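"""Synthetic geometries, inflow waveforms and analytic flow trajectories.

These generators emulate the study conditions of the benchmark cases the
package targets: a 4 mm-diameter curved (half-torus) parent artery carrying
a sidewall aneurysm bulge of 3-9 mm, a pulsatile parabolic inflow with a
0.8 s cardiac cycle preceded by a 0.2 s linear ramp and a ~6 mL/s systolic
peak, rigid no-slip walls, and trajectories sampled at a uniform timestep
(80 frames per 0.8 s cycle at the 0.01 s reference step).

Meshing is structured: a triangulated disc is extruded into prisms, each
split into three tetrahedra with an index-ordered diagonal rule (conforming
by construction), and curved geometries are obtained by smooth deformation
of the straight tube.  The generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .errors import GeometryError, StructuralError
from .mesh import (
    INLET,
    WALL,
    DiscSpec,
    FlowFrame,
    Trajectory,
    VolumetricMesh,
    classify_nodes,
    wall_normals,
)

ML_TO_MM3 = 1000.0  # 1 mL = 1000 mm^3


# ---------------------------------------------------------------------------
# inflow waveform
# ---------------------------------------------------------------------------

@dataclass
class InflowWaveform:
    """Pulsatile volumetric inflow Q(t) in mL/s.

    A 0.2 s linear ramp from zero joins a periodic carotid-like waveform
    built from three aligned cosine harmonics with a single systolic peak at
    ``peak_phase`` of the cycle; the shape is scaled so its maximum equals
    ``peak_flow`` exactly (the aligned harmonics peak analytically at
    ``peak_phase``).
    """

    period: float = 0.8       # s, cardiac cycle
    ramp_duration: float = 0.2  # s, linear start-up
    peak_flow: float = 6.0    # mL/s systolic peak
    peak_phase: float = 0.15  # cycle fraction of the systolic peak
    harmonics: tuple[float, ...] = (0.52, 0.20, 0.10)

    def __post_init__(self):
        if min(self.period, self.ramp_duration, self.peak_flow) <= 0:
            raise ValueError("period, ramp_duration and peak_flow must be positive")
        if sum(self.harmonics) >= 1.0:
            raise ValueError("harmonic amplitudes must sum below 1 to keep Q > 0")

    def _shape(self, phase: np.ndarray) -> np.ndarray:
        s = np.ones_like(phase)
        for k, amp in enumerate(self.harmonics, start=1):
            s = s + amp * np.cos(2.0 * np.pi * k * (phase - self.peak_phase))
        return s

    def __call__(self, t) -> np.ndarray:
        """Flow in mL/s; scalar in, scalar out."""
        t_arr = np.asarray(t, dtype=np.float64)
        scale = self.peak_flow / (1.0 + sum(self.harmonics))
        phase = (t_arr - self.ramp_duration) / self.period
        q_cycle = scale * self._shape(phase)
        q0 = scale * self._shape(np.zeros(()))
        ramp = np.clip(t_arr / self.ramp_duration, 0.0, 1.0)
        out = np.where(t_arr < self.ramp_duration, ramp * q0, q_cycle)
        return out if out.ndim else float(out)


def make_waveform(**kwargs) -> InflowWaveform:
    return InflowWaveform(**kwargs)


# ---------------------------------------------------------------------------
# inlet velocity profile
# ---------------------------------------------------------------------------

def inlet_frame(mesh: VolumetricMesh, planarity_tol: float = 1e-6):
    """Inlet disc geometry: (node indices, center, inward unit normal, radius).

    Raises :class:`GeometryError` if the inlet nodes are not planar within
    ``planarity_tol`` (mm).
    """
    if mesh.node_type is None:
        raise StructuralError("mesh is not classified")
    idx = np.flatnonzero(mesh.node_type == INLET)
    if idx.size < 3:
        raise GeometryError("fewer than 3 inlet nodes")
    pts = mesh.positions[idx]
    center = pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = vt[2]
    off = (pts - center) @ normal
    if np.abs(off).max() > planarity_tol:
        raise GeometryError(
            f"inlet nodes deviate {np.abs(off).max():.3g} mm from a plane"
        )
    # orient the normal into the fluid
    if (mesh.positions.mean(axis=0) - center) @ normal < 0:
        normal = -normal
    radius = float(np.linalg.norm(pts - center, axis=1).max())
    return idx, center, normal, radius


def parabolic_inlet(
    mesh: VolumetricMesh, frame_time: float, waveform: InflowWaveform
) -> np.ndarray:
    """Fully developed parabolic inflow velocities (N, 3), mm/s.

    u(r) = u_max (1 - r^2/R^2) along the inward inlet normal with
    u_max = 2 Q(t) / (pi R^2); rim nodes (r = R) get exactly zero.
    Rows off the inlet are zero.
    """
    idx, center, normal, radius = inlet_frame(mesh)
    q = waveform(frame_time) * ML_TO_MM3  # mm^3/s
    u_max = 2.0 * q / (np.pi * radius**2)
    r = np.linalg.norm(mesh.positions[idx] - center, axis=1)
    speed = u_max * (1.0 - (r / radius) ** 2)
    out = np.zeros((mesh.n_nodes, 3))
    out[idx] = speed[:, None] * normal
    return out


def inlet_surface_flux(mesh: VolumetricMesh, velocity: np.ndarray, label=INLET) -> float:
    """Discrete flux (mL/s) of a nodal field through the labeled boundary
    patch, by linear quadrature over its boundary triangles."""
    from .mesh import boundary_faces

    faces, _ = boundary_faces(mesh)
    on_patch = np.all(mesh.node_type[faces] != WALL, axis=1) & np.any(
        mesh.node_type[faces] == label, axis=1
    )
    faces = faces[on_patch]
    if faces.size == 0:
        raise GeometryError("no boundary faces on the requested patch")
    p = mesh.positions
    fn = 0.5 * np.cross(p[faces[:, 1]] - p[faces[:, 0]], p[faces[:, 2]] - p[faces[:, 0]])
    u_mean = velocity[faces].mean(axis=1)
    flux = np.abs(np.einsum("fc,fc->f", u_mean, fn)).sum()
    return float(flux / ML_TO_MM3)


# ---------------------------------------------------------------------------
# structured tube meshing
# ---------------------------------------------------------------------------

def _disc_points(radius: float, h: float) -> np.ndarray:
    """Rings of points covering a disc with spacing ~h, rim exactly at R."""
    n_rings = max(1, int(np.ceil(radius / h)))
    dr = radius / n_rings
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = k * dr
        n = max(6, round(2.0 * np.pi * r / dr))
        ang = 2.0 * np.pi * np.arange(n) / n + (0.5 * np.pi * (k % 2) / n)
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    return np.concatenate(pts)


def _split_prisms(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split prisms (bottom/top triangle node triples) into 3 tets each with
    the global-index diagonal rule, so adjacent prisms conform."""
    tets = []
    for tri_b, tri_t in zip(bottom, top):
        # rotate so the smallest global index is vertex 0
        r = int(np.argmin(tri_b))
        b = np.roll(tri_b, -r)
        t = np.roll(tri_t, -r)
        v0, v1, v2 = b
        w0, w1, w2 = t
        # quad faces (v1,v2,w2,w1) diagonal through the smaller of v1/v2
        if min(v1, w2) < min(v2, w1):
            tets += [[v0, v1, v2, w2], [v0, v1, w2, w1], [v0, w1, w2, w0]]
        else:
            tets += [[v0, v1, v2, w1], [v0, w1, v2, w2], [v0, w1, w2, w0]]
    return np.array(tets, dtype=np.int64)


def make_tube_mesh(radius: float = 2.0, length: float = 10.0, h: float = 0.3) -> VolumetricMesh:
    """Classified tetrahedral mesh of a straight cylinder along +z.

    Inlet disc at z = 0, outlet at z = length, lateral surface wall; target
    edge length ``h`` (median edge within 25 %).
    """
    if min(radius, length, h) <= 0:
        raise ValueError("radius, length and h must be positive")
    disc = _disc_points(radius, h)
    tri = Delaunay(disc)
    n_layers = max(1, int(np.ceil(length / h)))
    dz = length / n_layers
    n2 = disc.shape[0]
    pts = np.concatenate(
        [
            np.column_stack([disc, np.full(n2, k * dz)])
            for k in range(n_layers + 1)
        ]
    )
    tets = []
    for k in range(n_layers):
        bot = tri.simplices + k * n2
        top = tri.simplices + (k + 1) * n2
        tets.append(_split_prisms(bot, top))
    mesh = VolumetricMesh(positions=pts, tetrahedra=np.concatenate(tets)).orient()
    classify_nodes(
        mesh,
        inlet_spec=DiscSpec(center=(0, 0, 0), normal=(0, 0, 1), radius=radius),
        outlet_spec=DiscSpec(center=(0, 0, length), normal=(0, 0, 1), radius=radius),
    )
    wall_normals(mesh)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# semi-idealized aneurysm geometry
# ---------------------------------------------------------------------------

@dataclass
class GeometrySpec:
    """Half-torus parent artery with a parametric sidewall bulge.

    The bulge stands in for patient-derived sacs: a smooth radial inflation
    of the tube wall around the mid-arc point, apex oriented along +y so the
    standard region planes (y = 7 and 8.5 mm) apply.  ``bulge_diameter`` is
    the height of the sac above the vessel centerline; the sac width scales
    with it.
    """

    vessel_diameter: float = 4.0      # mm
    torus_major_radius: float = 10.0  # mm
    bulge_diameter: float = 7.0       # mm, in [3, 9] unless overridden
    bulge_offset: float = 0.0         # mm of arc length from mid-arc
    bulge_orientation: float = 0.0    # rad around the tube axis, 0 = +y
    target_edge_length: float = 0.3   # mm
    allow_out_of_range: bool = False
    jitter: float = 0.0               # mm of seeded node jitter (interior only)

    def __post_init__(self):
        if self.vessel_diameter <= 0:
            raise ValueError("vessel_diameter must be positive")
        if not self.allow_out_of_range and not 3.0 <= self.bulge_diameter <= 9.0:
            raise ValueError("bulge_diameter outside [3, 9] mm (set allow_out_of_range)")


def make_semi_idealized_geometry(spec: GeometrySpec, seed: int = 0) -> VolumetricMesh:
    """Curved-artery aneurysm mesh per ``spec``; deterministic given seed.

    The half torus lies in the x-z plane with end discs in the x = 0 plane
    (inlet centered at (0, 0, -R_major), outlet at (0, 0, +R_major)); the
    bulge inflates the wall toward +y at mid-arc.
    """
    a = spec.vessel_diameter / 2.0
    Rm = spec.torus_major_radius
    if Rm <= a:
        raise GeometryError("torus major radius must exceed the vessel radius")
    arc = np.pi * Rm
    h = spec.target_edge_length
    straight = make_tube_mesh(radius=a, length=arc, h=h)
    labels = straight.node_type.copy()

    p = straight.positions.copy()
    rng = np.random.default_rng(seed)
    if spec.jitter > 0:
        interior = labels == 2
        p[interior] += rng.normal(0.0, spec.jitter, size=(int(interior.sum()), 3))

    # radial bulge inflation in cross-section polar coordinates
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    r = np.hypot(x, y)
    theta = np.arctan2(x, y) - spec.bulge_orientation  # 0 along +y
    theta = np.arctan2(np.sin(theta), np.cos(theta))
    s0 = arc / 2.0 + spec.bulge_offset
    amp = spec.bulge_diameter  # apex at r = a + bulge height
    sigma_s = spec.bulge_diameter / 4.0
    sigma_t = spec.bulge_diameter / (4.0 * a)
    bump = np.exp(-0.5 * ((z - s0) / sigma_s) ** 2 - 0.5 * (theta / sigma_t) ** 2)
    scale = 1.0 + (amp / a) * bump
    with np.errstate(invalid="ignore", divide="ignore"):
        fac = np.where(r > 0, scale, 1.0)
    p2 = p.copy()
    p2[:, 0] = x * fac
    p2[:, 1] = y * fac

    # bend the tube into a half torus in the x-z plane
    phi = p2[:, 2] / Rm
    rad = Rm + p2[:, 0]
    bent = np.column_stack([rad * np.sin(phi) - 0.0, p2[:, 1], -rad * np.cos(phi)])

    mesh = VolumetricMesh(positions=bent, tetrahedra=straight.tetrahedra, node_type=labels)
    if np.any(mesh.cell_volumes() <= 0):
        raise GeometryError("bulge/bend deformation inverted cells; spec too extreme")
    wall_normals(mesh)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# analytic trajectories
# ---------------------------------------------------------------------------

def make_analytic_trajectory(
    mesh: VolumetricMesh,
    waveform: InflowWaveform | None = None,
    dt: float = 0.01,
    n_cycles: float = 1.0,
    kind: str = "quasi-steady-poiseuille",
    t0: float | None = None,
    omega: tuple[float, float, float] = (0.0, 0.0, 5.0),
    A: np.ndarray | None = None,
    with_pressure: bool = False,
) -> Trajectory:
    """Closed-form flow frames standing in for CFD ground truth.

    kinds
    -----
    ``quasi-steady-poiseuille``
        The parabolic inlet profile of Q(t) extended down the whole (straight,
        +z-aligned) tube: divergence-free, no-slip walls.
    ``rigid-rotation``
        u = omega x x, exactly divergence-free for the neighborhood estimator.
    ``linear-field``
        u = A x for a constant 3x3 matrix A.
    """
    if waveform is None:
        waveform = InflowWaveform()
    n_frames = round(n_cycles * waveform.period / dt)
    if t0 is None:
        t0 = waveform.ramp_duration
    times = t0 + dt * np.arange(n_frames)
    frames = []
    if kind == "quasi-steady-poiseuille":
        idx, center, normal, radius = inlet_frame(mesh)
        ax = mesh.positions - center
        rad2 = np.einsum("nc,nc->n", ax, ax) - (ax @ normal) ** 2
        shape = np.clip(1.0 - rad2 / radius**2, 0.0, None)
        wall = mesh.node_type == WALL
        shape[wall] = 0.0
        for t in times:
            u_max = 2.0 * waveform(t) * ML_TO_MM3 / (np.pi * radius**2)
            vel = (u_max * shape)[:, None] * normal
            pres = np.zeros(mesh.n_nodes) if with_pressure else None
            frames.append(FlowFrame(time=float(t), velocity=vel, pressure=pres))
    elif kind == "rigid-rotation":
        w = np.asarray(omega, dtype=np.float64)
        vel = np.cross(np.broadcast_to(w, (mesh.n_nodes, 3)), mesh.positions)
        for t in times:
            frames.append(FlowFrame(time=float(t), velocity=vel.copy()))
    elif kind == "linear-field":
        if A is None:
            A = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 2.0], [0.5, 0.0, 0.0]])
        vel = mesh.positions @ np.asarray(A, dtype=np.float64).T
        for t in times:
            frames.append(FlowFrame(time=float(t), velocity=vel.copy()))
    else:
        raise ValueError(f"unknown trajectory kind '{kind}'")
    return Trajectory(mesh=mesh, frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# case splitting
# ---------------------------------------------------------------------------

def split_cases(cases: list, n_test: int, seed: int = 0) -> tuple[list, list]:
    """Seeded, disjoint, exhaustive train/test partition."""
    if n_test >= len(cases):
        raise ValueError("n_test must be smaller than the number of cases")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    test_idx = set(order[:n_test].tolist())
    train = [c for k, c in enumerate(cases) if k not in test_idx]
    test = [c for k, c in enumerate(cases) if k in test_idx]
    return train, test
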