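"""Clinical summary quantities and conservation diagnostics.

TAWSS (time-averaged wall shear stress magnitude), SAWSS (space-averaged
WSS over a wall region, area-weighted), cross-sectional volumetric flux and
the inlet/outlet mass-conservation report used to judge whether a predicted
velocity field respects continuity over the cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mesh import (
    WALL,
    FlowFrame,
    PlaneSlice,
    Trajectory,
    VolumetricMesh,
    node_areas,
    plane_slice,
)
from .ops import FluidProperties, wall_shear_stress
from .synth import ML_TO_MM3


@dataclass
class Plane:
    """Cross-section descriptor: a point on the plane, the plane normal, and
    an optional through-flow direction fixing the sign convention."""

    point: np.ndarray
    normal: np.ndarray
    name: str = ""
    through_direction: np.ndarray | None = None


def patch_plane(mesh: VolumetricMesh, label: int, inset: float = 0.5,
                name: str = "") -> Plane:
    """Cross-section plane just inside a labeled boundary patch.

    Fits the patch plane (centroid + smallest-variance direction), orients
    the normal into the fluid and offsets the point by ``inset`` mm so the
    slice cuts cleanly through cells instead of grazing the boundary.
    """
    idx = np.flatnonzero(mesh.node_type == label)
    if idx.size < 3:
        raise ConfigurationError("patch has fewer than 3 nodes")
    pts = mesh.positions[idx]
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = vt[2]
    if (mesh.positions.mean(axis=0) - center) @ normal < 0:
        normal = -normal
    return Plane(point=center + inset * normal, normal=normal, name=name,
                 through_direction=normal)


def mass_flux(
    mesh: VolumetricMesh, frame: FlowFrame, plane: Plane
) -> float:
    """Volumetric flow rate through the plane section in mL/s.

    Linear quadrature of u . n over the tet-plane intersection triangles
    (exact for nodal-linear fields).  Positive along the plane normal, or
    along ``through_direction`` when given.
    """
    sl = plane_slice(mesh, frame, plane.point, plane.normal)
    p = sl.vertices[sl.triangles]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    u_mean = sl.velocity[sl.triangles].mean(axis=1)
    n = sl.normal
    if plane.through_direction is not None:
        d = np.asarray(plane.through_direction, dtype=np.float64)
        if d @ n < 0:
            n = -n
    return float((areas * (u_mean @ n)).sum() / ML_TO_MM3)


@dataclass
class FluxReport:
    """Per-frame flows (mL/s) at named planes plus inlet/outlet imbalance."""

    times: np.ndarray
    plane_names: list[str]
    flows: np.ndarray  # (T, P) mL/s
    rel_diff_pct: np.ndarray  # (T,) %, NaN where skipped
    mean_diff_pct: float
    max_diff_pct: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flows, columns=self.plane_names)
        df.insert(0, "time", self.times)
        df["inlet_outlet_diff_pct"] = self.rel_diff_pct
        return df


def conservation_report(
    traj: Trajectory,
    inlet_plane: Plane,
    outlet_plane: Plane,
    intermediate_planes: list[Plane] | None = None,
    flow_floor_fraction: float = 0.01,
) -> FluxReport:
    """Per-frame |Q_in - Q_out| / |Q_in| in percent with cycle mean and max.

    Frames whose inlet flow is below ``flow_floor_fraction`` of the cycle
    peak are excluded from the relative-difference statistics to avoid
    division blow-up near zero flow.
    """
    planes = [inlet_plane, outlet_plane] + list(intermediate_planes or [])
    names = [p.name or f"plane{k}" for k, p in enumerate(planes)]
    flows = np.array(
        [[mass_flux(traj.mesh, f, p) for p in planes] for f in traj.frames]
    )
    q_in = np.abs(flows[:, 0])
    q_out = np.abs(flows[:, 1])
    floor = flow_floor_fraction * q_in.max()
    valid = q_in > floor
    rel = np.full(traj.n_frames, np.nan)
    rel[valid] = 100.0 * np.abs(q_in[valid] - q_out[valid]) / q_in[valid]
    return FluxReport(
        times=traj.times,
        plane_names=names,
        flows=flows,
        rel_diff_pct=rel,
        mean_diff_pct=float(np.nanmean(rel)),
        max_diff_pct=float(np.nanmax(rel)),
    )


def tawss(
    traj: Trajectory,
    props: FluidProperties,
    window: slice | None = None,
    **wss_kwargs,
) -> np.ndarray:
    """Time-averaged WSS magnitude per wall node (N,), Pa.

    The window defaults to all frames (one cardiac cycle for a one-cycle
    trajectory); rows off the wall are zero.
    """
    frames = traj.frames[window] if window is not None else traj.frames
    if not frames:
        raise ConfigurationError("empty TAWSS window")
    acc = np.zeros(traj.mesh.n_nodes)
    for f in frames:
        tau = wall_shear_stress(traj.mesh, f, props, **wss_kwargs)
        acc += np.linalg.norm(tau, axis=1)
    return acc / len(frames)


def sawss(
    frame_or_traj,
    mesh_or_props,
    props: FluidProperties | None = None,
    region_mask: np.ndarray | None = None,
    **wss_kwargs,
):
    """Area-weighted spatial mean of |tau| over wall nodes in the mask, Pa.

    ``sawss(frame, mesh, props, mask)`` returns a scalar;
    ``sawss(traj, props, region_mask=mask)`` returns a (T,) time series.
    Node weights are one third of incident boundary-triangle areas.
    """
    if isinstance(frame_or_traj, Trajectory):
        traj = frame_or_traj
        props_ = mesh_or_props
        return np.array(
            [
                sawss(f, traj.mesh, props_, region_mask=region_mask, **wss_kwargs)
                for f in traj.frames
            ]
        )
    frame: FlowFrame = frame_or_traj
    mesh: VolumetricMesh = mesh_or_props
    if props is None:
        raise ConfigurationError("sawss(frame, mesh, props, ...) needs properties")
    wall = mesh.node_type == WALL
    mask = wall if region_mask is None else (np.asarray(region_mask, dtype=bool) & wall)
    if not mask.any():
        raise ConfigurationError("empty SAWSS region mask")
    weights = node_areas(mesh)[mask]
    tau = wall_shear_stress(mesh, frame, props, **wss_kwargs)
    mag = np.linalg.norm(tau[mask], axis=1)
    return float((weights * mag).sum() / weights.sum())


def sawss_of_field(mesh: VolumetricMesh, magnitude: np.ndarray,
                   region_mask: np.ndarray | None = None) -> float:
    """Area-weighted mean of a precomputed per-node magnitude (e.g. TAWSS)."""
    wall = mesh.node_type == WALL
    mask = wall if region_mask is None else (np.asarray(region_mask, dtype=bool) & wall)
    if not mask.any():
        raise ConfigurationError("empty region mask")
    weights = node_areas(mesh)[mask]
    return float((weights * magnitude[mask]).sum() / weights.sum())
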