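"""Autoregressive rollout and evaluation metrics.

Rollout feeds each predicted frame back as the next input, with exact
boundary enforcement at every step (wall zeros, prescribed inlet) and no
input noise.  Errors are the velocity-vector RMSEs: 1-RMSE for a single
next-step prediction and T-RMSE, the mean over T rollout steps of the
per-step RMSE, with the rollout seeded from the initial state only.
Regional errors use the standard geometry split at two planes normal to
the bulge axis (+y by the synthetic frame convention): bulge y >= 8.5 mm,
neck 7 <= y < 8.5 mm, parent artery y < 7 mm, ties assigned upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TrainingDivergedError
from .mesh import FlowFrame, Trajectory, VolumetricMesh, probe_values
from .model import (
    EncodeProcessDecode,
    apply_boundary_conditions,
    featurize_edges,
    featurize_nodes,
)
from .synth import InflowWaveform, parabolic_inlet


# ---------------------------------------------------------------------------
# rollout
# ---------------------------------------------------------------------------

def rollout(
    model: EncodeProcessDecode,
    traj: Trajectory,
    start: int,
    n_steps: int,
    waveform: InflowWaveform,
) -> Trajectory:
    """Autoregressive n-step prediction starting from ground-truth frame
    ``start`` (and ``start - 1`` for the enhanced features)."""
    cfg = model.config
    if cfg.enhanced and start < 1:
        raise ConfigurationError("enhanced features need start >= 1")
    mesh = traj.mesh
    senders, receivers, ef = featurize_edges(mesh)
    u = traj.frames[start].velocity.copy()
    u_prev = traj.frames[start - 1].velocity.copy() if start >= 1 else None
    t = traj.frames[start].time
    frames = [FlowFrame(time=t, velocity=u.copy())]
    for k in range(n_steps):
        t_next = t + traj.dt
        inlet_next = parabolic_inlet(mesh, t_next, waveform)
        cycle_time = (t - waveform.ramp_duration) % waveform.period
        nf = featurize_nodes(
            mesh, u, cycle_time, cfg,
            velocity_prev=u_prev, inlet_velocity_next=inlet_next,
        )
        delta = model.predict_delta(nf, ef, senders, receivers)
        if not np.all(np.isfinite(delta)):
            raise TrainingDivergedError(f"non-finite prediction at rollout step {k}")
        u_next = apply_boundary_conditions(mesh, u + delta, inlet_next)
        frames.append(FlowFrame(time=t_next, velocity=u_next))
        u_prev, u, t = u, u_next, t_next
    return Trajectory(mesh=mesh, frames=frames, dt=traj.dt)


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def rmse_1(pred: np.ndarray | FlowFrame, true: np.ndarray | FlowFrame,
           mask: np.ndarray | None = None) -> float:
    """Root of the node-mean squared vector error, mm/s."""
    p = getattr(pred, "velocity", pred)
    y = getattr(true, "velocity", true)
    if mask is not None:
        p, y = p[mask], y[mask]
    return float(np.sqrt(((p - y) ** 2).sum(axis=1).mean()))


def rmse_T(pred: Trajectory, true: Trajectory, start: int = 0, T: int | None = None,
           mask: np.ndarray | None = None) -> float:
    """Mean over T rollout steps of the per-step RMSE, mm/s.

    Rollout frame k (k >= 1) is compared against ground-truth frame
    ``start + k``; the shared initial state is not scored.
    """
    if T is None:
        T = pred.n_frames - 1
    if start + T >= true.n_frames:
        raise ConfigurationError("ground truth too short for the requested window")
    vals = [
        rmse_1(pred.frames[k].velocity, true.frames[start + k].velocity, mask)
        for k in range(1, T + 1)
    ]
    return float(np.mean(vals))


def normalized_error_field(pred: np.ndarray | FlowFrame,
                           true: np.ndarray | FlowFrame) -> np.ndarray:
    """Per-node error norm as a percentage of the frame's maximum
    ground-truth speed."""
    p = getattr(pred, "velocity", pred)
    y = getattr(true, "velocity", true)
    vmax = np.linalg.norm(y, axis=1).max()
    if vmax == 0:
        raise ConfigurationError("ground-truth frame is identically zero")
    return 100.0 * np.linalg.norm(p - y, axis=1) / vmax


# ---------------------------------------------------------------------------
# region split
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Disjoint, exhaustive node masks for bulge / neck / parent artery."""

    bulge: np.ndarray
    neck: np.ndarray
    artery: np.ndarray
    bulge_plane: float = 8.5
    neck_plane: float = 7.0

    def as_dict(self):
        return {"bulge": self.bulge, "neck": self.neck, "artery": self.artery}


def region_split(
    mesh: VolumetricMesh,
    bulge_plane: float = 8.5,
    neck_plane: float = 7.0,
    axis: int = 1,
) -> RegionPartition:
    """Split nodes at two planes along the bulge axis (default y = 8.5 and
    y = 7 mm); plane ties go to the region with larger coordinate."""
    if bulge_plane <= neck_plane:
        raise ConfigurationError("bulge plane must sit above the neck plane")
    c = mesh.positions[:, axis]
    bulge = c >= bulge_plane
    neck = (c >= neck_plane) & ~bulge
    artery = ~bulge & ~neck
    return RegionPartition(bulge=bulge, neck=neck, artery=artery,
                           bulge_plane=bulge_plane, neck_plane=neck_plane)


def regional_rmse(pred, true, partition: RegionPartition,
                  extra_mask: np.ndarray | None = None) -> dict:
    """Per-region 1-RMSE values (mm/s); empty regions report NaN."""
    out = {}
    for name, mask in partition.as_dict().items():
        m = mask if extra_mask is None else mask & extra_mask
        out[name] = rmse_1(pred, true, m) if m.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    rmse_1_global: float
    rmse_T_global: float
    rmse_1_regional: dict = field(default_factory=dict)
    rmse_T_regional: dict = field(default_factory=dict)
    n_steps: int = 0
    probe_points: np.ndarray | None = None
    probe_series: np.ndarray | None = None  # (T, P, 3)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": "rmse_1", "region": "global", "mm_per_s": self.rmse_1_global},
                {"metric": f"rmse_{self.n_steps}", "region": "global",
                 "mm_per_s": self.rmse_T_global}]
        for region, v in self.rmse_1_regional.items():
            rows.append({"metric": "rmse_1", "region": region, "mm_per_s": v})
        for region, v in self.rmse_T_regional.items():
            rows.append({"metric": f"rmse_{self.n_steps}", "region": region,
                         "mm_per_s": v})
        return pd.DataFrame(rows)


def evaluate_rollout(
    model: EncodeProcessDecode,
    truth: Trajectory,
    waveform: InflowWaveform,
    start: int = 1,
    n_steps: int = 50,
    partition: RegionPartition | None = None,
    probes: np.ndarray | None = None,
) -> tuple[EvalReport, Trajectory]:
    """Roll the model out against ground truth and collect all metrics."""
    pred = rollout(model, truth, start, n_steps, waveform)
    if partition is None:
        partition = region_split(truth.mesh)
    r1 = rmse_1(pred.frames[1], truth.frames[start + 1])
    rT = rmse_T(pred, truth, start=start, T=n_steps)
    r1_reg = regional_rmse(pred.frames[1].velocity,
                           truth.frames[start + 1].velocity, partition)
    rT_reg = {
        name: np.mean([
            rmse_1(pred.frames[k].velocity, truth.frames[start + k].velocity, m)
            for k in range(1, n_steps + 1)
        ]) if m.any() else float("nan")
        for name, m in partition.as_dict().items()
    }
    series = probe_values(pred, probes) if probes is not None else None
    report = EvalReport(
        rmse_1_global=r1, rmse_T_global=rT,
        rmse_1_regional=r1_reg, rmse_T_regional=rT_reg,
        n_steps=n_steps, probe_points=probes, probe_series=series,
    )
    return report, pred
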