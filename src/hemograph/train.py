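"""Loss assembly, physics-scale calibration, schedule and the training loop.

The one-step task: from the state at frame t (optionally noised), predict
the velocity at t+1.  The data term is the mean squared vector error over
the *trainable* nodes (interior and outlet; wall and inlet nodes are
excluded structurally, so their gradients are exactly zero).  The physics
terms are built from the neighborhood operators applied to the predicted
field after boundary enforcement:

    L_continuity = mean_v | div(u~)_v |
    L_convection = mean_v || rho (u.grad)u - rho (u~.grad)u~ ||^2
    L_viscous    = mean_v || mu lap(u) - mu lap(u~) ||^2

and enter the combined loss after a one-off scale calibration,

    L = w_d L_data + ((1 - w_d)/3) (alpha L_cont + beta L_conv + gamma L_visc),

with alpha = mean(L_data)/mean(L_cont) over the calibration window (beta,
gamma analogously), so each physics term contributes at the data-term scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor, column, spmm
from .errors import ConfigurationError, TrainingDivergedError
from .mesh import INLET, WALL, Trajectory
from .model import (
    EncodeProcessDecode,
    ModelConfig,
    Normalizer,
    add_training_noise,
    featurize_edges,
    featurize_from_trajectory,
)
from .ops import FluidProperties, OperatorSet, build_operators, convective_term
from .synth import InflowWaveform, parabolic_inlet


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

@dataclass
class LossWeights:
    data_weight: float = 0.5  # w_d; the physics share (1 - w_d) splits equally
    alpha: float = 1.0  # continuity scale
    beta: float = 1.0   # convection scale
    gamma: float = 1.0  # viscous scale
    max_scale: float = 1e8

    def __post_init__(self):
        if not 0.0 <= self.data_weight <= 1.0:
            raise ConfigurationError("data weight must lie in [0, 1]")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ConfigurationError("scale factors must be >= 0")


@dataclass
class LossBreakdown:
    data: float
    continuity: float
    convection: float
    viscous: float
    total: float

    def check(self, weights: LossWeights, tol: float = 1e-12) -> None:
        w = weights.data_weight
        expected = w * self.data + (1.0 - w) / 3.0 * (
            weights.alpha * self.continuity
            + weights.beta * self.convection
            + weights.gamma * self.viscous
        )
        scale = max(abs(expected), 1.0)
        if abs(expected - self.total) > tol * scale:
            raise AssertionError("loss breakdown does not recombine to the total")


def combine_losses(data, continuity, convection, viscous, weights: LossWeights):
    """Weighted combination; works on floats and on autodiff tensors."""
    w = weights.data_weight
    physics = (
        weights.alpha * continuity
        + weights.beta * convection
        + weights.gamma * viscous
    )
    return w * data + ((1.0 - w) / 3.0) * physics


def train_mask(node_type: np.ndarray) -> np.ndarray:
    """Trainable nodes: interior and outlet (walls and inlet excluded)."""
    return (node_type != WALL) & (node_type != INLET)


def data_loss(pred, true: np.ndarray, mask: np.ndarray):
    """Mean over masked nodes of the squared vector error (mm^2/s^2).

    ``pred`` may be a plain array or an autodiff tensor (used in training).
    """
    idx = np.flatnonzero(mask)
    if isinstance(pred, Tensor):
        err = ad.gather(pred, idx) - true[idx]
        return err.square().sum() * (1.0 / idx.size)
    err = pred[mask] - true[mask]
    return float((err**2).sum() / idx.size)


def continuity_loss(pred, operators: OperatorSet):
    """Mean absolute discrete divergence of the predicted field (1/s)."""
    G = operators.G
    if isinstance(pred, Tensor):
        div = sum(spmm(G[b], column(pred, b)) for b in range(3))
        return div.abs().mean()
    div = sum(G[b] @ pred[:, b] for b in range(3))
    return float(np.abs(div).mean())


def convection_loss(pred, true_term: np.ndarray, operators: OperatorSet,
                    props: FluidProperties):
    """Mean squared norm of rho (u.grad)u mismatch, truth term precomputed."""
    G = operators.G
    rho = props.density
    if isinstance(pred, Tensor):
        cols = [column(pred, b) for b in range(3)]
        sq = None
        for a in range(3):
            conv_a = sum(cols[b] * spmm(G[b], cols[a]) for b in range(3)) * rho
            err = conv_a - true_term[:, a]
            sq = err.square() if sq is None else sq + err.square()
        return sq.mean()
    # numpy path mirrors the truth-term computation exactly, so a perfect
    # prediction yields an exact zero
    conv = convective_term(pred, operators.positions, operators.table, rho)
    return float(((conv - true_term) ** 2).sum(axis=1).mean())


def viscous_loss(pred, true_term: np.ndarray, operators: OperatorSet,
                 props: FluidProperties):
    """Mean squared norm of mu lap(u) mismatch, truth term precomputed."""
    L = operators.laplacian
    mu = props.viscosity
    if isinstance(pred, Tensor):
        sq = None
        for a in range(3):
            err = spmm(L, column(pred, a)) * mu - true_term[:, a]
            sq = err.square() if sq is None else sq + err.square()
        return sq.mean()
    visc = mu * (L @ pred)
    return float(((visc - true_term) ** 2).sum(axis=1).mean())


def physics_truth_terms(u_true: np.ndarray, mesh, operators: OperatorSet,
                        props: FluidProperties):
    """(convection, viscous) reference terms of the ground-truth field."""
    conv = convective_term(u_true, mesh.positions, operators.table, props.density)
    visc = props.viscosity * (operators.laplacian @ u_true)
    return conv, visc


def calibrate_scales(loss_means: dict, weights: LossWeights) -> LossWeights:
    """Freeze alpha/beta/gamma so each physics term matches the data scale.

    ``loss_means`` holds mean values of the four raw terms over the
    calibration sample.  A vanishing physics term gets the configured
    maximum scale with a warning.
    """
    out = {}
    for name, key in (("alpha", "continuity"), ("beta", "convection"),
                      ("gamma", "viscous")):
        denom = loss_means[key]
        if denom <= 0:
            warnings.warn(f"{key} loss vanished during calibration; "
                          f"capping its scale at {weights.max_scale:g}", stacklevel=2)
            out[name] = weights.max_scale
        else:
            out[name] = min(loss_means["data"] / denom, weights.max_scale)
    return LossWeights(data_weight=weights.data_weight,
                       max_scale=weights.max_scale, **out)


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

@dataclass
class ScheduleConfig:
    lr: float = 1e-4
    lr_min: float = 1e-7
    constant_epochs: int = 16
    decay_epochs: int = 4
    steps_per_epoch: int = 1


def lr_schedule(step: int, config: ScheduleConfig) -> float:
    """Fixed rate through the constant epochs, then per-step exponential
    decay reaching ``lr_min`` on the last decay step."""
    spe = config.steps_per_epoch
    cutoff = config.constant_epochs * spe
    if step < cutoff:
        return config.lr
    n_decay = max(1, config.decay_epochs * spe)
    k = min(step - cutoff + 1, n_decay)
    return config.lr * (config.lr_min / config.lr) ** (k / n_decay)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 20
    max_steps: int | None = None
    physics: bool = False
    weights: LossWeights = field(default_factory=LossWeights)
    schedule: ScheduleConfig | None = None
    lr: float | None = None  # overrides the schedule with a constant rate
    calibration_steps: int = 200
    noise_anneal_to: float | None = None  # linearly anneal eta to this value
    anneal_total: int | None = None  # steps over which to anneal (default: max_steps)
    props: FluidProperties = field(default_factory=FluidProperties)
    target_rmse: float | None = None  # early stop on masked 1-step RMSE
    eval_every: int = 25
    clip_norm: float = 1.0
    log_every: int = 10


@dataclass
class _Sample:
    traj: Trajectory
    t: int
    features: np.ndarray
    target_next: np.ndarray
    bc_next: np.ndarray  # wall zeros + prescribed inlet at t+1, rest 0
    traj_key: int = 0


class _TrainingState:
    """Per-mesh precomputation shared across samples."""

    def __init__(self, trajectories, config_model: ModelConfig,
                 waveform: InflowWaveform | None, physics: bool):
        self.edges = {}
        self.operators = {}
        for k, traj in enumerate(trajectories):
            self.edges[k] = featurize_edges(traj.mesh)
            if physics:
                self.operators[k] = build_operators(traj.mesh)


def _bc_field(mesh, inlet_field):
    bc = np.zeros((mesh.n_nodes, 3))
    inlet = mesh.node_type == INLET
    bc[inlet] = inlet_field[inlet]
    return bc


def masked_rmse(model: EncodeProcessDecode, samples, state, mask_by_traj) -> float:
    """One-step masked RMSE (mm/s) over a list of samples, noise-free."""
    total, count = 0.0, 0
    for s in samples:
        senders, receivers, ef = state.edges[s.traj_key]
        delta = model.predict_delta(s.features, ef, senders, receivers)
        pred = s.features[:, 0:3] + delta
        mask = mask_by_traj[s.traj_key]
        err = pred[mask] - s.target_next[mask]
        total += float((err**2).sum())
        count += int(mask.sum())
    return float(np.sqrt(total / count))


def train(
    model: EncodeProcessDecode,
    trajectories: list[Trajectory],
    config: TrainConfig,
    seed: int = 0,
    waveform: InflowWaveform | None = None,
) -> pd.DataFrame:
    """Optimize the model on the one-step task; returns the loss history.

    One optimization step per (trajectory, t) sample; Gaussian noise on the
    dynamical input features only; seeded shuffling; deterministic given the
    seed in single-threaded execution.  Raises
    :class:`TrainingDivergedError` on a non-finite loss.
    """
    cfg_m = model.config
    t_min = 1 if cfg_m.enhanced else 0
    for traj in trajectories:
        if traj.n_frames < t_min + 2:
            raise ConfigurationError(
                "trajectories need at least "
                f"{t_min + 2} frames for the configured features"
            )
    state = _TrainingState(trajectories, cfg_m, waveform, config.physics)

    # assemble samples (features are rebuilt when noise is applied)
    samples = []
    mask_by_traj = {}
    for k, traj in enumerate(trajectories):
        mask_by_traj[k] = train_mask(traj.mesh.node_type)
        for t in range(t_min, traj.n_frames - 1):
            feats = featurize_from_trajectory(traj, t, cfg_m, waveform)
            t_next = traj.frames[t].time + traj.dt
            if waveform is not None:
                inlet_next = parabolic_inlet(traj.mesh, t_next, waveform)
            else:
                inlet_next = traj.frames[t + 1].velocity
            s = _Sample(
                traj=traj, t=t, features=feats,
                target_next=traj.frames[t + 1].velocity,
                bc_next=_bc_field(traj.mesh, inlet_next),
            )
            s.traj_key = k
            samples.append(s)
    if not samples:
        raise ConfigurationError("no training samples")
    steps_per_epoch = len(samples)

    # normalization statistics: accumulated over the epoch-1 sample order,
    # then frozen before the first optimizer step
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    if not model.normalizer.frozen:
        norm = model.normalizer
        for i in order:
            s = samples[i]
            _, _, ef = state.edges[s.traj_key]
            norm.accumulate(s.features, ef, s.target_next - s.features[:, 0:3])
        norm.freeze()
    sigma_v = model.normalizer.velocity_std

    schedule = config.schedule or ScheduleConfig(steps_per_epoch=steps_per_epoch)
    if config.schedule is None:
        schedule.steps_per_epoch = steps_per_epoch
    opt = Adam(model.parameters(), lr=schedule.lr, clip_norm=config.clip_norm)

    # physics truth terms are static per sample; cache them
    truth_cache = {}

    def truth_terms(s):
        key = (s.traj_key, s.t)
        if key not in truth_cache:
            truth_cache[key] = physics_truth_terms(
                s.target_next, s.traj.mesh, state.operators[s.traj_key], config.props
            )
        return truth_cache[key]

    weights = config.weights
    calibrating = config.physics
    calib_acc = {"data": [], "continuity": [], "convection": [], "viscous": []}

    history = []
    step = 0
    stop = False
    max_steps = config.max_steps or config.epochs * steps_per_epoch
    for epoch in range(config.epochs):
        if stop:
            break
        order = rng.permutation(len(samples)) if epoch > 0 else order
        for i in order:
            s = samples[i]
            mesh = s.traj.mesh
            senders, receivers, ef = state.edges[s.traj_key]
            eta = cfg_m.noise_scale
            total = config.anneal_total or max_steps
            if config.noise_anneal_to is not None and total > 1:
                frac = min(step / (total - 1), 1.0)
                eta = eta + (config.noise_anneal_to - eta) * frac
            feats = add_training_noise(s.features, eta, sigma_v, rng, cfg_m)
            out = model.forward(feats, ef, senders, receivers)
            mask = mask_by_traj[s.traj_key]
            # the data term is optimized on the network's normalized output
            # scale (keeps gradient norms O(1) so clipping acts as a mild
            # stabilizer); reported values are in physical units
            target_norm = (
                (s.target_next - feats[:, 0:3]) - model.normalizer.out_mean
            ) / model.normalizer.out_std
            l_data = data_loss(out, target_norm, mask)
            pred_phys = (out.data.astype(np.float64) * model.normalizer.out_std
                         + model.normalizer.out_mean + feats[:, 0:3])
            l_data_phys = data_loss(pred_phys, s.target_next, mask)

            if config.physics:
                delta = out * model.normalizer.out_std + model.normalizer.out_mean
                u_free = delta + feats[:, 0:3]
                keep = mask.astype(np.float64)[:, None]
                u_bc = u_free * keep + s.bc_next
                operators = state.operators[s.traj_key]
                conv_true, visc_true = truth_terms(s)
                l_cont = continuity_loss(u_bc, operators)
                l_conv = convection_loss(u_bc, conv_true, operators, config.props)
                l_visc = viscous_loss(u_bc, visc_true, operators, config.props)
                if calibrating:
                    calib_acc["data"].append(float(l_data.data))
                    calib_acc["continuity"].append(float(l_cont.data))
                    calib_acc["convection"].append(float(l_conv.data))
                    calib_acc["viscous"].append(float(l_visc.data))
                    loss = l_data  # data-only until the scales are frozen
                    if len(calib_acc["data"]) >= min(config.calibration_steps,
                                                     steps_per_epoch * 2):
                        weights = calibrate_scales(
                            {k: float(np.mean(v)) for k, v in calib_acc.items()},
                            weights,
                        )
                        calibrating = False
                else:
                    loss = combine_losses(l_data, l_cont, l_conv, l_visc, weights)
                breakdown = LossBreakdown(
                    data=float(l_data.data), continuity=float(l_cont.data),
                    convection=float(l_conv.data), viscous=float(l_visc.data),
                    total=combine_losses(
                        float(l_data.data), float(l_cont.data),
                        float(l_conv.data), float(l_visc.data), weights),
                )
            else:
                loss = l_data
                breakdown = LossBreakdown(
                    data=float(l_data.data), continuity=0.0, convection=0.0,
                    viscous=0.0, total=float(l_data.data) * weights.data_weight,
                )

            if not np.isfinite(float(loss.data)):
                raise TrainingDivergedError(
                    f"non-finite loss at step {step}",
                    diagnostics={"step": step, "epoch": epoch,
                                 "breakdown": breakdown},
                )
            opt.zero_grad()
            loss.backward(np.asarray(1.0, dtype=model.dtype))
            opt.lr = config.lr if config.lr is not None else lr_schedule(step, schedule)
            opt.step()

            if step % config.log_every == 0 or step == max_steps - 1:
                history.append({
                    "step": step, "epoch": epoch, "lr": opt.lr,
                    "loss": float(loss.data), "data": breakdown.data,
                    "data_mm2_s2": l_data_phys,
                    "continuity": breakdown.continuity,
                    "convection": breakdown.convection,
                    "viscous": breakdown.viscous,
                })
            step += 1
            if config.target_rmse is not None and step % config.eval_every == 0:
                rmse = masked_rmse(model, samples, state, mask_by_traj)
                if rmse < config.target_rmse:
                    stop = True
                    break
            if step >= max_steps:
                stop = True
                break

    df = pd.DataFrame(history)
    df.attrs["weights"] = weights
    df.attrs["steps"] = step
    df.attrs["final_rmse"] = masked_rmse(model, samples, state, mask_by_traj)
    return df
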