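"""Desk-scale overfit-and-rollout benchmark harness.

A deliberately small, fully deterministic end-to-end exercise of the
pipeline: a straight-tube stand-in geometry (~2k nodes), one full cardiac
cycle sampled with 10 frames (dt = 0.08 s), and a narrow surrogate (width
32, 4 message-passing rounds, enhanced features) trained on the one-step
task.  The trained model is rolled out autoregressively for 50 steps
against the periodic extension of the same analytic flow; sampling the
whole cycle with the 10 training frames keeps every rollout step inside
the training distribution (timestamp and inflow context are
cycle-periodic).

Training noise here follows an annealed curriculum (eta from 0.4 down to
0.15 of the velocity std): with only 9 training samples the rollout
re-enters each systole carrying drift of tens of mm/s, so early training
uses noise at that perturbation scale to shape a contracting map, and the
scale then decays so the final model keeps a sharp noise-free next-step
prediction — the noise-matching rule for autoregressive mesh simulators,
applied as a schedule because a single scale cannot serve both goals with
so few samples.

The harness exists because full-scale training (hours of GPU time on the
105-case benchmark) is not a sensible unit of verification; convergence of
the same code path at small scale is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .evaluate import rmse_T, rollout
from .mesh import Trajectory, VolumetricMesh
from .model import EncodeProcessDecode, ModelConfig
from .synth import InflowWaveform, make_analytic_trajectory, make_tube_mesh
from .train import ScheduleConfig, TrainConfig, train

PEAK_INLET_VELOCITY = 2.0 * 6000.0 / (np.pi * 4.0)  # 2 Q_peak / (pi R^2), mm/s


@dataclass
class HarnessSpec:
    """Study conditions of the desk-scale benchmark."""

    radius: float = 2.0          # mm
    length: float = 10.0         # mm
    h: float = 0.45              # mm -> ~2.3k nodes
    n_frames_per_cycle: int = 10
    latent_width: int = 32
    rounds: int = 4
    max_steps: int = 2000
    lr: float = 1e-3
    lr_min: float = 1e-5
    constant_fraction: float = 0.6  # of max_steps before the decay starts
    rollout_steps: int = 50
    dtype: str = "float32"
    noise_scale: float = 0.4       # initial eta
    noise_anneal_to: float = 0.15  # eta at the last step
    physics_weight: float = 0.5    # w_d when training physics-informed


@dataclass
class HarnessResult:
    mesh: VolumetricMesh
    waveform: InflowWaveform
    truth: Trajectory            # periodic extension covering the rollout
    model: EncodeProcessDecode
    history: object              # loss-history DataFrame
    steps: int
    one_step_rmse: float         # mm/s, masked, noise-free
    rollout_rmse: float | None = None  # mm/s, T-step
    peak_velocity: float = PEAK_INLET_VELOCITY


def build_harness_data(spec: HarnessSpec | None = None):
    """Mesh, waveform, 10-frame training trajectory and long ground truth."""
    spec = spec or HarnessSpec()
    mesh = make_tube_mesh(radius=spec.radius, length=spec.length, h=spec.h)
    waveform = InflowWaveform()
    dt = waveform.period / spec.n_frames_per_cycle
    short = make_analytic_trajectory(mesh, waveform, dt=dt, n_cycles=1.0)
    n_cycles_long = 1 + math.ceil(
        (spec.rollout_steps + 2) * dt / waveform.period
    )
    long = make_analytic_trajectory(mesh, waveform, dt=dt,
                                    n_cycles=n_cycles_long)
    return mesh, waveform, short, long


def run_harness(
    seed: int = 1,
    physics: bool = False,
    spec: HarnessSpec | None = None,
    max_steps: int | None = None,
    schedule_steps: int | None = None,
    do_rollout: bool = True,
    data: tuple | None = None,
) -> HarnessResult:
    """Train the benchmark model (data-only or physics-informed) and
    optionally roll it out; deterministic given the seed.

    ``schedule_steps`` derives the learning-rate and noise schedules from a
    longer nominal run, so a short run is an exact truncation of the long
    one (used for like-for-like loss comparisons at a fixed budget).
    """
    spec = spec or HarnessSpec()
    mesh, waveform, short, long = data if data is not None else build_harness_data(spec)
    steps = max_steps if max_steps is not None else spec.max_steps
    nominal = schedule_steps if schedule_steps is not None else steps
    cfg = ModelConfig(
        latent_width=spec.latent_width,
        message_passing_rounds=spec.rounds,
        features="in",
        dtype=spec.dtype,
        noise_scale=spec.noise_scale,
    )
    model = EncodeProcessDecode(cfg, seed=seed)
    n_samples = short.n_frames - 2  # enhanced features need t >= 1
    const_epochs = max(1, round(spec.constant_fraction * nominal / n_samples))
    decay_epochs = max(1, math.ceil(nominal / n_samples) - const_epochs)
    schedule = ScheduleConfig(
        lr=spec.lr, lr_min=spec.lr_min,
        constant_epochs=const_epochs, decay_epochs=decay_epochs,
        steps_per_epoch=n_samples,
    )
    tcfg = TrainConfig(
        epochs=10 * (steps // n_samples + 1),  # step cap governs
        max_steps=steps,
        schedule=schedule,
        physics=physics,
        noise_anneal_to=spec.noise_anneal_to,
        anneal_total=nominal,
        target_rmse=None,
        eval_every=10**9,
        log_every=10,
    )
    history = train(model, [short], tcfg, seed=seed, waveform=waveform)
    result = HarnessResult(
        mesh=mesh, waveform=waveform, truth=long, model=model,
        history=history, steps=int(history.attrs["steps"]),
        one_step_rmse=float(history.attrs["final_rmse"]),
    )
    if do_rollout:
        pred = rollout(model, long, start=1, n_steps=spec.rollout_steps,
                       waveform=waveform)
        result.rollout_rmse = rmse_T(pred, long, start=1,
                                     T=spec.rollout_steps)
    return result
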