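"""Validated YAML run configuration with seed fan-out.

A single global seed is derived into independent per-stage seeds via
``numpy.random.SeedSequence`` spawning with fixed stage indices, so any
stage can be re-run on its own and still reproduce.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigurationError

_STAGES = ("generate", "train", "rollout", "post")


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vessel_diameter: float = 4.0
    torus_major_radius: float = 10.0
    bulge_diameter_range: tuple[float, float] = (3.0, 9.0)
    target_edge_length: float = 0.3


class WaveformConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    period: float = 0.8
    ramp_duration: float = 0.2
    peak_flow: float = 6.0


class DataConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    root: str = "data"
    n_cases: int = 4
    n_test: int = 1
    dt: float = 0.01
    n_cycles: float = 1.0
    kind: str = "quasi-steady-poiseuille"
    format: str = "hdf5"


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    latent_width: int = 128
    mlp_hidden_layers: int = 2
    message_passing_rounds: int = 15
    features: str = "in"
    noise_scale: float = 0.02
    dtype: str = "float64"


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = 20
    max_steps: int | None = None
    physics: bool = False
    data_weight: float = 0.5
    lr: float | None = None
    target_rmse: float | None = None
    checkpoint: str = "model.npz"


class EvaluationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: int = 1
    n_steps: int = 50
    bulge_plane: float = 8.5
    neck_plane: float = 7.0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    log_level: str = "INFO"
    data: DataConfig = Field(default_factory=DataConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    waveform: WaveformConfig = Field(default_factory=WaveformConfig)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        if stage not in _STAGES:
            raise ConfigurationError(f"unknown stage '{stage}'")
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))
        return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except Exception as e:  # pydantic validation
        raise ConfigurationError(str(e)) from e
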