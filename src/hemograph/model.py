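"""Featurization and the encode-process-decode graph-network surrogate.

The surrogate learns one-step velocity dynamics on the mesh graph: node and
edge features are encoded into latent vectors, L rounds of message passing
(edge update from the incident node latents, sum aggregation at receivers,
node update) propagate information, and a decoder emits a per-node velocity
update added to the current state.  Boundary conditions are imposed after
every step: wall nodes are zeroed and inlet nodes carry the prescribed
parabolic profile.

Feature sets
------------
baseline (11): velocity (3), position (3), timestamp (1), node-type one-hot
    (4, order inlet/wall/interior/outlet).
"in" (17): baseline + acceleration u_t - u_{t-1} (3) + inflow context (3):
    mean/min/max inlet speed at the *target* time t+1, broadcast to every
    node (the inlet boundary condition is known ahead of time).

Each undirected mesh edge is stored in both directions with features
[receiver - sender coordinates (3), Euclidean distance (1)].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Parameter, Tensor, layer_norm, no_grad, spmm
from .errors import ConfigurationError, StructuralError
from .mesh import (
    INLET,
    N_NODE_TYPES,
    WALL,
    FlowFrame,
    Trajectory,
    VolumetricMesh,
    extract_edges,
)
from .synth import InflowWaveform, parabolic_inlet

FEATURE_SETS = {"baseline": 11, "in": 17}
EDGE_FEATURES = 4
VELOCITY_COLS = slice(0, 3)
ACCELERATION_COLS = slice(11, 14)  # only present in the "in" feature set


@dataclass
class ModelConfig:
    """Architecture and featurization switches.

    Defaults follow the reference configuration: width-128 MLPs with two
    hidden layers, 15 rounds of message passing, ReLU activations, sum
    aggregation, residual connections and layer normalization after every
    MLP except the decoder.
    """

    latent_width: int = 128
    mlp_hidden_layers: int = 2
    message_passing_rounds: int = 15
    features: str = "in"  # "baseline" or "in"
    noise_scale: float = 0.02  # eta: training-noise std as fraction of velocity std
    dtype: str = "float64"

    def __post_init__(self):
        if self.message_passing_rounds < 1 or self.latent_width < 1:
            raise ConfigurationError("rounds and width must be >= 1")
        if self.features not in FEATURE_SETS:
            raise ConfigurationError(f"features must be one of {list(FEATURE_SETS)}")

    @property
    def node_feature_width(self) -> int:
        return FEATURE_SETS[self.features]

    @property
    def enhanced(self) -> bool:
        return self.features == "in"


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def one_hot_types(node_type: np.ndarray) -> np.ndarray:
    out = np.zeros((node_type.shape[0], N_NODE_TYPES))
    out[np.arange(node_type.shape[0]), node_type] = 1.0
    return out


def inflow_context(inlet_velocity_next: np.ndarray, inlet_mask: np.ndarray) -> np.ndarray:
    """(mean, min, max) inlet speed at the target time, as a 3-vector."""
    speeds = np.linalg.norm(inlet_velocity_next[inlet_mask], axis=1)
    if speeds.size == 0:
        raise StructuralError("mesh has no inlet nodes")
    return np.array([speeds.mean(), speeds.min(), speeds.max()])


def featurize_nodes(
    mesh: VolumetricMesh,
    velocity: np.ndarray,
    time_in_cycle: float,
    config: ModelConfig,
    velocity_prev: np.ndarray | None = None,
    inlet_velocity_next: np.ndarray | None = None,
) -> np.ndarray:
    """Node feature matrix (N, 11) or (N, 17).

    The enhanced set needs the previous-step velocity (for the t-1 -> t
    acceleration) and the prescribed inlet field at t+1 (for the inflow
    context); both are preconditions, not silent defaults.
    """
    n = mesh.n_nodes
    cols = [
        velocity,
        mesh.positions,
        np.full((n, 1), time_in_cycle),
        one_hot_types(mesh.node_type),
    ]
    if config.enhanced:
        if velocity_prev is None:
            raise ConfigurationError(
                "enhanced features need the previous frame (t >= 1)"
            )
        if inlet_velocity_next is None:
            raise ConfigurationError(
                "enhanced features need the prescribed inlet field at t+1"
            )
        ctx = inflow_context(inlet_velocity_next, mesh.node_type == INLET)
        cols.append(velocity - velocity_prev)
        cols.append(np.broadcast_to(ctx, (n, 3)))
    out = np.concatenate([np.asarray(c, dtype=np.float64) for c in cols], axis=1)
    assert out.shape[1] == config.node_feature_width
    return out


def featurize_from_trajectory(
    traj: Trajectory,
    t: int,
    config: ModelConfig,
    waveform: InflowWaveform | None = None,
) -> np.ndarray:
    """Features for frame index t of a trajectory (target is frame t+1).

    The inflow context uses the prescribed profile when a waveform is given
    and otherwise the ground-truth frame at t+1.
    """
    if config.enhanced and t < 1:
        raise ConfigurationError("enhanced features need t >= 1")
    prev = traj.frames[t - 1].velocity if (config.enhanced and t >= 1) else None
    nxt = None
    if config.enhanced:
        if waveform is not None:
            nxt = parabolic_inlet(traj.mesh, traj.frames[t].time + traj.dt, waveform)
        elif t + 1 < traj.n_frames:
            nxt = traj.frames[t + 1].velocity
        else:
            raise ConfigurationError("no source for the inflow context at t+1")
    cycle_time = traj.frames[t].time
    if waveform is not None:
        cycle_time = (traj.frames[t].time - waveform.ramp_duration) % waveform.period
    return featurize_nodes(
        traj.mesh, traj.frames[t].velocity, cycle_time, config,
        velocity_prev=prev, inlet_velocity_next=nxt,
    )


def featurize_edges(mesh: VolumetricMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed edges and their features.

    Returns (senders, receivers, features) where each undirected mesh edge
    appears once per direction and features are
    [receiver - sender coordinates, distance].
    """
    und = extract_edges(mesh)
    senders = np.concatenate([und[:, 0], und[:, 1]])
    receivers = np.concatenate([und[:, 1], und[:, 0]])
    rel = mesh.positions[receivers] - mesh.positions[senders]
    dist = np.linalg.norm(rel, axis=1, keepdims=True)
    if np.any(dist == 0):
        raise StructuralError("zero-length edge")
    return senders, receivers, np.concatenate([rel, dist], axis=1)


def add_training_noise(
    features: np.ndarray,
    eta: float,
    velocity_std: float,
    rng: np.random.Generator,
    config: ModelConfig,
) -> np.ndarray:
    """Gaussian noise (std eta * velocity_std per component) on the dynamical
    columns only: velocity, plus acceleration when present."""
    if eta < 0:
        raise ConfigurationError("noise scale must be >= 0")
    if eta == 0:
        return features
    out = features.copy()
    scale = eta * velocity_std
    out[:, VELOCITY_COLS] += rng.normal(0.0, scale, size=(features.shape[0], 3))
    if features.shape[1] == FEATURE_SETS["in"]:
        out[:, ACCELERATION_COLS] += rng.normal(0.0, scale, size=(features.shape[0], 3))
    return out


# ---------------------------------------------------------------------------
# normalization statistics
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    """Per-feature standardization statistics, frozen after accumulation."""

    node_mean: np.ndarray | None = None
    node_std: np.ndarray | None = None
    edge_mean: np.ndarray | None = None
    edge_std: np.ndarray | None = None
    out_mean: np.ndarray | None = None
    out_std: np.ndarray | None = None
    velocity_std: float = 1.0
    _count: int = 0
    _sums: dict = field(default_factory=dict, repr=False)

    def accumulate(self, node_f, edge_f, target):
        s = self._sums
        for key, arr in (("node", node_f), ("edge", edge_f), ("out", target)):
            s.setdefault(key + "_n", 0)
            s.setdefault(key + "_s", np.zeros(arr.shape[1]))
            s.setdefault(key + "_ss", np.zeros(arr.shape[1]))
            s[key + "_n"] += arr.shape[0]
            s[key + "_s"] += arr.sum(axis=0)
            s[key + "_ss"] += (arr**2).sum(axis=0)
        s.setdefault("vel_n", 0)
        s.setdefault("vel_s", 0.0)
        s.setdefault("vel_ss", 0.0)
        v = node_f[:, VELOCITY_COLS]
        s["vel_n"] += v.size
        s["vel_s"] += v.sum()
        s["vel_ss"] += (v**2).sum()

    def freeze(self, floor: float = 1e-8):
        """Finalize statistics.  Components of a physical vector (velocity,
        acceleration, relative coordinates, the output update) share one
        pooled standard deviation, so a flow aligned with a coordinate axis
        cannot produce degenerate per-axis scales that blow up injected
        noise."""
        s = self._sums
        for key in ("node", "edge", "out"):
            n = s[key + "_n"]
            mean = s[key + "_s"] / n
            var = np.maximum(s[key + "_ss"] / n - mean**2, 0.0)
            width = mean.shape[0]
            if key == "node":
                blocks = [(0, 3)] + ([(11, 14)] if width == 17 else [])
            elif key == "edge":
                blocks = [(0, 3)]
            else:
                blocks = [(0, width)]
            for a, b in blocks:
                var[a:b] = var[a:b].mean()
            std = np.maximum(np.sqrt(var), floor)
            setattr(self, key + "_mean", mean)
            setattr(self, key + "_std", std)
        vmean = s["vel_s"] / s["vel_n"]
        self.velocity_std = float(
            max(np.sqrt(max(s["vel_ss"] / s["vel_n"] - vmean**2, 0.0)), floor)
        )
        self._sums = {}

    @property
    def frozen(self) -> bool:
        return self.node_mean is not None


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _mlp_params(rng, sizes, dtype, layernorm: bool):
    """Glorot-uniform weights for a chain of linear layers."""
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        W = Parameter(rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(dtype))
        b = Parameter(np.zeros(fan_out, dtype=dtype))
        layers.append((W, b))
    ln = None
    if layernorm:
        ln = (
            Parameter(np.ones(sizes[-1], dtype=dtype)),
            Parameter(np.zeros(sizes[-1], dtype=dtype)),
        )
    return {"layers": layers, "ln": ln}


def _mlp_forward(params, x: Tensor) -> Tensor:
    layers = params["layers"]
    for k, (W, b) in enumerate(layers):
        x = ad.linear(x, W, b)
        if k < len(layers) - 1:
            x = x.relu()
    if params["ln"] is not None:
        x = layer_norm(x, *params["ln"])
    return x


def mlp_parameter_count(in_width: int, width: int, hidden_layers: int,
                        out_width: int, layernorm: bool) -> int:
    sizes = [in_width] + [width] * hidden_layers + [out_width]
    n = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
    return n + (2 * out_width if layernorm else 0)


def count_parameters(config: ModelConfig) -> int:
    """Closed-form parameter count of the architecture."""
    w, h = config.latent_width, config.mlp_hidden_layers
    total = mlp_parameter_count(config.node_feature_width, w, h, w, True)
    total += mlp_parameter_count(EDGE_FEATURES, w, h, w, True)
    total += config.message_passing_rounds * (
        mlp_parameter_count(3 * w, w, h, w, True)   # edge update phi_E
        + mlp_parameter_count(2 * w, w, h, w, True)  # node update phi_V
    )
    total += mlp_parameter_count(w, w, h, 3, False)  # decoder
    return total


class EncodeProcessDecode:
    """The graph-network surrogate: shared encoders, L GN blocks with
    per-block parameters and residual connections, and a velocity-update
    decoder."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 normalizer: Normalizer | None = None):
        self.config = config
        self.normalizer = normalizer or Normalizer()
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        w, h = config.latent_width, config.mlp_hidden_layers

        def mlp(in_w, out_w, ln=True):
            return _mlp_params(rng, [in_w] + [w] * h + [out_w], self.dtype, ln)

        self.node_encoder = mlp(config.node_feature_width, w)
        self.edge_encoder = mlp(EDGE_FEATURES, w)
        self.blocks = [
            {"edge": mlp(3 * w, w), "node": mlp(2 * w, w)}
            for _ in range(config.message_passing_rounds)
        ]
        self.decoder = mlp(w, 3, ln=False)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        out = []

        def collect(p):
            for W, b in p["layers"]:
                out.extend([W, b])
            if p["ln"] is not None:
                out.extend(p["ln"])

        collect(self.node_encoder)
        collect(self.edge_encoder)
        for blk in self.blocks:
            collect(blk["edge"])
            collect(blk["node"])
        collect(self.decoder)
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward ------------------------------------------------------------

    def _graph_matrices(self, senders, receivers, n_nodes):
        e = senders.shape[0]
        ones = np.ones(e, dtype=self.dtype)
        S = sp.csr_matrix((ones, (np.arange(e), senders)), shape=(e, n_nodes))
        R = sp.csr_matrix((ones, (np.arange(e), receivers)), shape=(e, n_nodes))
        return S, R

    def forward(
        self,
        node_features: np.ndarray,
        edge_features: np.ndarray,
        senders: np.ndarray,
        receivers: np.ndarray,
    ) -> Tensor:
        """Decoded per-node update in *normalized* output units (N, 3)."""
        norm = self.normalizer
        if not norm.frozen:
            raise ConfigurationError("normalizer statistics are not frozen yet")
        nf = ((node_features - norm.node_mean) / norm.node_std).astype(self.dtype)
        ef = ((edge_features - norm.edge_mean) / norm.edge_std).astype(self.dtype)
        n = nf.shape[0]
        S, R = self._graph_matrices(senders, receivers, n)
        RT = R.T.tocsr()
        v = _mlp_forward(self.node_encoder, Tensor(nf))
        e = _mlp_forward(self.edge_encoder, Tensor(ef))
        for blk in self.blocks:
            e_in = ad.concat([e, spmm(S, v), spmm(R, v)], axis=1)
            e = e + _mlp_forward(blk["edge"], e_in)  # residual on edges
            agg = spmm(RT, e)
            v = v + _mlp_forward(blk["node"], ad.concat([v, agg], axis=1))
        return _mlp_forward(self.decoder, v)

    def predict_delta(self, node_features, edge_features, senders, receivers) -> np.ndarray:
        """Physical velocity update (N, 3) in mm/s (denormalized), no tape."""
        with no_grad():
            out = self.forward(node_features, edge_features, senders, receivers)
        return out.data.astype(np.float64) * self.normalizer.out_std + self.normalizer.out_mean

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights + config + normalization stats."""
        arrays = {f"p{k}": p.data for k, p in enumerate(self.parameters())}
        norm = {
            k: getattr(self.normalizer, k).tolist()
            for k in ("node_mean", "node_std", "edge_mean", "edge_std",
                      "out_mean", "out_std")
            if getattr(self.normalizer, k) is not None
        }
        norm["velocity_std"] = self.normalizer.velocity_std
        meta = json.dumps({"config": asdict(self.config), "normalizer": norm})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "EncodeProcessDecode":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            config = ModelConfig(**meta["config"])
            model = cls(config, seed=0)
            norm = meta["normalizer"]
            for k in ("node_mean", "node_std", "edge_mean", "edge_std",
                      "out_mean", "out_std"):
                if k in norm:
                    setattr(model.normalizer, k, np.asarray(norm[k]))
            model.normalizer.velocity_std = norm.get("velocity_std", 1.0)
            for k, p in enumerate(model.parameters()):
                p.data = z[f"p{k}"].astype(model.dtype)
        return model


# ---------------------------------------------------------------------------
# one-step prediction with boundary enforcement
# ---------------------------------------------------------------------------

def apply_boundary_conditions(
    mesh: VolumetricMesh,
    velocity: np.ndarray,
    inlet_velocity: np.ndarray,
) -> np.ndarray:
    """Exact BC overwrite: wall rows zero, inlet rows prescribed."""
    out = velocity.copy()
    out[mesh.node_type == WALL] = 0.0
    inlet = mesh.node_type == INLET
    out[inlet] = inlet_velocity[inlet]
    return out


def predict_next(
    model: EncodeProcessDecode,
    traj: Trajectory,
    t: int,
    waveform: InflowWaveform,
) -> FlowFrame:
    """One-step prediction u_{t+1} = u_t + decoded update, with wall and
    inlet values overwritten by the prescribed boundary conditions."""
    mesh = traj.mesh
    nf = featurize_from_trajectory(traj, t, model.config, waveform)
    senders, receivers, ef = featurize_edges(mesh)
    delta = model.predict_delta(nf, ef, senders, receivers)
    u_next = traj.frames[t].velocity + delta
    t_next = traj.frames[t].time + traj.dt
    inlet_field = parabolic_inlet(mesh, t_next, waveform)
    return FlowFrame(
        time=t_next,
        velocity=apply_boundary_conditions(mesh, u_next, inlet_field),
    )
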