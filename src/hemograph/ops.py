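"""Neighborhood finite-difference operators and continuum quantities.

The gradient estimator is the averaged rank-one form over mesh-edge
neighborhoods

    grad(u)_i = (1/|N_i|) * sum_{j in N_i} (u_j - u_i) (x_j - x_i)^T / ||x_j - x_i||^2

with the divergence its contraction and the vector Laplacian obtained by
applying the same estimator to each nodal gradient component and taking the
trace.  The estimator is implemented *as defined*, including its scaling
behavior (a uniform 6-axis stencil gives div(x, y, z) = 1, not the continuum
value 3): the physics-informed training losses are built from these exact
operators, so consistency with the continuum is deliberately not patched in.
A least-squares gradient is available behind ``method="least_squares"`` for
comparison only.

All operators are linear in the nodal field and are materialized as sparse
matrices (one per coordinate direction), which makes both vectorized
evaluation and exact loss backpropagation a sparse mat-vec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import StructuralError
from .mesh import WALL, VolumetricMesh, extract_edges


# ---------------------------------------------------------------------------
# fluid properties
# ---------------------------------------------------------------------------

@dataclass
class CarreauYasuda:
    """Shear-thinning viscosity law parameters (blood defaults)."""

    mu0: float = 0.056      # Pa s, zero-shear viscosity
    mu_inf: float = 0.00345  # Pa s, infinite-shear viscosity
    relaxation: float = 3.313  # s
    n: float = 0.3568       # power index
    a: float = 2.0          # Yasuda exponent

    def __post_init__(self):
        if min(self.mu0, self.mu_inf, self.relaxation, self.a) <= 0:
            raise ValueError("Carreau-Yasuda parameters must be positive")
        if self.mu0 < self.mu_inf:
            raise ValueError("shear-thinning requires mu0 >= mu_inf")


@dataclass
class FluidProperties:
    """Blood properties: density in kg/m^3, viscosity in Pa s."""

    density: float = 1060.0
    viscosity: float = 3.5e-3
    carreau_yasuda: CarreauYasuda | None = None

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


def carreau_yasuda(shear_rate, props: FluidProperties | CarreauYasuda) -> np.ndarray:
    """Effective viscosity mu(gamma_dot) in Pa s.

    mu = mu_inf + (mu0 - mu_inf) * (1 + (tau*gamma_dot)^a)^((n-1)/a)
    """
    cy = props.carreau_yasuda if isinstance(props, FluidProperties) else props
    if cy is None:
        raise ValueError("no Carreau-Yasuda parameters configured")
    g = np.asarray(shear_rate, dtype=np.float64)
    return cy.mu_inf + (cy.mu0 - cy.mu_inf) * (
        1.0 + (cy.relaxation * g) ** cy.a
    ) ** ((cy.n - 1.0) / cy.a)


# ---------------------------------------------------------------------------
# neighborhoods and operator matrices
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodTable:
    """CSR-style adjacency: node i's neighbors are
    ``indices[indptr[i]:indptr[i+1]]``."""

    indptr: np.ndarray
    indices: np.ndarray
    n_nodes: int

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]: self.indptr[i + 1]]

    @property
    def degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def __iter__(self):
        for i in range(self.n_nodes):
            yield self.neighbors(i)


def neighborhoods(mesh: VolumetricMesh, min_neighbors: int = 3) -> NeighborhoodTable:
    """Symmetric edge-sharing adjacency from the mesh's tetrahedra."""
    edges = extract_edges(mesh)
    n = mesh.n_nodes
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)
    table = NeighborhoodTable(indptr=indptr, indices=dst, n_nodes=n)
    deg = table.degree
    if np.any(deg == 0):
        raise StructuralError("isolated node with no mesh-edge neighbors")
    n_thin = int((deg < min_neighbors).sum())
    if n_thin:
        warnings.warn(
            f"{n_thin} node(s) have fewer than {min_neighbors} neighbors; "
            "the neighborhood estimators degrade there",
            stacklevel=2,
        )
    return table


def operator_matrices(
    positions: np.ndarray, table: NeighborhoodTable
) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
    """The three directional estimator matrices G_x, G_y, G_z.

    ``(G_b @ f)[i]`` approximates df/dx_b at node i for a nodal scalar f, so
    the full gradient of a vector field is ``grad[:, a, b] = G_b @ u[:, a]``.
    """
    n = table.n_nodes
    i = np.repeat(np.arange(n), table.degree)
    j = table.indices
    d = positions[j] - positions[i]
    r2 = np.einsum("kc,kc->k", d, d)
    if np.any(r2 == 0):
        raise StructuralError("zero-length mesh edge")
    w = 1.0 / (table.degree[i] * r2)
    mats = []
    for b in range(3):
        off = sp.coo_matrix((w * d[:, b], (i, j)), shape=(n, n))
        diag = sp.diags(np.asarray(-off.sum(axis=1)).ravel())
        mats.append((off + diag).tocsr())
    return tuple(mats)


@dataclass
class OperatorSet:
    """Pre-assembled sparse operators for one mesh."""

    table: NeighborhoodTable
    G: tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]
    positions: np.ndarray
    laplacian: sp.csr_matrix = field(init=False)

    def __post_init__(self):
        self.laplacian = sum(Gb @ Gb for Gb in self.G).tocsr()


def build_operators(mesh: VolumetricMesh) -> OperatorSet:
    table = neighborhoods(mesh)
    return OperatorSet(table=table,
                       G=operator_matrices(mesh.positions, table),
                       positions=mesh.positions)


# ---------------------------------------------------------------------------
# field operators
# ---------------------------------------------------------------------------

def _least_squares_gradient(field, positions, table):
    n = table.n_nodes
    grad = np.zeros((n, field.shape[1], 3))
    for i_ in range(n):
        nb = table.neighbors(i_)
        D = positions[nb] - positions[i_]
        dU = field[nb] - field[i_]
        g, *_ = np.linalg.lstsq(D, dU, rcond=None)
        grad[i_] = g.T
    return grad


def _edge_data(positions, table):
    i = np.repeat(np.arange(table.n_nodes), table.degree)
    j = table.indices
    d = positions[j] - positions[i]
    r2 = np.einsum("kc,kc->k", d, d)
    if np.any(r2 == 0):
        raise StructuralError("zero-length mesh edge")
    return i, j, d, r2


def _estimator(values: np.ndarray, positions, table) -> np.ndarray:
    """Averaged rank-one estimator of an (N, C)-valued nodal field, in the
    printed difference form (v_j - v_i) d^T / |d|^2: exact zeros for constant
    fields.  Returns (N, C, 3)."""
    i, j, d, r2 = _edge_data(positions, table)
    dv = values[j] - values[i]  # (K, C)
    contrib = dv[:, :, None] * (d / r2[:, None])[:, None, :]  # (K, C, 3)
    out = np.zeros((table.n_nodes,) + contrib.shape[1:])
    np.add.at(out, i, contrib)
    return out / table.degree[:, None, None]


def discrete_gradient(
    field: np.ndarray,
    positions: np.ndarray,
    table: NeighborhoodTable,
    method: str = "neighborhood",
) -> np.ndarray:
    """Per-node gradient (N, C, 3) of a nodal field (N, C); entry
    ``[i, a, b]`` approximates d(field_a)/dx_b at node i (1/s for velocity)."""
    field = np.asarray(field, dtype=np.float64)
    squeeze = field.ndim == 1
    if squeeze:
        field = field[:, None]
    if method == "least_squares":
        grad = _least_squares_gradient(field, positions, table)
    elif method == "neighborhood":
        grad = _estimator(field, positions, table)
    else:
        raise ValueError(f"unknown gradient method '{method}'")
    return grad[:, 0, :] if squeeze else grad


def discrete_divergence(
    field: np.ndarray, positions: np.ndarray, table: NeighborhoodTable
) -> np.ndarray:
    """Per-node divergence (N,) of a nodal vector field (N, 3), in 1/s."""
    i, j, d, r2 = _edge_data(positions, table)
    dv = field[j] - field[i]
    terms = np.einsum("kc,kc->k", dv, d) / r2
    out = np.zeros(table.n_nodes)
    np.add.at(out, i, terms)
    return out / table.degree


def discrete_laplacian(
    field: np.ndarray, positions: np.ndarray, table: NeighborhoodTable
) -> np.ndarray:
    """Per-node vector Laplacian (N, C): the estimator applied to each nodal
    gradient component, contracted by trace (the unique reading of the
    matrix-times-row-vector form for which constant-gradient fields give 0)."""
    field = np.asarray(field, dtype=np.float64)
    squeeze = field.ndim == 1
    if squeeze:
        field = field[:, None]
    grad = _estimator(field, positions, table)  # (N, C, 3)
    n, c, _ = grad.shape
    second = _estimator(grad.reshape(n, c * 3), positions, table)  # (N, C*3, 3)
    lap = np.einsum("ncbb->nc", second.reshape(n, c, 3, 3))
    return lap[:, 0] if squeeze else lap


def convective_term(field: np.ndarray, positions, table, density: float) -> np.ndarray:
    """rho * (u . grad) u per node, from the neighborhood gradient."""
    grad = discrete_gradient(field, positions, table)
    return density * np.einsum("nab,nb->na", grad, field)


# ---------------------------------------------------------------------------
# stress and wall shear stress
# ---------------------------------------------------------------------------

def strain_rate(grad: np.ndarray) -> np.ndarray:
    """Symmetric strain-rate tensor eps = (grad + grad^T) / 2 (1/s)."""
    return 0.5 * (grad + np.swapaxes(grad, -1, -2))


def shear_rate(grad: np.ndarray) -> np.ndarray:
    """Scalar shear-rate magnitude gamma_dot = sqrt(2 eps:eps) (1/s)."""
    eps = strain_rate(grad)
    return np.sqrt(2.0 * np.einsum("...ab,...ab->...", eps, eps))


def cauchy_stress(grad: np.ndarray, p, mu) -> np.ndarray:
    """sigma = -p I + mu (grad + grad^T), Pa.  ``p`` and ``mu`` may be
    scalars or per-node arrays broadcast over the leading axis."""
    grad = np.asarray(grad, dtype=np.float64)
    mu_ = np.asarray(mu, dtype=np.float64)
    p_ = np.asarray(p, dtype=np.float64)
    sym = grad + np.swapaxes(grad, -1, -2)
    sigma = mu_[..., None, None] * sym if mu_.ndim else mu_ * sym
    eye = np.eye(3)
    sigma = sigma - (p_[..., None, None] * eye if p_.ndim else p_ * eye)
    return sigma


def traction_tangential(sigma: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """tau = sigma.n - ((sigma.n).n) n : tangential part of the traction."""
    t = np.einsum("...ab,...b->...a", sigma, normals)
    tn = np.einsum("...a,...a->...", t, normals)
    return t - tn[..., None] * normals


def wall_shear_stress(
    mesh: VolumetricMesh,
    frame_or_velocity,
    props: FluidProperties,
    grad: np.ndarray | None = None,
    use_carreau_yasuda: bool = False,
) -> np.ndarray:
    """Wall shear stress vectors (N, 3) in Pa; zero rows off the wall.

    Velocity gradients default to the neighborhood estimator; an analytic
    (N, 3, 3) gradient may be supplied instead.  Any uniform pressure
    contributes only a normal traction and provably cancels from tau.
    """
    if mesh.wall_normals is None:
        raise StructuralError("mesh has no wall normals; call wall_normals() first")
    velocity = getattr(frame_or_velocity, "velocity", frame_or_velocity)
    if grad is None:
        table = neighborhoods(mesh)
        grad = discrete_gradient(velocity, mesh.positions, table)
    if use_carreau_yasuda:
        mu = carreau_yasuda(shear_rate(grad), props)
    else:
        mu = props.viscosity
    sigma = cauchy_stress(grad, 0.0, mu)  # pressure cancels in the tangential part
    wall = mesh.node_type == WALL
    tau = np.zeros((mesh.n_nodes, 3))
    tau[wall] = traction_tangential(sigma[wall], mesh.wall_normals[wall])
    return tau
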