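"""Independent brute-force oracles used to check the vectorized operators.

These deliberately re-derive every quantity with naive double loops and
plain formulas, sharing no code with the package implementation.
"""

import numpy as np


def naive_gradient(field, positions, table):
    """Averaged rank-one neighborhood gradient, one node at a time."""
    field = np.atleast_2d(field.T).T
    n, c = field.shape
    out = np.zeros((n, c, 3))
    for i in range(n):
        nb = list(table.neighbors(i))
        acc = np.zeros((c, 3))
        for j in nb:
            d = positions[j] - positions[i]
            acc += np.outer(field[j] - field[i], d) / (d @ d)
        out[i] = acc / len(nb)
    return out


def naive_divergence(field, positions, table):
    n = field.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = list(table.neighbors(i))
        s = 0.0
        for j in nb:
            d = positions[j] - positions[i]
            s += (field[j] - field[i]) @ d / (d @ d)
        out[i] = s / len(nb)
    return out


def naive_laplacian(field, positions, table):
    """Estimator applied to each nodal gradient, contracted by trace."""
    grad = naive_gradient(field, positions, table)  # (n, c, 3)
    n, c, _ = grad.shape
    out = np.zeros((n, c))
    for i in range(n):
        nb = list(table.neighbors(i))
        acc = np.zeros(c)
        for j in nb:
            d = positions[j] - positions[i]
            # second application per component a: trace of
            # mean_j (g_j - g_i) d^T / |d|^2  over the gradient 3-vector
            acc += (grad[j] - grad[i]) @ d / (d @ d)
        out[i] = acc / len(nb)
    return out


def naive_wss(grad, normals, mu, p=0.0):
    """tau = sigma.n - ((sigma.n).n) n with sigma = -p I + mu (g + g^T)."""
    out = np.zeros((grad.shape[0], 3))
    for i in range(grad.shape[0]):
        sigma = -p * np.eye(3) + mu * (grad[i] + grad[i].T)
        t = sigma @ normals[i]
        out[i] = t - (t @ normals[i]) * normals[i]
    return out


def random_tet_mesh(rng, n_points=30):
    """Small random Delaunay tet mesh for operator property tests."""
    from scipy.spatial import Delaunay

    from hemograph.mesh import VolumetricMesh

    pts = rng.uniform(-1.0, 1.0, size=(n_points, 3))
    tri = Delaunay(pts)
    mesh = VolumetricMesh(positions=pts, tetrahedra=tri.simplices).orient()
    # drop slivers that Delaunay occasionally emits on random points, then
    # compact away any node left without a cell
    vols = mesh.cell_volumes()
    tets = mesh.tetrahedra[vols > 1e-9]
    used = np.unique(tets)
    remap = -np.ones(n_points, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return VolumetricMesh(positions=pts[used], tetrahedra=remap[tets])
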