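"""Eigenvector centrality, eccentricity and subnetwork summaries.

Eigenvector centrality (EC) is the leading eigenvector of the (binary,
symmetric, connected) adjacency matrix, sign-fixed positive and scaled to
unit Euclidean norm; Perron-Frobenius guarantees the eigenpair is simple
and strictly positive.  For a multiplex the EC is computed on the
supra-adjacency matrix and collapsed to one value per brain region by
averaging the region's L replica entries (the collapse rule is isolated
in :func:`multilayer_nodal_ec` so alternatives are a one-line change);
the collapsed vector is renormalized to unit norm, which makes the
identical-layer multiplex reproduce the single-layer EC exactly.

Eccentricity of a node is its longest shortest-path distance to any other
node, found by breadth-first search from every node; the mean over nodes
is the global summary.
"""

from __future__ import annotations

from collections import deque
from typing import NamedTuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import eigsh

from .connectome_io import Parcellation
from .exceptions import ConvergenceError, DisconnectedGraphError, FormatError
from .graph_layers import MultiplexNetwork, supra_adjacency

_EC_RESIDUAL_TOL = 1e-8


def _check_connected(adjacency: np.ndarray) -> None:
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    if n_comp != 1:
        reps = [int(np.flatnonzero(labels == c)[0]) for c in range(n_comp)]
        raise DisconnectedGraphError(n_comp, reps)


def eigenvector_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a connected symmetric adjacency matrix.

    Solved with Lanczos iteration (deterministic all-ones start); falls
    back to a dense eigendecomposition for very small matrices where the
    iterative solver cannot run.  The returned vector is positive, has
    unit Euclidean norm, and satisfies ``A v = lambda_1 v`` within 1e-8.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise FormatError(f"adjacency must be square, got {a.shape}")
    n = a.shape[0]
    _check_connected(a)
    if n <= 5:
        eigvals, eigvecs = np.linalg.eigh(a)
        lam, v = eigvals[-1], eigvecs[:, -1]
    else:
        lam_arr, v_arr = eigsh(a, k=1, which="LA", v0=np.ones(n), maxiter=10_000)
        lam, v = float(lam_arr[0]), v_arr[:, 0]
    if v.sum() < 0:
        v = -v
    residual = float(np.linalg.norm(a @ v - lam * v))
    if residual > _EC_RESIDUAL_TOL:
        raise ConvergenceError(residual, _EC_RESIDUAL_TOL)
    v = np.clip(v, 0.0, None)
    return v / np.linalg.norm(v)


def multilayer_nodal_ec(multiplex: MultiplexNetwork) -> np.ndarray:
    """Per-region multilayer EC from the supra-adjacency eigenvector.

    Each region's L replica entries of the unit-norm supra eigenvector
    are averaged, then the length-N result is renormalized to unit norm.
    """
    supra = supra_adjacency(multiplex)
    v = eigenvector_centrality(supra)
    per_region = v.reshape(multiplex.n_layers, multiplex.n_nodes).mean(axis=0)
    return per_region / np.linalg.norm(per_region)


def _bfs_eccentricity(neighbors: list[list[int]], source: int) -> int:
    n = len(neighbors)
    dist = [-1] * n
    dist[source] = 0
    queue = deque([source])
    far = 0
    while queue:
        u = queue.popleft()
        for w in neighbors[u]:
            if dist[w] < 0:
                dist[w] = dist[u] + 1
                far = dist[w]
                queue.append(w)
    if min(dist) < 0:
        raise DisconnectedGraphError(2, [source, dist.index(-1)])
    return far


def eccentricity(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node eccentricities (ints) and their mean, by repeated BFS."""
    a = np.asarray(adjacency)
    _check_connected(a)
    n = a.shape[0]
    neighbors = [np.flatnonzero(a[i]).tolist() for i in range(n)]
    ecc = np.array([_bfs_eccentricity(neighbors, s) for s in range(n)], dtype=int)
    return ecc, float(ecc.mean())


def multiplex_eccentricity(multiplex: MultiplexNetwork) -> tuple[np.ndarray, float]:
    """Supra-node eccentricities of the multiplex and their mean.

    The mean is over all L*N supra-nodes; a per-region collapse (mean of
    each region's replicas) is available by reshaping the first output.
    """
    return eccentricity(supra_adjacency(multiplex))


class SubnetworkMean(NamedTuple):
    mean: float
    n_regions: int


def subnetwork_mean(
    values: np.ndarray, parcellation: Parcellation, network: str
) -> SubnetworkMean:
    """Arithmetic mean of per-region values over one network's members."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != parcellation.n_regions:
        raise FormatError(
            f"{values.shape[0]} values for {parcellation.n_regions} regions"
        )
    idx = parcellation.members(network)
    if idx.size == 0:
        raise FormatError(f"parcellation has no region in network {network!r}")
    return SubnetworkMean(float(values[idx].mean()), int(idx.size))
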