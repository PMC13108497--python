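"""Spanning-tree layers and the two-layer multiplex.

Each layer is the binarized maximum spanning tree of one weighted
connectivity matrix: edges are ranked strongest-first and accepted with
Kruskal's algorithm until all N nodes are connected by N - 1 loop-free
links.  (Much of the neuroimaging literature calls this backbone the
"MST" even though it maximizes, not minimizes, total weight.)

Layers over the same node set are stacked into a multiplex in which every
node is linked to its own replica in every other layer with weight 1, and
the whole object can be materialized as an (L*N) x (L*N) binary
supra-adjacency matrix: diagonal N x N blocks hold the layer adjacencies,
off-diagonal blocks are identity matrices.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectome_io import ConnectivityMatrix
from .exceptions import DisconnectedGraphError, FormatError


@dataclasses.dataclass(frozen=True)
class SpanningTreeLayer:
    """A binary, connected, acyclic layer with exactly N - 1 edges."""

    layer_name: str
    n_nodes: int
    edges: tuple[tuple[int, int], ...]  # sorted (i, j) with i < j

    def __post_init__(self):
        if len(self.edges) != self.n_nodes - 1:
            raise FormatError(
                f"layer {self.layer_name!r}: {len(self.edges)} edges for "
                f"{self.n_nodes} nodes (need N-1)"
            )
        for i, j in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise FormatError(f"bad edge ({i}, {j}) for n_nodes={self.n_nodes}")

    @property
    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def total_weight(self, weights: np.ndarray) -> float:
        return float(sum(weights[i, j] for i, j in self.edges))


@dataclasses.dataclass(frozen=True)
class MultiplexNetwork:
    """L spanning-tree layers on one node set, coupled by unit links."""

    layers: tuple[SpanningTreeLayer, ...]
    interlayer_weight: float = 1.0

    def __post_init__(self):
        if len(self.layers) < 1:
            raise FormatError("a multiplex needs at least one layer")
        n0 = self.layers[0].n_nodes
        for layer in self.layers[1:]:
            if layer.n_nodes != n0:
                raise FormatError(
                    f"layers {self.layers[0].layer_name!r} ({n0} nodes) and "
                    f"{layer.layer_name!r} ({layer.n_nodes} nodes) differ in size"
                )

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)


class _UnionFind:
    """Disjoint sets with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return True


def maximum_spanning_tree(matrix, layer_name: str = "layer") -> SpanningTreeLayer:
    """Kruskal's algorithm on positive-weight links ranked strongest-first.

    Ties are broken deterministically by (weight descending, smaller node
    index ascending, larger node index ascending); with distinct weights
    the maximizing tree is unique and the tie-break is inert.  A
    disconnected positive-weight graph raises
    :class:`~mplexcog.exceptions.DisconnectedGraphError`.
    """
    if isinstance(matrix, ConnectivityMatrix):
        w = matrix.weights
    else:
        w = np.asarray(matrix, dtype=float)
    n = w.shape[0]
    if n < 2:
        raise FormatError("need at least 2 nodes for a spanning tree")
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    keep = vals > 0
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    order = np.lexsort((ju, iu, -vals))
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    if len(edges) < n - 1:
        roots: dict[int, int] = {}
        for node in range(n):
            roots.setdefault(uf.find(node), node)
        raise DisconnectedGraphError(len(roots), sorted(roots.values()))
    return SpanningTreeLayer(layer_name, n, tuple(edges))


def build_multiplex(layers: Sequence[SpanningTreeLayer]) -> MultiplexNetwork:
    """Stack layers into a multiplex with unit same-node interlayer links."""
    return MultiplexNetwork(tuple(layers))


def supra_adjacency(multiplex: MultiplexNetwork) -> np.ndarray:
    """Materialize the (L*N) x (L*N) binary supra-adjacency matrix.

    Interlayer identity blocks are placed between every pair of layers
    (for the two-layer case this is the only possible choice).
    """
    n, L = multiplex.n_nodes, multiplex.n_layers
    supra = np.zeros((L * n, L * n))
    eye = np.eye(n) * multiplex.interlayer_weight
    for a, layer in enumerate(multiplex.layers):
        supra[a * n:(a + 1) * n, a * n:(a + 1) * n] = layer.adjacency
        for b in range(a + 1, L):
            supra[a * n:(a + 1) * n, b * n:(b + 1) * n] = eye
            supra[b * n:(b + 1) * n, a * n:(a + 1) * n] = eye
    return supra


def is_connected(adjacency: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adjacency), directed=False)
    return n_comp == 1


def write_edgelist(path, multiplex: MultiplexNetwork) -> None:
    """Export intra- and interlayer links as a TSV edge list."""
    n = multiplex.n_nodes
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tlayer_i\tlayer_j\n")
        for a, layer in enumerate(multiplex.layers):
            for i, j in layer.edges:
                fh.write(f"{i}\t{j}\t{a}\t{a}\n")
        for a in range(multiplex.n_layers):
            for b in range(a + 1, multiplex.n_layers):
                for i in range(n):
                    fh.write(f"{i}\t{i}\t{a}\t{b}\n")


def write_supra_matrix(path, multiplex: MultiplexNetwork) -> None:
    supra = supra_adjacency(multiplex)
    with open(path, "w") as fh:
        for row in supra:
            fh.write("\t".join(format(x, "g") for x in row) + "\n")
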