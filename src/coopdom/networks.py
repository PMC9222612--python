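"""Layer construction and multilayer assembly.

Layers are simple undirected graphs on node ids 0..N-1.  Barabasi-Albert
(preferential attachment) and Watts-Strogatz (small-world) layers delegate
to networkx; a multilayer network is an ordered stack of equal-size layers
where node i of every layer forms coupling group i.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "LayerSpec",
    "Layer",
    "MultilayerNetwork",
    "build_ba",
    "build_ws",
    "build_layer",
    "assemble",
    "read_graph",
    "write_graph",
]


@dataclass(frozen=True)
class LayerSpec:
    """Parameters of one layer.

    model : {"ba", "ws", "custom"}
    n_nodes : number of nodes N
    ba_m : edges attached per new node (BA); m=2 gives average degree ~4
    ws_k : even number of ring-lattice neighbours (WS)
    ws_p : rewiring probability in [0, 1] (WS)
    seed : construction seed (ignored when a seed is supplied externally)
    """

    model: str
    n_nodes: int
    ba_m: int | None = None
    ws_k: int | None = None
    ws_p: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("ba", "ws", "custom"):
            raise ValueError(f"unknown layer model {self.model!r}")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.model == "ba":
            if self.ba_m is None or self.ba_m < 1 or self.ba_m >= self.n_nodes:
                raise ValueError(
                    f"ba_m must satisfy 1 <= ba_m < n_nodes, got {self.ba_m}"
                )
        if self.model == "ws":
            if self.ws_k is None or self.ws_k % 2 != 0 or not 0 < self.ws_k < self.n_nodes:
                raise ValueError(
                    f"ws_k must be even with 0 < ws_k < n_nodes, got {self.ws_k}"
                )
            if self.ws_p is None or not 0.0 <= self.ws_p <= 1.0:
                raise ValueError(f"ws_p must be in [0, 1], got {self.ws_p}")

    @classmethod
    def ba(cls, n_nodes: int, ba_m: int = 2, seed: int | None = None) -> "LayerSpec":
        return cls(model="ba", n_nodes=n_nodes, ba_m=ba_m, seed=seed)

    @classmethod
    def ws(
        cls, n_nodes: int, ws_k: int = 4, ws_p: float = 0.5, seed: int | None = None
    ) -> "LayerSpec":
        return cls(model="ws", n_nodes=n_nodes, ws_k=ws_k, ws_p=ws_p, seed=seed)


class Layer:
    """An undirected simple graph layer with cached sparse adjacency.

    Node ids must be exactly {0..N-1}; self-loops are rejected.  The CSR
    adjacency, CSR neighbour arrays and degree vector are cached because the
    simulator touches them every round.
    """

    def __init__(self, graph: nx.Graph, spec: LayerSpec | None = None):
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("layers must be simple undirected graphs")
        n = graph.number_of_nodes()
        if n == 0:
            raise ValueError("layer graph must have at least one node")
        if set(graph.nodes) != set(range(n)):
            raise ValueError("node ids must be exactly 0..N-1")
        if any(u == v for u, v in graph.edges):
            raise ValueError("self-loops are not allowed")
        self.graph = graph
        self.spec = spec if spec is not None else LayerSpec(model="custom", n_nodes=n)
        self._adj = nx.to_scipy_sparse_array(
            graph, nodelist=range(n), format="csr", dtype=np.float64
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency_matrix(self) -> sp.csr_array:
        return self._adj

    @property
    def neighbor_indptr(self) -> np.ndarray:
        return self._adj.indptr

    @property
    def neighbor_indices(self) -> np.ndarray:
        return self._adj.indices

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self._adj.indptr)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    def __repr__(self) -> str:  # pragma: no cover
        return f"Layer({self.spec.model}, N={self.n_nodes}, E={self.n_edges})"


def build_ba(n_nodes: int, ba_m: int, seed=None) -> Layer:
    """Grow a Barabasi-Albert scale-free layer by preferential attachment.

    The initial graph is a star on ``ba_m + 1`` nodes (the networkx
    convention); every subsequent node attaches ``ba_m`` edges to existing
    nodes with probability proportional to degree.  The result is connected
    with ``ba_m * (n_nodes - ba_m)`` edges, so mean degree approaches
    ``2 * ba_m`` for large N (m=2 -> average degree ~4 at N=500).
    """
    spec = LayerSpec.ba(n_nodes, ba_m, seed=_as_int_seed(seed))
    g = nx.barabasi_albert_graph(n_nodes, ba_m, seed=spec.seed)
    return Layer(g, spec)


def build_ws(n_nodes: int, ws_k: int, ws_p: float, seed=None) -> Layer:
    """Build a classic Watts-Strogatz small-world layer.

    A ring lattice joins every node to its ``ws_k`` nearest neighbours;
    each lattice edge is then rewired with probability ``ws_p`` (one
    endpoint moved to a uniform node, rejecting self-loops and duplicates),
    which conserves the edge count ``n_nodes * ws_k / 2`` exactly.
    """
    spec = LayerSpec.ws(n_nodes, ws_k, ws_p, seed=_as_int_seed(seed))
    g = nx.watts_strogatz_graph(n_nodes, ws_k, ws_p, seed=spec.seed)
    return Layer(g, spec)


def build_layer(spec: LayerSpec, seed=None) -> Layer:
    """Build a layer from its spec; an explicit seed overrides the spec's."""
    use_seed = seed if seed is not None else spec.seed
    if spec.model == "ba":
        return build_ba(spec.n_nodes, spec.ba_m, seed=use_seed)
    if spec.model == "ws":
        return build_ws(spec.n_nodes, spec.ws_k, spec.ws_p, seed=use_seed)
    raise ValueError("custom layers must be constructed from a graph or file")


def _as_int_seed(seed) -> int | None:
    """Reduce any seed-like object to a plain int for networkx."""
    if seed is None:
        return None
    if isinstance(seed, (int, np.integer)):
        return int(seed) & 0x7FFFFFFF
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0]) & 0x7FFFFFFF
    raise TypeError(f"unsupported seed type {type(seed)!r}")


class MultilayerNetwork:
    """Ordered stack of equal-size layers with index-aligned coupling.

    Node i of every layer belongs to coupling group i; the groups are the
    only interlayer structure (there are no interlayer game interactions).
    """

    def __init__(self, layers: Sequence[Layer]):
        layers = list(layers)
        if not layers:
            raise ValueError("a multilayer network needs at least one layer")
        n = layers[0].n_nodes
        for i, layer in enumerate(layers):
            if layer.n_nodes != n:
                raise ValueError(
                    f"layer {i} has {layer.n_nodes} nodes, expected {n}; "
                    "all layers must share N"
                )
        self.layers = layers

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    def coupling_group(self, i: int) -> list[tuple[int, int]]:
        """The (layer, node) members of coupling group i."""
        if not 0 <= i < self.n_nodes:
            raise IndexError(f"no coupling group {i}")
        return [(ell, i) for ell in range(self.n_layers)]

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return self.n_layers

    def __repr__(self) -> str:  # pragma: no cover
        models = "-".join(layer.spec.model.upper() for layer in self.layers)
        return f"MultilayerNetwork({models}, N={self.n_nodes})"


def assemble(layers: Iterable[Layer]) -> MultilayerNetwork:
    """Stack layers into a multilayer network (all must share N)."""
    return MultilayerNetwork(list(layers))


def write_graph(layer: Layer, path, format: str = "edgelist") -> None:
    """Write a layer as a plain edge list ("u v" per line) or GraphML."""
    path = Path(path)
    if format == "edgelist":
        with path.open("w") as fh:
            for u, v in sorted(layer.edge_set()):
                fh.write(f"{u} {v}\n")
    elif format == "graphml":
        nx.write_graphml(layer.graph, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str = "edgelist", n_nodes: int | None = None) -> Layer:
    """Read a layer back from an edge list or GraphML file.

    Edge lists are 0-based "u v" pairs, one per line; ``n_nodes`` may be
    given to include trailing isolated nodes (otherwise N = max id + 1).
    Self-loops and duplicate edges are rejected with the offending line
    number; an empty file is an error, not an empty graph.
    """
    path = Path(path)
    if format == "edgelist":
        g = _read_edgelist(path)
    elif format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.relabel_nodes(raw, {node: int(node) for node in raw.nodes})
    else:
        raise ValueError(f"unknown graph format {format!r}")
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no nodes found")
    max_id = max(g.nodes)
    n = max(max_id + 1, n_nodes or 0)
    g.add_nodes_from(range(n))
    return Layer(g)


def _read_edgelist(path: Path) -> nx.Graph:
    g = nx.Graph()
    n_lines = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            n_lines += 1
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'u v', got {stripped!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer node id in {stripped!r}"
                ) from None
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: negative node id")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}-{v} not allowed")
            if g.has_edge(u, v):
                raise ValueError(f"{path}:{lineno}: duplicate edge {u}-{v}")
            g.add_edge(u, v)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    return g
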