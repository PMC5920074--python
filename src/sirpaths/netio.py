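"""Contact-network container, edge-list I/O and synthetic network generators.

Node identifiers are opaque strings externally; internally every algorithm
works on dense integer indices in a canonical order (natural sort of the
ids).  The directed-arc arrays double as a CSR adjacency structure, which
is what the shortest-path kernels consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "ContactNetwork",
    "NetworkFormatError",
    "read_edge_list",
    "write_edge_list",
    "generate_lattice",
    "generate_er",
    "generate_scale_free",
]


class NetworkFormatError(ValueError):
    """Raised for malformed edge-list input (self-loops, duplicates, ...)."""


def _natural_key(s: str):
    return tuple(int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", s))


@dataclass
class ContactNetwork:
    """An undirected simple contact graph.

    Parameters
    ----------
    node_ids
        Canonically ordered node identifiers.
    edges
        ``(E, 2)`` integer array of index pairs with ``i < j``, sorted
        lexicographically.
    """

    node_ids: tuple
    edges: np.ndarray
    name: str = "network"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_ids = tuple(str(v) for v in self.node_ids)
        if len(set(self.node_ids)) != len(self.node_ids):
            raise NetworkFormatError("duplicate node ids")
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= len(self.node_ids):
                raise NetworkFormatError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise NetworkFormatError("self-loops are not permitted")
        lo = np.minimum(self.edges[:, 0], self.edges[:, 1])
        hi = np.maximum(self.edges[:, 0], self.edges[:, 1])
        order = np.lexsort((hi, lo))
        self.edges = np.column_stack([lo, hi])[order]
        if self.edges.shape[0] > 1 and np.any(
            (np.diff(self.edges[:, 0]) == 0) & (np.diff(self.edges[:, 1]) == 0)
        ):
            raise NetworkFormatError("duplicate edges are not permitted")
        self._index = {v: i for i, v in enumerate(self.node_ids)}
        self._arc_cache = None

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def index(self, node_id) -> int:
        try:
            return self._index[str(node_id)]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    # -- directed-arc / CSR view ----------------------------------------
    def _arcs(self):
        if self._arc_cache is None:
            e = self.edges
            src = np.concatenate([e[:, 0], e[:, 1]])
            dst = np.concatenate([e[:, 1], e[:, 0]])
            eid = np.concatenate([np.arange(self.n_edges)] * 2)
            order = np.lexsort((dst, src))
            src, dst, eid = src[order], dst[order], eid[order]
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.add.at(indptr, src + 1, 1)
            np.cumsum(indptr, out=indptr)
            self._arc_cache = (src, dst, eid, indptr)
        return self._arc_cache

    @property
    def arc_src(self) -> np.ndarray:
        """Source index of each directed arc, sorted by (src, dst)."""
        return self._arcs()[0]

    @property
    def arc_dst(self) -> np.ndarray:
        return self._arcs()[1]

    @property
    def arc_edge(self) -> np.ndarray:
        """Undirected edge id underlying each directed arc."""
        return self._arcs()[2]

    @property
    def indptr(self) -> np.ndarray:
        """CSR row pointer over arcs: arcs of node i are indptr[i]:indptr[i+1]."""
        return self._arcs()[3]

    @property
    def n_arcs(self) -> int:
        return 2 * self.n_edges

    # -- construction / conversion ---------------------------------------
    @classmethod
    def from_edge_ids(cls, pairs, nodes=None, name="network", meta=None):
        """Build from an iterable of (id, id) pairs plus optional extra nodes."""
        pairs = [(str(a), str(b)) for a, b in pairs]
        ids = set(nodes or [])
        ids.update(v for pair in pairs for v in pair)
        node_ids = sorted((str(v) for v in ids), key=_natural_key)
        index = {v: i for i, v in enumerate(node_ids)}
        edges = np.array([[index[a], index[b]] for a, b in pairs], dtype=np.int64).reshape(-1, 2)
        return cls(tuple(node_ids), edges, name=name, meta=dict(meta or {}))

    @classmethod
    def from_networkx(cls, graph: nx.Graph, name="network", meta=None):
        return cls.from_edge_ids(
            ((str(a), str(b)) for a, b in graph.edges()),
            nodes=[str(v) for v in graph.nodes()],
            name=name,
            meta=meta,
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((self.node_ids[i], self.node_ids[j]) for i, j in self.edges)
        return g

    def largest_component(self) -> "ContactNetwork":
        g = self.to_networkx()
        cc = max(nx.connected_components(g), key=len)
        sub = g.subgraph(cc)
        return ContactNetwork.from_networkx(sub, name=self.name + "_lcc", meta=self.meta)


def read_edge_list(path) -> ContactNetwork:
    """Parse a whitespace- or comma-delimited edge list.

    Lines starting with ``#`` are comments; a single-token line declares an
    isolated node.  Self-loops and duplicate edges raise
    :class:`NetworkFormatError` naming the offending line.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    singles: list[str] = []
    seen: set[frozenset] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = [t for t in re.split(r"[,\s]+", line) if t]
            if len(tokens) == 1:
                singles.append(tokens[0])
                continue
            if len(tokens) != 2:
                raise NetworkFormatError(f"{path}:{lineno}: expected 1 or 2 columns")
            a, b = tokens
            if a == b:
                raise NetworkFormatError(f"{path}:{lineno}: self-loop {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise NetworkFormatError(f"{path}:{lineno}: duplicate edge {a!r}-{b!r}")
            seen.add(key)
            pairs.append((a, b))
    return ContactNetwork.from_edge_ids(pairs, nodes=singles, name=path.stem)


def write_edge_list(network: ContactNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {network.name}: {network.n_nodes} nodes, {network.n_edges} edges\n")
        deg = network.degrees()
        for i, j in network.edges:
            fh.write(f"{network.node_ids[i]} {network.node_ids[j]}\n")
        for i in np.flatnonzero(deg == 0):
            fh.write(f"{network.node_ids[i]}\n")


# -- generators ----------------------------------------------------------

def generate_lattice(rows: int, cols: int) -> ContactNetwork:
    """4-connected (von Neumann) two-dimensional grid, non-periodic."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    pairs = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                pairs.append((f"{r}_{c}", f"{r}_{c + 1}"))
            if r + 1 < rows:
                pairs.append((f"{r}_{c}", f"{r + 1}_{c}"))
    nodes = [f"{r}_{c}" for r in range(rows) for c in range(cols)]
    return ContactNetwork.from_edge_ids(
        pairs, nodes=nodes, name=f"lattice_{rows}x{cols}", meta={"rows": rows, "cols": cols}
    )


def generate_er(n: int, mean_degree: float, rng: np.random.Generator,
                connected: bool = False) -> ContactNetwork:
    """Erdős–Rényi G(n, p) with p = mean_degree / (n - 1).

    With ``connected=True`` the largest connected component is returned.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p = mean_degree / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    net = ContactNetwork.from_networkx(
        g, name=f"er_{n}", meta={"n": n, "mean_degree": mean_degree}
    )
    return net.largest_component() if connected else net


def generate_scale_free(n: int, attachment: int = 3,
                        rng: np.random.Generator | None = None) -> ContactNetwork:
    """Preferential-attachment (Barabási–Albert) network with heavy-tailed degrees."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = rng or np.random.default_rng()
    g = nx.barabasi_albert_graph(n, attachment, seed=int(rng.integers(2**31)))
    return ContactNetwork.from_networkx(
        g, name=f"ba_{n}", meta={"n": n, "attachment": attachment}
    )
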