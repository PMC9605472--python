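"""Protein–protein interactome: loading, cleaning, and hop-distance queries.

The interactome is an undirected, unweighted graph over gene identifiers.
Every proximity evaluation in the pipeline reduces to hop distances on this
graph, so the class keeps a cached CSR adjacency matrix and answers
nearest-member distance queries through ``scipy.sparse.csgraph`` rather than
per-node Python BFS.

Gene identifiers are opaque, case-sensitive strings; no symbol normalization
is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "gene", "gene1", "gene2", "genea", "geneb", "protein", "protein1",
    "protein2", "node", "node1", "node2", "source", "target", "from", "to",
    "interactor", "interactora", "interactorb", "symbol", "symbol1", "symbol2",
}


@dataclass
class NodeSet:
    """A labeled set of gene identifiers (a drug-target or disease-gene module)."""

    members: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def restrict(self, graph: "InteractomeGraph") -> "NodeSet":
        """Drop members absent from *graph* (logged); may become empty."""
        kept = frozenset(m for m in self.members if m in graph)
        dropped = len(self.members) - len(kept)
        if dropped:
            logger.info("NodeSet %r: %d of %d members not in graph, dropped",
                        self.label, dropped, len(self.members))
        return NodeSet(kept, self.label)


class InteractomeGraph:
    """Undirected gene network; no self-loops, no duplicate edges.

    Wraps a :class:`networkx.Graph` and lazily builds an integer node index
    plus a CSR adjacency matrix for fast multi-source hop-distance queries.
    """

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges()):
            raise ValueError("interactome must not contain self-loops")
        self._g = graph
        self._order: list[str] | None = None
        self._index: dict[str, int] | None = None
        self._csr: csr_matrix | None = None

    # -- accessors -------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self._g.nodes())

    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges()}

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    # -- distance engine -------------------------------------------------

    def _ensure_csr(self) -> None:
        if self._csr is not None:
            return
        self._order = sorted(self._g.nodes())
        self._index = {n: i for i, n in enumerate(self._order)}
        n = len(self._order)
        rows, cols = [], []
        for u, v in self._g.edges():
            iu, iv = self._index[u], self._index[v]
            rows.extend((iu, iv))
            cols.extend((iv, iu))
        data = np.ones(len(rows), dtype=np.int8)
        self._csr = csr_matrix((data, (rows, cols)), shape=(n, n))

    def node_order(self) -> list[str]:
        self._ensure_csr()
        return list(self._order)

    def node_indices(self, nodes: Iterable[str]) -> np.ndarray:
        self._ensure_csr()
        return np.fromiter((self._index[n] for n in nodes), dtype=np.intp)

    def distance_to_set_array(self, sources: Iterable[str]) -> np.ndarray:
        """Hop distance from every node to its nearest member of *sources*.

        Returned in :meth:`node_order` order; unreachable nodes are ``inf``.
        """
        self._ensure_csr()
        idx = self.node_indices(sources)
        if idx.size == 0:
            raise ValueError("empty source set")
        return dijkstra(self._csr, unweighted=True, indices=idx, min_only=True)


def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_interactome(path: str | Path) -> InteractomeGraph:
    """Read a 2-column TSV edge list (or 3-column SIF; middle column ignored).

    A header line is auto-detected by common column-name tokens. Self-loops
    and duplicate (including reversed) edges are dropped with logged counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except OSError as exc:
        raise OSError(f"cannot read interactome file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge table needs at least 2 columns, "
                         f"found {df.shape[1]}")
    if df.shape[1] >= 3 and df.iloc[:, 2].notna().any():
        # SIF dialect: node1 <relation> node2
        df = df.iloc[:, [0, 2]]
    else:
        df = df.iloc[:, [0, 1]]
    df.columns = ["a", "b"]
    if _looks_like_header(df.iloc[0].tolist()):
        df = df.iloc[1:]
    df = df.dropna()
    return build_interactome(df.itertuples(index=False, name=None))


def build_interactome(pairs: Iterable[tuple[str, str]]) -> InteractomeGraph:
    """Assemble a clean graph from identifier pairs (dedup + self-loop removal)."""
    g = nx.Graph()
    n_self = n_dup = n_total = 0
    for a, b in pairs:
        n_total += 1
        a, b = str(a).strip(), str(b).strip()
        if not a or not b:
            raise ValueError("empty gene identifier in edge table")
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    logger.info("interactome: %d rows read, %d self-loops and %d duplicates "
                "dropped -> %d nodes, %d edges",
                n_total, n_self, n_dup, g.number_of_nodes(), g.number_of_edges())
    return InteractomeGraph(g)


def largest_connected_component(g: InteractomeGraph) -> InteractomeGraph:
    """Induced subgraph on the largest component (size ties broken by the
    lexicographically smallest member node)."""
    if g.n_nodes == 0:
        raise ValueError("empty graph has no connected component")
    comps = list(nx.connected_components(g.graph))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    removed = g.n_nodes - len(best)
    if removed:
        logger.warning("largest_connected_component: dropping %d of %d nodes "
                       "outside the LCC", removed, g.n_nodes)
    return InteractomeGraph(g.graph.subgraph(best).copy())


def single_source_distances(g: InteractomeGraph, sources: NodeSet) -> dict[str, int]:
    """Hop distance from the nearest source for every reachable node.

    Sources map to 0; unreachable nodes are absent from the mapping.
    """
    restricted = sources.restrict(g)
    if len(restricted) == 0:
        raise ValueError(f"source set {sources.label!r} has no member in the graph")
    dist = g.distance_to_set_array(restricted)
    order = g.node_order()
    return {order[i]: int(d) for i, d in enumerate(dist) if np.isfinite(d)}


def write_edge_list(g: InteractomeGraph, path: str | Path) -> None:
    """Canonical sorted 2-column TSV (each edge once, endpoints sorted)."""
    edges = sorted(tuple(sorted(e)) for e in g.graph.edges())
    pd.DataFrame(edges).to_csv(path, sep="\t", header=False, index=False)


def write_graphml(g: InteractomeGraph, path: str | Path) -> None:
    nx.write_graphml(g.graph, path)
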