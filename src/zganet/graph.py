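"""Undirected weighted graphs for protein–protein interaction networks.

The graph model follows the usual conventions of weighted community
detection: the weight :math:`A_{ij} > 0` of an edge measures interaction
strength, the (weighted) degree of node *i* is :math:`k_i = \\sum_j A_{ij}`,
and the total edge weight is :math:`m = \\tfrac12 \\sum_{ij} A_{ij}`, so that
:math:`\\sum_i k_i = 2m` holds exactly.

Self-loops are rejected in input edge lists.  They arise only internally,
when Louvain aggregation collapses a community into a super-node: a
community whose members are joined by internal weight *w* becomes a
super-node with self-weight *w*, contributing ``2w`` to that node's degree
and ``w`` to *m*.  This keeps the degree identity — and therefore
modularity — exact under aggregation.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Hashable, Iterable, Iterator, Tuple

Node = Hashable


class GraphError(ValueError):
    """Raised for malformed edge lists or invalid graph operations."""


class WeightedGraph:
    """Undirected weighted graph with O(1) degree and total-weight queries.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v, weight)`` triples, ``u != v``, ``weight > 0``.
        Duplicate pairs (either orientation) keep the maximum weight.
    """

    def __init__(self, edges: Iterable[Tuple[Node, Node, float]] = ()) -> None:
        self._adj: Dict[Node, Dict[Node, float]] = {}
        self._self_weight: Dict[Node, float] = {}
        self._m: float = 0.0
        for u, v, w in edges:
            self.add_edge(u, v, w)

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> None:
        if node not in self._adj:
            self._adj[node] = {}
            self._self_weight[node] = 0.0

    def add_edge(self, u: Node, v: Node, weight: float) -> None:
        """Add (or overwrite) the undirected edge u–v."""
        if u == v:
            raise GraphError(f"self-loop on node {u!r} is not allowed in input")
        if not weight > 0:
            raise GraphError(f"edge {u!r}–{v!r} has non-positive weight {weight}")
        self.add_node(u)
        self.add_node(v)
        old = self._adj[u].get(v)
        if old is not None:
            self._m -= old
        self._adj[u][v] = weight
        self._adj[v][u] = weight
        self._m += weight

    def add_self_weight(self, node: Node, weight: float) -> None:
        """Attach internal (aggregated) weight to ``node``.

        Contributes ``2*weight`` to the node's degree and ``weight`` to m.
        Used by Louvain aggregation; not representable in edge-list input.
        """
        if weight < 0:
            raise GraphError("self-weight must be non-negative")
        self.add_node(node)
        self._m -= self._self_weight[node]
        self._self_weight[node] = weight
        self._m += weight

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list:
        return list(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    @property
    def total_weight(self) -> float:
        """m = half the sum of all A_ij (self-weights counted once)."""
        return self._m

    def __contains__(self, node: Node) -> bool:
        return node in self._adj

    def neighbors(self, node: Node) -> Dict[Node, float]:
        return self._adj[node]

    def self_weight(self, node: Node) -> float:
        return self._self_weight.get(node, 0.0)

    def edge_weight(self, u: Node, v: Node, default: float = 0.0) -> float:
        return self._adj.get(u, {}).get(v, default)

    def edges(self) -> Iterator[Tuple[Node, Node, float]]:
        """Yield each undirected edge once (insertion order of endpoints)."""
        seen = set()
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield u, v, w

    def degree(self, node: Node) -> float:
        """Weighted degree k_i = sum_j A_ij; a self-weight counts twice."""
        return sum(self._adj[node].values()) + 2.0 * self._self_weight[node]

    def unweighted_degree(self, node: Node) -> int:
        return len(self._adj[node])

    def degrees(self) -> Dict[Node, float]:
        return {n: self.degree(n) for n in self._adj}

    def copy(self) -> "WeightedGraph":
        g = WeightedGraph()
        for n in self._adj:
            g.add_node(n)
        for u, v, w in self.edges():
            g.add_edge(u, v, w)
        for n, w in self._self_weight.items():
            if w:
                g.add_self_weight(n, w)
        return g


def load_edge_list(path, weight_scale: float | None = None) -> WeightedGraph:
    """Read a TSV edge list (node_a, node_b[, weight]) into a WeightedGraph.

    A header line is auto-detected (third field non-numeric, or first line
    matching common column names).  Missing weights default to 1.0.
    ``weight_scale`` divides every weight, e.g. 1000 to map STRING
    combined_score (0–1000) onto [0, 1].  Duplicate pairs in either
    orientation are merged keeping the maximum weight, with a warning when
    the weights differ.
    """
    graph = WeightedGraph()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GraphError(f"{path}:{lineno}: expected >= 2 columns")
            u, v = fields[0], fields[1]
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) >= 3 and fields[2] != "":
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise GraphError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if weight_scale is not None:
                w = w / weight_scale
            if u == v:
                raise GraphError(f"{path}:{lineno}: self-pair {u!r}")
            if not w > 0:
                raise GraphError(f"{path}:{lineno}: non-positive weight {w}")
            old = graph.edge_weight(u, v)
            if old:
                if old != w:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate edge {u}–{v} with differing "
                        f"weights ({old} vs {w}); keeping max",
                        stacklevel=2,
                    )
                graph.add_edge(u, v, max(old, w))
            else:
                graph.add_edge(u, v, w)
    return graph


def _looks_like_header(fields) -> bool:
    if len(fields) >= 3:
        try:
            float(fields[2])
            return False
        except ValueError:
            return True
    lowered = [f.lower() for f in fields[:2]]
    header_names = {"node_a", "node_b", "protein1", "protein2", "source", "target"}
    return bool(header_names.intersection(lowered))


def write_edge_list(graph: WeightedGraph, path) -> None:
    """Write the graph as a TSV edge list with a node_a/node_b/weight header."""
    with Path(path).open("w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, w in graph.edges():
            fh.write(f"{u}\t{v}\t{w!r}\n")


def node_degrees(graph: WeightedGraph):
    """Per-node weighted and unweighted degrees plus the maximum.

    Returns a dict with keys ``weighted``, ``unweighted``, ``max_weighted``,
    ``max_unweighted`` (max keys are None on an empty graph).
    """
    weighted = {n: graph.degree(n) for n in graph.nodes}
    unweighted = {n: graph.unweighted_degree(n) for n in graph.nodes}
    return {
        "weighted": weighted,
        "unweighted": unweighted,
        "max_weighted": max(weighted.values(), default=None),
        "max_unweighted": max(unweighted.values(), default=None),
    }


def filter_by_degree(
    graph: WeightedGraph, threshold: float = 200.0, mode: str = "weighted"
) -> WeightedGraph:
    """Induced subgraph on nodes with original-graph degree strictly above threshold.

    Degrees are computed once on the input graph; the surviving node set is
    `{i : k_i > threshold}` (strict), then the subgraph is induced on it in a
    single pass — degrees are NOT iteratively recomputed, so low-degree
    nodes dragged below the cut by their neighbours' removal still survive.
    The default threshold of 200 mirrors hub-core extraction on STRING-scale
    PPI networks.
    """
    if mode == "weighted":
        keep = {n for n in graph.nodes if graph.degree(n) > threshold}
    elif mode == "unweighted":
        keep = {n for n in graph.nodes if graph.unweighted_degree(n) > threshold}
    else:
        raise ValueError(f"mode must be 'weighted' or 'unweighted', got {mode!r}")
    if not keep:
        warnings.warn("degree filter removed every node", stacklevel=2)
    return induce_subgraph(graph, keep, _warn_empty=False)


def induce_subgraph(
    graph: WeightedGraph, node_set: Iterable[Node], _warn_empty: bool = True
) -> WeightedGraph:
    """Subgraph induced on ``node_set`` intersected with the graph's nodes."""
    keep = set(node_set).intersection(graph.nodes)
    if not keep and _warn_empty:
        warnings.warn("induced subgraph is empty", stacklevel=2)
    sub = WeightedGraph()
    for n in graph.nodes:
        if n in keep:
            sub.add_node(n)
    for u, v, w in graph.edges():
        if u in keep and v in keep:
            sub.add_edge(u, v, w)
    return sub


def write_node_report(graph: WeightedGraph, path, threshold: float = 200.0) -> None:
    """TSV of node, weighted_degree, unweighted_degree, retained_flag."""
    with Path(path).open("w") as fh:
        fh.write("node\tweighted_degree\tunweighted_degree\tretained\n")
        for n in graph.nodes:
            kw = graph.degree(n)
            fh.write(f"{n}\t{kw!r}\t{graph.unweighted_degree(n)}\t{int(kw > threshold)}\n")
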