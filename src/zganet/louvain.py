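"""Weighted Louvain community detection, written from scratch.

The algorithm greedily maximizes modularity

.. math::

    Q = \\frac{1}{2m} \\sum_{ij} \\left( A_{ij} -
        \\frac{k_i k_j}{2m} \\right) \\delta(c_i, c_j)

by alternating two phases: a *local moving* phase, where each node is moved
to the neighbouring community with the largest positive modularity gain
:math:`\\Delta Q`, and an *aggregation* phase, where communities collapse
into super-nodes carrying their internal weight as a self-weight.  The two
phases repeat until a level no longer improves Q, yielding a hierarchy of
partitions.

The gain of inserting an isolated node *i* (degree :math:`k_i`, weight
:math:`k_{i,\\mathrm{in}}` to community *c*) into *c* is

.. math::

    \\Delta Q = \\frac{k_{i,\\mathrm{in}}}{m}
        - \\frac{\\Sigma_{tot,c}\\, k_i}{2m^2},

the standard algebraic reduction of the textbook expression with
:math:`\\Sigma_{in}`/:math:`\\Sigma_{tot}` bookkeeping.  A general move is
evaluated as insert-gain(target) − insert-gain(source) after provisionally
removing the node, which keeps the isolated-node premise of the printed
gain formula intact; every accepted move is exactly consistent with a
from-scratch recomputation of Q (tested to 1e-10).

A brute-force maximizer over all set partitions is provided as a test
oracle for graphs of up to ~10 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Tuple

import numpy as np

from .graph import WeightedGraph

Node = Hashable


class Partition:
    """Node → community labels with Σ_in / Σ_tot bookkeeping.

    ``sigma_tot[c]`` is the summed degree of members of *c*;
    ``sigma_in[c]`` is :math:`\\sum_{i,j \\in c} A_{ij}` over *ordered*
    pairs, i.e. twice the internal edge weight (self-weights, which stand
    for aggregated internal weight, also count twice).  Modularity is then
    ``sum_c [sigma_in/(2m) - (sigma_tot/(2m))^2]``.
    """

    def __init__(self, graph: WeightedGraph, labels: Dict[Node, int]):
        if set(labels) != set(graph.nodes):
            raise ValueError("partition must cover exactly the graph's nodes")
        self.graph = graph
        self.labels = dict(labels)
        self.sigma_tot: Dict[int, float] = {}
        self.sigma_in: Dict[int, float] = {}
        for node, c in self.labels.items():
            self.sigma_tot[c] = self.sigma_tot.get(c, 0.0) + graph.degree(node)
            self.sigma_in.setdefault(c, 0.0)
            self.sigma_in[c] += 2.0 * graph.self_weight(node)
        for u, v, w in graph.edges():
            if self.labels[u] == self.labels[v]:
                self.sigma_in[self.labels[u]] += 2.0 * w

    @classmethod
    def singletons(cls, graph: WeightedGraph) -> "Partition":
        return cls(graph, {n: i for i, n in enumerate(graph.nodes)})

    def copy(self) -> "Partition":
        return Partition(self.graph, self.labels)

    def communities(self) -> Dict[int, List[Node]]:
        out: Dict[int, List[Node]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        return out

    def neighbour_community_weights(self, node: Node) -> Dict[int, float]:
        """k_{i,in}(c) for every community adjacent to ``node`` (self excluded)."""
        weights: Dict[int, float] = {}
        for nbr, w in self.graph.neighbors(node).items():
            c = self.labels[nbr]
            weights[c] = weights.get(c, 0.0) + w
        return weights

    def remove_node(self, node: Node, k_in_own: float) -> int:
        """Provisionally detach ``node`` from its community; returns old label."""
        c = self.labels[node]
        self.sigma_tot[c] -= self.graph.degree(node)
        self.sigma_in[c] -= 2.0 * k_in_own + 2.0 * self.graph.self_weight(node)
        self.labels[node] = -1  # sentinel: detached
        return c

    def insert_node(self, node: Node, community: int, k_in: float) -> None:
        self.labels[node] = community
        self.sigma_tot[community] = (
            self.sigma_tot.get(community, 0.0) + self.graph.degree(node)
        )
        self.sigma_in[community] = (
            self.sigma_in.get(community, 0.0)
            + 2.0 * k_in
            + 2.0 * self.graph.self_weight(node)
        )

    def modularity(self) -> float:
        m = self.graph.total_weight
        if m <= 0:
            raise ValueError("modularity undefined for a graph with m = 0")
        two_m = 2.0 * m
        q = 0.0
        for c, s_tot in self.sigma_tot.items():
            if s_tot == 0.0 and self.sigma_in.get(c, 0.0) == 0.0:
                continue  # emptied community
            q += self.sigma_in.get(c, 0.0) / two_m - (s_tot / two_m) ** 2
        return q


def modularity(graph: WeightedGraph, labels_or_partition) -> float:
    """Modularity Q of a partition, Q ∈ [−1, 1].

    Accepts either a :class:`Partition` or a plain node → label mapping.
    """
    if isinstance(labels_or_partition, Partition):
        return labels_or_partition.modularity()
    return Partition(graph, labels_or_partition).modularity()


def modularity_direct(graph: WeightedGraph, labels: Dict[Node, int]) -> float:
    """Q via the literal double sum over node pairs — O(n^2) oracle form."""
    m = graph.total_weight
    if m <= 0:
        raise ValueError("modularity undefined for a graph with m = 0")
    two_m = 2.0 * m
    nodes = graph.nodes
    deg = {n: graph.degree(n) for n in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if labels[i] != labels[j]:
                continue
            if i == j:
                a_ij = 2.0 * graph.self_weight(i)
            else:
                a_ij = graph.edge_weight(i, j)
            q += a_ij - deg[i] * deg[j] / two_m
    return q / two_m


def _insert_gain(graph: WeightedGraph, partition: Partition, node: Node,
                 community: int, k_in: float) -> float:
    """ΔQ of inserting detached ``node`` into ``community``."""
    m = graph.total_weight
    k_i = graph.degree(node)
    s_tot = partition.sigma_tot.get(community, 0.0)
    return k_in / m - s_tot * k_i / (2.0 * m * m)


def delta_q_move(graph: WeightedGraph, partition: Partition, node: Node,
                 target_community: int) -> float:
    """Modularity change of moving ``node`` to ``target_community``.

    Equals ``modularity(after) - modularity(before)`` to ~1e-15; the move
    is *not* applied.
    """
    if target_community not in partition.sigma_tot:
        raise ValueError(f"community {target_community!r} does not exist")
    source = partition.labels[node]
    if source == target_community:
        return 0.0
    k_by_comm = partition.neighbour_community_weights(node)
    k_in_own = k_by_comm.get(source, 0.0)
    partition.remove_node(node, k_in_own)
    gain_target = _insert_gain(
        graph, partition, node, target_community, k_by_comm.get(target_community, 0.0)
    )
    gain_source = _insert_gain(graph, partition, node, source, k_in_own)
    partition.insert_node(node, source, k_in_own)  # restore
    return gain_target - gain_source


def local_moving_phase(
    graph: WeightedGraph,
    partition: Partition,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> Tuple[Partition, bool]:
    """Sweep nodes, greedily accepting the best strictly positive ΔQ move.

    Nodes are visited in a seeded-shuffle order per sweep (or in sorted
    order when ``deterministic``); sweeps repeat until one completes with
    zero accepted moves.  Ties between equal best gains go to the lowest
    community id.  Returns the (mutated) partition and whether any move
    was accepted.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    nodes = sorted(graph.nodes, key=repr)
    improved = False
    while True:
        if deterministic:
            order = nodes
        else:
            order = list(nodes)
            rng.shuffle(order)
        moves = 0
        for node in order:
            source = partition.labels[node]
            k_by_comm = partition.neighbour_community_weights(node)
            k_in_own = k_by_comm.get(source, 0.0)
            partition.remove_node(node, k_in_own)
            gain_stay = _insert_gain(graph, partition, node, source, k_in_own)
            best_comm, best_gain = source, 0.0
            for comm in sorted(k_by_comm):
                if comm == source:
                    continue
                gain = _insert_gain(graph, partition, node, comm, k_by_comm[comm])
                delta = gain - gain_stay
                if delta > best_gain or (delta == best_gain > 0.0 and comm < best_comm):
                    best_comm, best_gain = comm, delta
            partition.insert_node(node, best_comm, k_by_comm.get(best_comm, k_in_own))
            if best_comm != source:
                moves += 1
                improved = True
        if moves == 0:
            return partition, improved


def aggregate_graph(graph: WeightedGraph, partition: Partition) -> WeightedGraph:
    """Collapse each community into a super-node.

    Inter-community edges sum crossing weights; each super-node carries the
    community's internal weight (edges + member self-weights) as its
    self-weight, so that the identity partition of the aggregate has
    exactly the modularity of ``partition`` on the original graph.
    """
    agg = WeightedGraph()
    for c in sorted({partition.labels[n] for n in graph.nodes}):
        agg.add_node(c)
    internal: Dict[int, float] = {}
    for n in graph.nodes:
        c = partition.labels[n]
        internal[c] = internal.get(c, 0.0) + graph.self_weight(n)
    for u, v, w in graph.edges():
        cu, cv = partition.labels[u], partition.labels[v]
        if cu == cv:
            internal[cu] = internal.get(cu, 0.0) + w
        else:
            agg.add_edge(cu, cv, agg.edge_weight(cu, cv) + w)
    for c, w in internal.items():
        if w:
            agg.add_self_weight(c, w)
    return agg


@dataclass
class LouvainResult:
    """Outcome of a full Louvain run."""

    labels: Dict[Node, int]                     # final flat partition, original nodes
    levels: List[Dict[Node, int]] = field(default_factory=list)  # per-level flats
    q_trajectory: List[float] = field(default_factory=list)
    seed: int = 0
    n_levels: int = 0

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def community_sizes(self) -> Dict[int, int]:
        sizes: Dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes


def run_louvain(
    graph: WeightedGraph,
    seed: int = 0,
    min_gain: float = 1e-10,
    deterministic: bool = False,
) -> LouvainResult:
    """Full two-phase Louvain loop until modularity converges.

    Levels alternate local moving and super-node aggregation; the loop
    stops when a level improves Q by less than ``min_gain``.  Community
    ids in the returned flat partition are relabeled 0, 1, ... by
    descending community size (ties by smallest member, for determinism).
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot run Louvain on an empty graph")
    if not graph.total_weight > 0:
        raise ValueError("cannot run Louvain on a graph with no edge weight")
    rng = np.random.default_rng(seed)
    current = graph
    # flat[n] = community of original node n in the current level's graph
    flat: Dict[Node, Node] = {n: n for n in graph.nodes}
    levels: List[Dict[Node, int]] = []
    q_traj: List[float] = []
    q_prev = Partition.singletons(graph).modularity()
    while True:
        partition = Partition.singletons(current)
        partition, improved = local_moving_phase(
            current, partition, rng, deterministic
        )
        q = partition.modularity()
        if not improved or q - q_prev < min_gain:
            break
        flat = {n: partition.labels[flat[n]] for n in flat}
        levels.append(dict(flat))
        q_traj.append(q)
        q_prev = q
        current = aggregate_graph(current, partition)
    final = levels[-1] if levels else dict(flat)  # no gain anywhere: singletons
    relabeled = _relabel_by_size(final)
    return LouvainResult(
        labels=relabeled,
        levels=[_relabel_by_size(lv) for lv in levels] or [relabeled],
        q_trajectory=q_traj or [q_prev],
        seed=seed,
        n_levels=max(len(levels), 1),
    )


def _relabel_by_size(labels: Dict[Node, int]) -> Dict[Node, int]:
    sizes: Dict[int, list] = {}
    for n, c in labels.items():
        sizes.setdefault(c, []).append(n)
    order = sorted(sizes, key=lambda c: (-len(sizes[c]), repr(min(sizes[c], key=repr))))
    remap = {c: i for i, c in enumerate(order)}
    return {n: remap[c] for n, c in labels.items()}


def _set_partitions(items: List[Node]):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def brute_force_max_modularity(
    graph: WeightedGraph, max_nodes: int = 8
) -> Tuple[Dict[Node, int], float]:
    """Globally optimal partition by exhaustive set-partition search.

    Bell-number growth restricts this to ~``max_nodes`` nodes; intended as
    an exactness oracle for :func:`run_louvain` on tiny fixtures.
    """
    nodes = graph.nodes
    if len(nodes) > max_nodes:
        raise ValueError(
            f"{len(nodes)} nodes exceeds brute-force limit {max_nodes}"
        )
    best_q = -np.inf
    best: Dict[Node, int] = {}
    for blocks in _set_partitions(nodes):
        labels = {n: i for i, block in enumerate(blocks) for n in block}
        q = modularity(graph, labels)
        if q > best_q:
            best_q, best = q, labels
    return best, best_q
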