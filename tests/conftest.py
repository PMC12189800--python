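"""Shared fixtures: tiny hand-checkable graphs and seeded random generators."""

import numpy as np
import pytest

from zganet import WeightedGraph


@pytest.fixture
def single_edge():
    return WeightedGraph([("a", "b", 1.0)])


@pytest.fixture
def two_triangles():
    return WeightedGraph(
        [
            ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
            ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0),
        ]
    )


@pytest.fixture
def triangle_labels():
    return {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}


def complete_graph(n: int) -> WeightedGraph:
    g = WeightedGraph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(f"n{i}", f"n{j}", 1.0)
    return g


def path_graph(labels=("a", "b", "c")) -> WeightedGraph:
    g = WeightedGraph()
    for u, v in zip(labels, labels[1:]):
        g.add_edge(u, v, 1.0)
    return g


def random_weighted_graph(rng: np.random.Generator, n: int = 12, p: float = 0.4):
    """Connected-ish G(n, p) with Uniform(0.2, 2) weights; retries until m > 0."""
    while True:
        g = WeightedGraph()
        for i in range(n):
            g.add_node(i)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(i, j, float(rng.uniform(0.2, 2.0)))
        if g.total_weight > 0:
            return g


def random_partition(rng: np.random.Generator, g: WeightedGraph, n_comm: int = 4):
    return {node: int(rng.integers(n_comm)) for node in g.nodes}


# the <= 8-node oracle fixture suite: (name, graph builder, is_disjoint_cliques)
def oracle_suite():
    return [
        ("single_edge", WeightedGraph([("a", "b", 1.0)]), True),
        ("path3", path_graph(), False),
        ("triangle", complete_graph(3), True),
        (
            "two_triangles",
            WeightedGraph(
                [
                    ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                    ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0),
                ]
            ),
            True,
        ),
        ("k5", complete_graph(5), True),
        (
            "two_k4",
            WeightedGraph(
                [(f"a{i}", f"a{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
                + [(f"b{i}", f"b{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
            ),
            True,
        ),
        (
            "barbell",
            WeightedGraph(
                [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("c", "d", 1.0),
                 ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0)]
            ),
            False,
        ),
        (
            "weighted_star",
            WeightedGraph([("hub", f"leaf{i}", 0.5 + 0.25 * i) for i in range(5)]),
            False,
        ),
        (
            "cycle8",
            WeightedGraph(
                [(f"c{i}", f"c{(i + 1) % 8}", 1.0) for i in range(8)]
            ),
            False,
        ),
    ]
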