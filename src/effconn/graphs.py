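"""Shared graph containers: undirected skeletons and directed acyclic graphs.

Nodes are ROI labels (strings).  An undirected adjacency is stored as the
sorted pair ``(min(u, v), max(u, v))``; a directed edge as ``(source, target)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

Pair = tuple[str, str]

#: Canonical condition labels of the 7-condition block design:
#: three preparation periods, three task (n-back) periods, and rest.
CONDITIONS: tuple[str, ...] = (
    "prep1", "prep2", "prep3", "task1", "task2", "task3", "rest",
)
LOADS: tuple[int, ...] = (1, 2, 3)


def undirected(u: str, v: str) -> Pair:
    """Canonical unordered pair for an adjacency between ``u`` and ``v``."""
    if u == v:
        raise ValueError(f"self-loop on node {u!r}")
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Skeleton:
    """Undirected projection of a graph: adjacencies without directions."""

    nodes: tuple[str, ...]
    edges: frozenset[Pair]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u > v:
                raise ValueError(f"edge {(u, v)} not in canonical sorted order")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {(u, v)} references unknown node")

    @classmethod
    def from_pairs(cls, nodes: Iterable[str], pairs: Iterable[tuple[str, str]]) -> "Skeleton":
        return cls(tuple(nodes), frozenset(undirected(u, v) for u, v in pairs))

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def triangles(self) -> list[tuple[str, str, str]]:
        """All node triples that are pairwise adjacent, sorted."""
        adj = self.adjacency()
        found = set()
        for u, v in self.edges:
            for w in adj[u] & adj[v]:
                found.add(tuple(sorted((u, v, w))))
        return sorted(found)  # type: ignore[arg-type]

    def has_triangle(self) -> bool:
        adj = self.adjacency()
        return any(adj[u] & adj[v] for u, v in self.edges)


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over ROI labels.

    ``edges`` holds ordered ``(source, target)`` pairs; acyclicity is
    enforced at construction.
    """

    nodes: tuple[str, ...]
    edges: frozenset[Pair]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for s, t in self.edges:
            if s == t:
                raise ValueError(f"self-loop on node {s!r}")
            if s not in node_set or t not in node_set:
                raise ValueError(f"edge {(s, t)} references unknown node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(s for s, t in self.edges if t == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(t for s, t in self.edges if s == node))

    def skeleton(self) -> Skeleton:
        return Skeleton(self.nodes, frozenset(undirected(s, t) for s, t in self.edges))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))


def edges_to_dot(edges: Iterable[tuple[str, str]], directed: bool = True,
                 weights: dict | None = None) -> str:
    """Render an edge list as Graphviz DOT text."""
    kind, arrow = ("digraph", "->") if directed else ("graph", "--")
    lines = [f"{kind} G {{"]
    for e in sorted(edges):
        label = ""
        if weights is not None and e in weights:
            label = f' [label="{weights[e]:.2f}"]'
        lines.append(f'  "{e[0]}" {arrow} "{e[1]}"{label};')
    lines.append("}")
    return "\n".join(lines) + "\n"
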