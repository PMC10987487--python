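"""Temporal network container: a simple undirected graph plus edge arrival history.

The central object of the package is a grown network whose edges carry either a
fine-grained arrival position ``alpha_i`` (a bijection onto ``{1..E}``) or a
coarse snapshot label (edges within one snapshot have indistinguishable order),
or both.  All downstream machinery — edge views, pairwise comparators, Borda
aggregation, error theory — consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import networkx as nx

Node = Hashable
Edge = Tuple[Node, Node]


def canonical_edge(u: Node, v: Node) -> Edge:
    """Return the unordered edge (u, v) in a canonical orientation."""
    try:
        return (u, v) if u <= v else (v, u)  # type: ignore[operator]
    except TypeError:
        return (u, v) if str(u) <= str(v) else (v, u)


@dataclass
class TemporalNetwork:
    """An undirected simple graph whose edges are ordered by arrival.

    Parameters
    ----------
    edges
        Edge list in arrival order; position ``i`` (0-based) corresponds to
        arrival position ``alpha = i + 1`` (1-based, oldest first).
    snapshots
        Optional coarse labels, one per edge in the same order, non-decreasing
        integers starting at 1.
    node_labels
        Optional per-node category strings (e.g. protein functional classes)
        for meso-level analysis.
    """

    edges: List[Edge]
    snapshots: Optional[List[int]] = None
    node_labels: Optional[Dict[Node, str]] = None
    extra_nodes: List[Node] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon = [canonical_edge(u, v) for u, v in self.edges]
        seen = set()
        for k, (u, v) in enumerate(canon):
            if u == v:
                raise ValueError(f"self-loop at arrival position {k + 1}: {u!r}")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge at arrival position {k + 1}: {(u, v)!r}")
            seen.add((u, v))
        self.edges = canon
        if self.snapshots is not None:
            if len(self.snapshots) != len(self.edges):
                raise ValueError("snapshot labels must match the number of edges")
            labs = list(self.snapshots)
            if any(b < a for a, b in zip(labs, labs[1:])):
                raise ValueError("snapshot labels must be non-decreasing along arrival order")
            self.snapshots = labs

    # -- basic accessors ---------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> List[Node]:
        out: List[Node] = []
        seen = set()
        for u, v in self.edges:
            for w in (u, v):
                if w not in seen:
                    seen.add(w)
                    out.append(w)
        for w in self.extra_nodes:
            if w not in seen:
                seen.add(w)
                out.append(w)
        return out

    @property
    def arrival(self) -> Dict[Edge, int]:
        """1-based arrival position per edge."""
        return {e: i + 1 for i, e in enumerate(self.edges)}

    def snapshot_sizes(self) -> List[int]:
        """Edge counts l_1..l_n of the coarse snapshots."""
        if self.snapshots is None:
            raise ValueError("network has no snapshot labels")
        sizes: List[int] = []
        prev = None
        for s in self.snapshots:
            if s != prev:
                sizes.append(0)
                prev = s
            sizes[-1] += 1
        return sizes

    def graph(self) -> nx.Graph:
        """The final topology as a networkx graph (arrival info dropped)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def subnetwork(self, n_first_edges: int) -> "TemporalNetwork":
        """The network formed by the first ``n_first_edges`` arrivals."""
        if not 0 <= n_first_edges <= self.n_edges:
            raise ValueError("n_first_edges out of range")
        snaps = self.snapshots[:n_first_edges] if self.snapshots is not None else None
        return TemporalNetwork(self.edges[:n_first_edges], snapshots=snaps,
                               node_labels=self.node_labels)

    def reordered(self, order: Sequence[int]) -> "TemporalNetwork":
        """Same topology with edges re-ordered; ``order[k]`` is the 1-based
        arrival position assigned to input edge ``k``."""
        if sorted(order) != list(range(1, self.n_edges + 1)):
            raise ValueError("order must be a permutation of 1..E")
        new_edges: List[Edge] = [None] * self.n_edges  # type: ignore[list-item]
        for k, pos in enumerate(order):
            new_edges[pos - 1] = self.edges[k]
        return TemporalNetwork(new_edges, node_labels=self.node_labels)


def distinguishable_pair_count(net: TemporalNetwork) -> int:
    """Number of unordered edge pairs whose relative age is knowable.

    With fine order all E(E-1)/2 pairs are distinguishable; with snapshots the
    pairs inside one snapshot are not: the count is
    ``E(E-1)/2 - sum_k l_k (l_k - 1) / 2``.
    """
    e = net.n_edges
    total = e * (e - 1) // 2
    if net.snapshots is None:
        return total
    return total - sum(l * (l - 1) // 2 for l in net.snapshot_sizes())
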