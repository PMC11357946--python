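"""Louvain community detection with explicit modularity bookkeeping.

Newman modularity of a partition of an undirected graph is

    Q = sum_c [ L_c / m  -  (D_c / 2m)^2 ]

with m the total edge weight, L_c the weight of edges inside community
c, and D_c the total degree of c's nodes. The Louvain heuristic greedily
maximizes Q in two alternating phases: local moves of single nodes into
the neighboring community with the largest positive modularity gain, and
aggregation of the resulting communities into super-nodes. Input
interactomes are unweighted; weights appear only on aggregated graphs,
where parallel edges collapse to weighted edges and intra-community
edges become self-loops.

The gain of inserting an isolated node i (weighted degree k_i, with
k_i_in weight toward community c) into c is

    dQ = k_i_in / m  -  D_c * k_i / (2 m^2)

which equals the brute-force modularity difference of the move.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx

from .errors import EdgelessGraphError, LookupError_

Node = Hashable

# floating-point slack for "equal gain" tie-breaking
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class CommunityPartition:
    """A hard partition of a graph's nodes with its modularity.

    Community ids are canonical: communities are numbered 0..k-1 in
    order of their smallest member label.
    """

    assignment: dict[Node, int]
    communities: dict[int, frozenset[Node]]
    modularity: float

    def __post_init__(self):
        covered = set()
        for cid, members in self.communities.items():
            for node in members:
                if self.assignment.get(node) != cid:
                    raise ValueError("communities inconsistent with assignment")
            covered |= members
        if covered != set(self.assignment):
            raise ValueError("communities do not cover the assignment")

    def __len__(self) -> int:
        return len(self.communities)

    def sizes(self) -> dict[int, int]:
        return {cid: len(members) for cid, members in self.communities.items()}


def modularity(net: nx.Graph, partition: Mapping[Node, object]) -> float:
    """Newman modularity Q of a node→community map over ``net``.

    Works for weighted graphs with self-loops (needed on aggregated
    graphs); a plain interactome reduces to intra-edge counts. Raises
    :class:`EdgelessGraphError` when m = 0.
    """
    m = net.size(weight="weight")
    if m == 0:
        raise EdgelessGraphError("modularity undefined: graph has no edges")
    missing = [n for n in net.nodes() if n not in partition]
    if missing:
        raise LookupError_(f"partition missing {len(missing)} nodes, e.g. {missing[0]!r}")
    intra: dict[object, float] = {}
    degree: dict[object, float] = {}
    for node, k in net.degree(weight="weight"):
        c = partition[node]
        degree[c] = degree.get(c, 0.0) + k
    for u, v, w in net.edges(data="weight", default=1):
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    two_m = 2.0 * m
    return sum(
        intra.get(c, 0.0) / m - (degree[c] / two_m) ** 2 for c in degree
    )


class LouvainState:
    """Mutable bookkeeping for one local-move phase on one graph level.

    Tracks, per community, the total intra-community edge weight
    (``internal``) and the summed weighted degree (``total_degree``),
    allowing O(deg) gain evaluation and node moves.
    """

    def __init__(self, graph: nx.Graph):
        if graph.size(weight="weight") == 0:
            raise EdgelessGraphError("Louvain undefined on an edgeless graph")
        self.graph = graph
        self.m = graph.size(weight="weight")
        self.node2com: dict[Node, int] = {n: i for i, n in enumerate(graph.nodes())}
        self.degree: dict[Node, float] = dict(graph.degree(weight="weight"))
        self.loop: dict[Node, float] = {
            n: graph[n][n].get("weight", 1) if graph.has_edge(n, n) else 0.0
            for n in graph.nodes()
        }
        self.internal: dict[int, float] = {
            self.node2com[n]: self.loop[n] for n in graph.nodes()
        }
        self.total_degree: dict[int, float] = {
            self.node2com[n]: self.degree[n] for n in graph.nodes()
        }

    def neighbor_weights(self, node: Node) -> dict[int, float]:
        """Total edge weight from ``node`` to each adjacent community."""
        weights: dict[int, float] = {}
        for neigh, data in self.graph[node].items():
            if neigh == node:
                continue
            c = self.node2com[neigh]
            weights[c] = weights.get(c, 0.0) + data.get("weight", 1)
        return weights

    def remove(self, node: Node, links_to_com: float) -> None:
        c = self.node2com[node]
        self.internal[c] -= links_to_com + self.loop[node]
        self.total_degree[c] -= self.degree[node]
        self.node2com[node] = -1

    def insert(self, node: Node, community: int, links_to_com: float) -> None:
        self.internal[community] = (
            self.internal.get(community, 0.0) + links_to_com + self.loop[node]
        )
        self.total_degree[community] = (
            self.total_degree.get(community, 0.0) + self.degree[node]
        )
        self.node2com[node] = community

    def gain(self, node: Node, community: int, links_to_com: float) -> float:
        """Modularity gain of inserting the (removed) node into ``community``."""
        return (
            links_to_com / self.m
            - self.total_degree.get(community, 0.0) * self.degree[node] / (2.0 * self.m**2)
        )

    def partition(self) -> dict[Node, int]:
        return dict(self.node2com)


def modularity_gain(state: LouvainState, node: Node, community: int) -> float:
    """Gain dQ of moving ``node`` (currently isolated in ``state``) into ``community``.

    Equals ``modularity(after) - modularity(before)`` on the state's
    graph, where "before" has the node in a singleton community.
    """
    if node not in state.node2com:
        raise LookupError_(f"unknown node {node!r}")
    if community not in state.total_degree:
        raise LookupError_(f"unknown community {community!r}")
    return state.gain(node, community, state.neighbor_weights(node).get(community, 0.0))


def _one_level(graph: nx.Graph, rng: random.Random) -> tuple[dict[Node, int], bool]:
    """One local-move phase; returns (node→community, any move made)."""
    state = LouvainState(graph)
    order = sorted(graph.nodes(), key=str)
    rng.shuffle(order)
    improved = False
    moved = True
    while moved:
        moved = False
        for node in order:
            current = state.node2com[node]
            weights = state.neighbor_weights(node)
            state.remove(node, weights.get(current, 0.0))
            best_com, best_gain = current, state.gain(
                node, current, weights.get(current, 0.0)
            )
            for com in sorted(weights):
                if com == current:
                    continue
                g = state.gain(node, com, weights[com])
                # strict improvement beyond tie tolerance; ties prefer the
                # current community, then the lowest community id
                if g > best_gain + _TIE_EPS or (
                    g > best_gain - _TIE_EPS and best_com != current and com < best_com
                ):
                    best_com, best_gain = com, g
            state.insert(node, best_com, weights.get(best_com, 0.0))
            if best_com != current:
                moved = improved = True
    return state.partition(), improved


def _aggregate(graph: nx.Graph, partition: Mapping[Node, int]) -> nx.Graph:
    """Phase-2 graph: one node per community, intra edges as self-loops."""
    agg = nx.Graph()
    agg.add_nodes_from(sorted(set(partition.values())))
    for u, v, w in graph.edges(data="weight", default=1):
        cu, cv = partition[u], partition[v]
        if agg.has_edge(cu, cv):
            agg[cu][cv]["weight"] += w
        else:
            agg.add_edge(cu, cv, weight=w)
    return agg


def _canonicalize(net: nx.Graph, assignment: Mapping[Node, int]) -> CommunityPartition:
    groups: dict[int, set[Node]] = {}
    for node, cid in assignment.items():
        groups.setdefault(cid, set()).add(node)
    ordered = sorted(groups.values(), key=lambda members: min(map(str, members)))
    final_assignment: dict[Node, int] = {}
    communities: dict[int, frozenset[Node]] = {}
    for new_id, members in enumerate(ordered):
        communities[new_id] = frozenset(members)
        for node in members:
            final_assignment[node] = new_id
    return CommunityPartition(
        assignment=final_assignment,
        communities=communities,
        modularity=modularity(net, final_assignment),
    )


def louvain(net: nx.Graph, seed: int = 0, max_passes: int | None = None) -> CommunityPartition:
    """Louvain community detection on an interactome.

    Alternates local moves (while any positive-gain move exists) with
    graph aggregation until modularity stops improving, or for at most
    ``max_passes`` levels. Deterministic for a given seed: node visit
    order is the seeded shuffle of the sorted labels, and ties prefer
    the current community, then the lowest community id. The returned
    partition's modularity is never below the singleton partition's.
    """
    if net.number_of_edges() == 0:
        raise EdgelessGraphError("Louvain undefined on an edgeless graph")
    rng = random.Random(seed)
    # node → community of the original graph, refined level by level
    membership = {n: i for i, n in enumerate(sorted(net.nodes(), key=str))}
    graph = _aggregate(net, membership)
    passes = 0
    while max_passes is None or passes < max_passes:
        passes += 1
        local, improved = _one_level(graph, rng)
        if not improved:
            break
        membership = {n: local[membership[n]] for n in membership}
        graph = _aggregate(graph, local)
    return _canonicalize(net, membership)
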