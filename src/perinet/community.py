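"""Modularity-based community detection on the transport network.

The directed transport graph is symmetrized (edge weights summed across the
two directions by default) and partitioned by greedy modularity optimization
(Louvain: local-move phase plus aggregation phase, repeated to a fixed
point).  Weighted Newman-Girvan modularity at resolution gamma:

    Q = (1/2m) * sum_uv [ w_uv - gamma * k_u k_v / 2m ] * delta(c_u, c_v)

where m is the total edge weight and k the weighted degree.  For graphs of
at most ten nodes an exhaustive oracle enumerates every set partition and
returns the global optimum, which bounds and validates the heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterator, Mapping

import networkx as nx
import numpy as np

from .network import TransportNetwork

_EXHAUSTIVE_MAX_NODES = 10


@dataclass(frozen=True)
class Partition:
    """Community assignment with contiguous labels 0..k-1 and its score."""

    assignment: dict[Hashable, int]
    n_communities: int
    modularity: float

    def communities(self) -> list[set]:
        groups: dict[int, set] = {}
        for node, label in self.assignment.items():
            groups.setdefault(label, set()).add(node)
        return [groups[k] for k in sorted(groups)]


@dataclass(frozen=True)
class DetectionParams:
    """Tunables for community detection.

    ``restarts`` runs the seeded heuristic from several starts (the first
    from all-singletons, the rest from random coarse partitions) and keeps
    the best-scoring result; greedy modularity search on small dense graphs
    in particular benefits from the added diversity.
    """

    resolution: float = 1.0
    seed: int = 0
    symmetrization: str = "sum"
    weighted: bool = True
    restarts: int = 8

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.symmetrization not in ("sum", "max"):
            raise ValueError("symmetrization must be 'sum' or 'max'")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def symmetrize(network: TransportNetwork, mode: str = "sum") -> nx.Graph:
    """Collapse the directed graph to an undirected weighted graph.

    Under ``sum`` the undirected weight is w(u->v) + w(v->u), so the total
    undirected weight equals the directed total volume; ``max`` keeps the
    larger direction.
    """
    if mode not in ("sum", "max"):
        raise ValueError("mode must be 'sum' or 'max'")
    out = nx.Graph()
    out.add_nodes_from(network.graph.nodes(data=True))
    for u, v, d in network.graph.edges(data=True):
        w = float(d["weight"])
        if out.has_edge(u, v):
            prev = out[u][v]["weight"]
            out[u][v]["weight"] = prev + w if mode == "sum" else max(prev, w)
        else:
            out.add_edge(u, v, weight=w)
    return out


def _canonicalize(assignment: Mapping[Hashable, int]) -> dict[Hashable, int]:
    """Relabel communities 0..k-1 in order of their smallest member node."""
    groups: dict[int, list] = {}
    for node, label in assignment.items():
        groups.setdefault(label, []).append(node)
    order = sorted(groups, key=lambda lab: min(map(str, groups[lab])))
    relabel = {lab: i for i, lab in enumerate(order)}
    return {node: relabel[lab] for node, lab in assignment.items()}


def modularity(
    graph: nx.Graph, assignment: Mapping[Hashable, int], resolution: float = 1.0
) -> float:
    """Weighted modularity of a node->community assignment.

    With every node in one community Q = 1 - 1 = 0 exactly (no self-loop
    convention: absent self-loops the within weight is all of m and the null
    term is (2m/2m)^2).
    """
    if not assignment:
        raise ValueError("empty partition")
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    m = graph.size(weight="weight")
    if m <= 0:
        raise ValueError("graph has zero total weight")
    within = 0.0
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        if assignment[u] == assignment[v]:
            # a self-loop appears once in the ordered double sum per (u,u)
            within += w if u == v else 2.0 * w
    degree = dict(graph.degree(weight="weight"))
    totals: dict[int, float] = {}
    for node, label in assignment.items():
        totals[label] = totals.get(label, 0.0) + degree[node]
    null = sum((t / (2.0 * m)) ** 2 for t in totals.values())
    return within / (2.0 * m) - resolution * null


def _adjacency(graph: nx.Graph, weighted: bool) -> dict:
    adj: dict = {u: {} for u in graph.nodes}
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0)) if weighted else 1.0
        adj[u][v] = adj[u].get(v, 0.0) + w
        if u != v:
            adj[v][u] = adj[v].get(u, 0.0) + w
    return adj


def _local_moves(adj, comm, k, ctot, two_m, gamma, order) -> bool:
    """One pass of greedy node moves; returns True if anything moved."""
    improved = False
    moved = True
    while moved:
        moved = False
        for u in order:
            cu = comm[u]
            ku = k[u]
            ctot[cu] -= ku
            links: dict[int, float] = {}
            for v, w in adj[u].items():
                if v == u:
                    continue
                links[comm[v]] = links.get(comm[v], 0.0) + w
            best_c, best_gain = cu, links.get(cu, 0.0) - gamma * ku * ctot[cu] / two_m
            for c, wuc in sorted(links.items()):
                gain = wuc - gamma * ku * ctot[c] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            ctot[best_c] += ku
            if best_c != cu:
                comm[u] = best_c
                moved = improved = True
    return improved


def _aggregate(adj, comm):
    """Collapse communities into supernodes; internal weight -> self-loop.

    The symmetric dict stores each unordered pair twice (once per row) and a
    self-loop once, so internal off-diagonal weight is halved when folded
    into the supernode self-loop.
    """
    new_adj: dict = {}
    for u, nbrs in adj.items():
        cu = comm[u]
        row = new_adj.setdefault(cu, {})
        for v, w in nbrs.items():
            cv = comm[v]
            if cu == cv:
                row[cv] = row.get(cv, 0.0) + (w if u == v else 0.5 * w)
            else:
                row[cv] = row.get(cv, 0.0) + w
    return new_adj


def _louvain_once(graph: nx.Graph, gamma: float, rng: np.random.Generator,
                  weighted: bool, init: Mapping | None = None) -> dict:
    """One multilevel greedy run; ``init`` seeds the first-level partition
    (defaults to all-singletons)."""
    adj = _adjacency(graph, weighted)
    two_m = sum(sum(nbrs.values()) for nbrs in adj.values())
    for u in adj:  # self-loops stored once but count twice in 2m
        if u in adj[u]:
            two_m += adj[u][u]
    if two_m <= 0:
        raise ValueError("graph has zero total weight")
    node_to_final: dict = {u: u for u in graph.nodes}
    first = True
    while True:
        k = {
            u: sum(w for v, w in adj[u].items() if v != u)
            + 2.0 * adj[u].get(u, 0.0)
            for u in adj
        }
        if first and init is not None:
            comm = {u: int(init[u]) for u in adj}
        else:
            comm = {u: i for i, u in enumerate(sorted(adj, key=str))}
        ctot: dict = {}
        for u in adj:
            ctot[comm[u]] = ctot.get(comm[u], 0.0) + k[u]
        order = list(sorted(adj, key=str))
        rng.shuffle(order)
        improved = _local_moves(adj, comm, k, ctot, two_m, gamma, order)
        node_to_final = {u: comm[node_to_final[u]] for u in node_to_final}
        new_adj = _aggregate(adj, comm)
        if not improved or len(new_adj) == len(adj):
            break
        adj = new_adj
        first = False
    return dict(node_to_final)


def louvain(graph: nx.Graph, params: DetectionParams = DetectionParams()) -> Partition:
    """Greedy modularity optimization (local moves + aggregation to a fixed
    point), deterministic given ``params.seed``.

    The returned score is recomputed independently via :func:`modularity`
    and never falls below the all-singletons start (only strictly improving
    moves are accepted).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.size(weight="weight" if params.weighted else None) <= 0:
        raise ValueError("graph has zero total weight")
    work = graph if params.weighted else _unit_weights(graph)
    nodes = sorted(work.nodes, key=str)
    best_assignment = None
    best_q = -np.inf
    for r in range(params.restarts):
        rng = np.random.default_rng([params.seed, r])
        init = None
        if r > 0:  # diversify the greedy search with random coarse starts
            k_groups = int(rng.integers(2, max(2, min(len(nodes), 5)) + 1))
            init = {u: int(rng.integers(k_groups)) for u in nodes}
        assignment = _louvain_once(work, params.resolution, rng, True,
                                   init=init)
        q = modularity(work, assignment, params.resolution)
        if q > best_q + 1e-12:
            best_q, best_assignment = q, assignment
    canonical = _canonicalize(best_assignment)
    return Partition(
        assignment=canonical,
        n_communities=len(set(canonical.values())),
        modularity=float(best_q),
    )


def _unit_weights(graph: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    out.add_edges_from(((u, v, {"weight": 1.0}) for u, v in graph.edges()))
    return out


def _set_partitions(n: int) -> Iterator[np.ndarray]:
    """All restricted-growth strings of length n, in lexicographic order."""
    a = np.zeros(n, dtype=int)
    b = np.ones(n, dtype=int)  # b[j] = 1 + max(a[:j]); b[0] unused
    b[0] = 0
    while True:
        yield a.copy()
        j = n - 1
        while j > 0 and a[j] == b[j]:
            j -= 1
        if j == 0:
            return
        a[j] += 1
        for i in range(j + 1, n):
            a[i] = 0
            b[i] = max(b[i - 1], a[i - 1] + 1)


def exhaustive_best_partition(
    graph: nx.Graph, resolution: float = 1.0
) -> Partition:
    """Globally optimal modularity partition by full enumeration.

    Enumerates all Bell(n) set partitions, so refuses graphs with more than
    ten nodes.  Ties are broken by the lexicographically smallest restricted
    growth string over ID-sorted nodes (first optimum found is kept).
    """
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    if n > _EXHAUSTIVE_MAX_NODES:
        raise ValueError(
            f"exhaustive search limited to {_EXHAUSTIVE_MAX_NODES} nodes, got {n}"
        )
    m = graph.size(weight="weight")
    if m <= 0:
        raise ValueError("graph has zero total weight")
    idx = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        i, j = idx[u], idx[v]
        A[i, j] += w
        if i != j:
            A[j, i] += w
    k = A.sum(axis=1) + np.diag(A)  # self-loops count twice in degree
    B = A - resolution * np.outer(k, k) / (2.0 * m)
    best_q = -np.inf
    best = None
    for rgs in _set_partitions(n):
        q = 0.0
        for label in range(rgs.max() + 1):
            members = np.flatnonzero(rgs == label)
            q += B[np.ix_(members, members)].sum()
        q /= 2.0 * m
        if q > best_q + 1e-12:
            best_q, best = q, rgs
    assignment = _canonicalize({nodes[i]: int(best[i]) for i in range(n)})
    return Partition(
        assignment=assignment,
        n_communities=len(set(assignment.values())),
        modularity=float(best_q),
    )


def detect_communities(
    network: TransportNetwork, params: DetectionParams = DetectionParams()
) -> Partition:
    """Symmetrize the directed transport network and run Louvain."""
    return louvain(symmetrize(network, params.symmetrization), params)
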