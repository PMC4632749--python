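"""Graph-theory properties of the correlation networks.

All metrics treat the network as a simple, undirected, unweighted graph (the
correlation strength is carried as an edge attribute but never used as a
weight). Three community schemes are characterized by Newman-Girvan
modularity Q:

* ``biochemical`` — the fixed partition by biochemical class annotation;
* ``edge_betweenness`` — divisive Girvan-Newman: repeatedly remove the edge
  of maximum shortest-path betweenness (recomputed each step, ties broken by
  lexicographic node pair) and return the component partition maximizing Q;
* ``walk_trap`` — agglomerative Pons-Latapy clustering from t-step random-walk
  distances (t = 4 by default), returning the merge level maximizing Q.

Q = sum over communities c of (e_cc - a_c^2), where e_cc is the fraction of
edges inside c and a_c the fraction of edge endpoints in c; Q of the single
all-node community is exactly 0.

Diameter follows the max-finite-geodesic convention: on a disconnected graph
it is the largest shortest-path length within any component, so fragmented
correlation networks still get a defined value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io import network_to_graph, sorted_pair

Partition = list[set]


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else network_to_graph(net)


def degree(net) -> dict[str, int]:
    """Incident edge count per node."""
    graph = _as_graph(net)
    return {node: int(d) for node, d in graph.degree()}


def diameter(net) -> int | None:
    """Maximum finite shortest-path length; None for an edgeless graph."""
    graph = _as_graph(net)
    if graph.number_of_edges() == 0:
        return None
    best = 0
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        sub = graph.subgraph(component)
        best = max(best, nx.diameter(sub))
    return int(best)


def transitivity(net) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples."""
    graph = _as_graph(net)
    return float(nx.transitivity(graph))


def modularity(net, partition: Iterable[Iterable[str]]) -> float:
    """Newman-Girvan Q of a node partition on the (unweighted) graph."""
    graph = _as_graph(net)
    parts = [set(p) for p in partition]
    covered: set = set()
    for part in parts:
        if covered & part:
            raise ValueError("partition parts are not disjoint")
        covered |= part
    missing = set(graph.nodes) - covered
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for part in parts:
        internal = sum(1 for a, b in graph.edges(part) if a in part and b in part)
        endpoints = sum(graph.degree(node) for node in part)
        q += internal / m - (endpoints / (2.0 * m)) ** 2
    return float(q)


def biochemical_partition(net, annotation: Mapping[str, str]) -> Partition:
    """Fixed partition of the network's nodes by biochemical class."""
    graph = _as_graph(net)
    groups: dict[str, set] = {}
    for node in graph.nodes:
        if node not in annotation:
            raise ValueError(f"node {node!r} has no biochemical class")
        groups.setdefault(annotation[node], set()).add(node)
    return [groups[c] for c in sorted(groups)]


def _component_partition(graph: nx.Graph) -> Partition:
    return [set(c) for c in nx.connected_components(graph)]


def communities_edge_betweenness(net) -> tuple[Partition, float]:
    """Girvan-Newman divisive clustering, returning the max-Q partition.

    Edge betweenness is recomputed after every removal; among equally central
    edges the lexicographically smallest sorted node pair is removed, so the
    trajectory — and hence the returned partition — is reproducible. Q is
    always evaluated against the original graph. Ties on Q favor the earliest
    (coarsest) partition.
    """
    graph = _as_graph(net)
    if graph.number_of_edges() == 0:
        return _component_partition(graph), 0.0
    work = graph.copy()
    best_partition = _component_partition(work)
    best_q = modularity(graph, best_partition)
    while work.number_of_edges() > 0:
        centrality = nx.edge_betweenness_centrality(work)
        top = max(centrality.values())
        candidates = [e for e, c in centrality.items() if c >= top - 1e-12]
        edge = min(sorted_pair(*e) for e in candidates)
        work.remove_edge(*edge)
        part = _component_partition(work)
        q = modularity(graph, part)
        if q > best_q + 1e-12:
            best_q, best_partition = q, part
    return best_partition, float(best_q)


def _walk_distance_sq(p_c1: np.ndarray, p_c2: np.ndarray, deg: np.ndarray) -> float:
    return float(np.sum((p_c1 - p_c2) ** 2 / deg))


def communities_walktrap(net, t: int = 4) -> tuple[Partition, float]:
    """Pons-Latapy walk-trap clustering, returning the max-Q merge level.

    Within each connected component: start from singleton communities, and at
    every step merge the adjacent pair minimizing the Ward-style variation

        delta sigma = (1/n) |C1||C2| / (|C1| + |C2|) * r^2(C1, C2),

    where r is the Euclidean distance between the communities' mean t-step
    transition-probability profiles, degree-weighted. Q (against the whole
    graph) is tracked along the merge sequence of each component and the best
    level kept; components optimize independently because Q is additive over
    them. Ties are broken by lexicographic community labels.
    """
    graph = _as_graph(net)
    m = graph.number_of_edges()
    final: Partition = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1 or m == 0:
            final.append(set(nodes))
            continue
        sub = graph.subgraph(nodes)
        index = {node: i for i, node in enumerate(nodes)}
        n = len(nodes)
        A = nx.to_numpy_array(sub, nodelist=nodes)
        deg = A.sum(axis=1)
        P = A / deg[:, None]
        Pt = np.linalg.matrix_power(P, t)

        communities: list[set] = [{node} for node in nodes]
        profiles: list[np.ndarray] = [Pt[i] for i in range(n)]
        adjacency: list[set] = [
            {index[nb] for nb in sub.neighbors(node)} for node in nodes
        ]
        levels: list[Partition] = [[set(c) for c in communities]]
        active = set(range(n))
        while len(active) > 1:
            best = None
            for i in sorted(active):
                for j in sorted(adjacency[i]):
                    if j <= i or j not in active:
                        continue
                    si, sj = len(communities[i]), len(communities[j])
                    dsq = _walk_distance_sq(profiles[i], profiles[j], deg)
                    dsigma = dsq * si * sj / (si + sj) / n
                    key = (dsigma, min(communities[i] | communities[j]))
                    if best is None or key < best[0]:
                        best = (key, i, j)
            if best is None:  # no adjacent pairs left (cannot happen: connected)
                break
            _, i, j = best
            si, sj = len(communities[i]), len(communities[j])
            profiles[i] = (si * profiles[i] + sj * profiles[j]) / (si + sj)
            communities[i] |= communities[j]
            adjacency[i] = (adjacency[i] | adjacency[j]) - {i, j}
            for k in adjacency[j]:
                adjacency[k].discard(j)
                if k != i:
                    adjacency[k].add(i)
                    adjacency[i].add(k)
            active.discard(j)
            levels.append([set(communities[k]) for k in sorted(active)])

        def contribution(parts: Partition) -> float:
            q = 0.0
            for part in parts:
                internal = sum(
                    1 for a, b in graph.edges(part) if a in part and b in part
                )
                endpoints = sum(graph.degree(node) for node in part)
                q += internal / m - (endpoints / (2.0 * m)) ** 2
            return q

        best_level = max(range(len(levels)),
                         key=lambda idx: (contribution(levels[idx]), idx))
        final.extend(levels[best_level])
    return final, modularity(graph, final)


@dataclass(frozen=True)
class GraphStats:
    """One variety's row of the network-property report."""

    variety: str
    n_nodes: int
    n_edges: int
    n_common_edges: int | None
    percent_common: float | None
    diameter: int | None
    transitivity: float
    communities: dict  # scheme -> {"n_communities": int, "modularity": float}

    def to_dict(self) -> dict:
        return {
            "variety": self.variety,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_common_edges": self.n_common_edges,
            "percent_common": self.percent_common,
            "diameter": self.diameter,
            "transitivity": round(self.transitivity, 4),
            "communities": {
                scheme: {
                    "n_communities": entry["n_communities"],
                    "modularity": round(entry["modularity"], 4),
                }
                for scheme, entry in self.communities.items()
            },
        }


def graph_stats(
    net,
    annotation: Mapping[str, str],
    comparison=None,
    walktrap_t: int = 4,
) -> GraphStats:
    """Assemble every property column for one variety's network."""
    graph = network_to_graph(net)
    n_common = percent = None
    if comparison is not None:
        n_common = len(comparison.common)
        percent = round(comparison.percent_common[net.variety])
    bio = biochemical_partition(graph, {**annotation, **dict(net.nodes)})
    gn_part, gn_q = communities_edge_betweenness(graph)
    wt_part, wt_q = communities_walktrap(graph, t=walktrap_t)
    return GraphStats(
        variety=net.variety,
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_common_edges=n_common,
        percent_common=percent,
        diameter=diameter(graph),
        transitivity=transitivity(graph),
        communities={
            "biochemical": {
                "n_communities": len(bio),
                "modularity": modularity(graph, bio),
            },
            "walk_trap": {
                "n_communities": len(wt_part),
                "modularity": wt_q,
            },
            "edge_betweenness": {
                "n_communities": len(gn_part),
                "modularity": gn_q,
            },
        },
    )
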