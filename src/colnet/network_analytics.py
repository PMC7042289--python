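"""Case-study analytics for collection networks.

Connected components, density (whole graph or giant component), average
degree, betweenness centrality, Louvain community detection, team-size
statistics and the island-filtering routine used to summarize a coworking
network for display.

All functions accept either a bare :class:`networkx.Graph` or one of the
package's network objects (anything with a ``.graph`` attribute).  Bipartite
graphs are recognized by the ``part`` node attribute that the SCN sets.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import networkx as nx

from colnet.cwn_model import CollectorCoworkingNetwork, Team


def _as_graph(obj) -> nx.Graph:
    return obj.graph if hasattr(obj, "graph") and isinstance(obj.graph, nx.Graph) else obj


def _is_bipartite_scn(g: nx.Graph) -> bool:
    return any(d.get("part") in ("collector", "taxon") for _, d in g.nodes(data=True))


@dataclass
class ComponentPartition:
    """Connected components ordered by decreasing size.

    Ties broken by lexicographically smallest member, so component labels
    c_1, c_2, ... are deterministic.
    """

    components: list[frozenset]
    part_counts: Optional[list[dict[str, int]]] = None  # per-component, bipartite only

    @property
    def giant(self) -> frozenset:
        return self.components[0]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def giant_share(self) -> float:
        return len(self.giant) / sum(self.sizes())


@dataclass
class CommunityPartition:
    """Node → community assignment with the partition's modularity."""

    assignment: dict
    modularity: float
    seed: int
    resolution: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[set]:
        groups: dict[int, set] = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, set()).add(node)
        return [groups[c] for c in sorted(groups)]


def connected_components(graph) -> ComponentPartition:
    """Standard undirected connectivity with deterministic ordering."""
    g = _as_graph(graph)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    part_counts = None
    if _is_bipartite_scn(g):
        part_counts = [
            dict(Counter(g.nodes[n].get("part", "?") for n in c)) for c in comps
        ]
    return ComponentPartition(comps, part_counts)


def density(graph, scope: str = "whole") -> float:
    """Network density.

    Bipartite (SCN): ``|E| / (n * m)`` with n collectors and m taxa.
    Unipartite: ``2|E| / (n(n-1))``.  With ``scope="giant_component"`` the
    density of the subgraph induced by the largest component is returned —
    on sparse collection networks this is typically much higher than the
    whole-graph value because isolated and peripheral nodes are excluded.
    """
    g = _as_graph(graph)
    if scope not in ("whole", "giant_component"):
        raise ValueError(f"unknown scope {scope!r}")
    if g.number_of_nodes() == 0:
        raise ValueError("density undefined for an empty graph")
    if scope == "giant_component":
        g = g.subgraph(connected_components(g).giant)
    if _is_bipartite_scn(g):
        n = sum(1 for _, d in g.nodes(data=True) if d.get("part") == "collector")
        m = sum(1 for _, d in g.nodes(data=True) if d.get("part") == "taxon")
        if n == 0 or m == 0:
            raise ValueError("bipartite density needs both parts nonempty")
        return g.number_of_edges() / (n * m)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("unipartite density undefined for a single-node graph")
    return 2 * g.number_of_edges() / (n * (n - 1))


def average_degree(graph) -> float:
    """Mean degree 2|E|/|V| (0 for an edgeless graph)."""
    g = _as_graph(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("average degree undefined for an empty graph")
    return 2 * g.number_of_edges() / n


def average_degree_by_part(graph) -> dict[str, float]:
    """Per-part mean degree for a bipartite SCN graph."""
    g = _as_graph(graph)
    sums: dict[str, list[int]] = {}
    for node, d in g.nodes(data=True):
        part = d.get("part", "?")
        sums.setdefault(part, [0, 0])
        sums[part][0] += g.degree(node)
        sums[part][1] += 1
    return {part: s / c for part, (s, c) in sums.items()}


def betweenness(graph, normalized: bool = True) -> dict:
    """Betweenness centrality over unweighted shortest paths.

    ``c_B(v) = sum_{s,t} sigma(s,t|v) / sigma(s,t)`` with endpoints excluded
    and disconnected pairs contributing zero; normalized scores divide by
    ``(n-1)(n-2)/2``.  Edge weights are deliberately ignored — tie strength
    is a count, not a distance.
    """
    g = _as_graph(graph)
    return nx.betweenness_centrality(g, normalized=normalized, weight=None)


def detect_communities(graph, seed: int = 0, resolution: float = 1.0) -> CommunityPartition:
    """Louvain modularity maximization (Newman modularity, weighted).

    Reproducible for a fixed seed.  Community ids are assigned in order of
    each community's lexicographically smallest member so labels are stable.
    """
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        return CommunityPartition({}, 0.0, seed, resolution)
    comms = nx.community.louvain_communities(
        g, weight="weight", seed=seed, resolution=resolution
    )
    comms = sorted(comms, key=lambda c: min(str(n) for n in c))
    assignment = {node: cid for cid, comm in enumerate(comms) for node in comm}
    mod = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    return CommunityPartition(assignment, mod, seed, resolution)


@dataclass
class TeamSizeStats:
    histogram: dict[int, int]
    mean: float
    n_teams: int


def team_size_stats(teams: Sequence[Team]) -> TeamSizeStats:
    """Exact team-size histogram and mean over a team sequence."""
    if not teams:
        raise ValueError("team_size_stats needs a nonempty team sequence")
    sizes = [t.size for t in teams]
    hist = dict(sorted(Counter(sizes).items()))
    return TeamSizeStats(hist, sum(sizes) / len(sizes), len(sizes))


def island_filter(
    cwn,
    min_edge_weight: float,
    min_island_score: float,
    node_weight: Callable[[str], float],
) -> tuple[nx.Graph, list[tuple[frozenset, float]]]:
    """Summarize a coworking network by dropping weak edges and light islands.

    First removes edges with weight below ``min_edge_weight``; the remaining
    components are *islands*.  Each island is scored as the sum of
    ``node_weight`` over its members (by convention the collector's total
    record count), and islands scoring below ``min_island_score`` are dropped.

    Returns the filtered graph and the per-island scores of the survivors,
    ordered like :func:`connected_components`.
    """
    g = _as_graph(cwn).copy()
    weak = [(u, v) for u, v, d in g.edges(data=True) if d.get("weight", 1) < min_edge_weight]
    g.remove_edges_from(weak)
    islands = connected_components(g).components
    kept: list[tuple[frozenset, float]] = []
    for island in islands:
        score = sum(node_weight(n) for n in island)
        if score >= min_island_score:
            kept.append((island, score))
        else:
            g.remove_nodes_from(island)
    return g, kept
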