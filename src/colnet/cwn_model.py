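"""The collector coworking network: weighted co-collecting ties.

Each occurrence record is authored by a *team* — the distinct list of
collectors on that record.  Every record whose team has at least two members
is a distinct collaboration act; records with a single collector are
*non-collaborative* and create nodes but never edges.

Two weighting schemes for the tie between collectors *i* and *j*:

* ``full_count`` — the number of records in which both appear;
* ``hyperbolic`` — each shared record of team size ``n_k`` contributes
  ``1 / (n_k - 1)``, so a two-person record contributes the maximum of 1 and
  large teams are discounted:

      w_ij = sum_k  delta_i(k) * delta_j(k) / (n_k - 1)

  The rule is undefined for one-person teams (singularity at ``n_k = 1``),
  which is consistent with excluding them.  A team of size n >= 2 spreads a
  total weight of exactly n/2 over its n(n-1)/2 pairs.

The adjacency matrix is symmetric with a zero diagonal: records list each
collector once, so no self-loops can form.  Hyperbolic weights are
accumulated as exact rationals and stored as floats on the graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from colnet.errors import ConfigurationError
from colnet.occurrence_io import OccurrenceRecord

WEIGHTING_SCHEMES = ("full_count", "hyperbolic")


@dataclass(frozen=True)
class Team:
    """The distinct collectors authoring one record."""

    record_id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"team for record {self.record_id} has duplicate members")
        if not self.members:
            raise ValueError(f"team for record {self.record_id} is empty")

    @property
    def size(self) -> int:
        return len(self.members)


class CollectorCoworkingNetwork:
    """Unipartite weighted graph over collectors.

    Includes every collector seen in the input — also those with no
    collaborations, which remain isolated nodes (degree 0) and are the
    network's *individualist* collectors.
    """

    def __init__(self, graph: nx.Graph, weighting: str):
        self.graph = graph
        self.weighting = weighting

    @property
    def collectors(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_collectors(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        if u == v:
            return 0.0  # zero diagonal by construction
        if self.graph.has_edge(u, v):
            return self.graph[u][v]["weight"]
        return 0.0

    def total_edge_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def extract_teams(
    records: Iterable[OccurrenceRecord],
) -> tuple[list[Team], list[str]]:
    """One team per record with at least one collector id.

    Returns ``(teams, skipped_record_ids)``; records with no resolved
    collectors cannot form a team and are reported, not silently dropped.
    """
    teams: list[Team] = []
    skipped: list[str] = []
    for rec in records:
        if not rec.collector_ids:
            skipped.append(rec.record_id)
            continue
        # ids are deduplicated upstream by resolve(); guard anyway
        members = tuple(dict.fromkeys(rec.collector_ids))
        teams.append(Team(rec.record_id, members))
    return teams, skipped


def pair_weights(teams: Sequence[Team], scheme: str) -> dict[tuple[str, str], Fraction]:
    """Accumulate tie weights as exact rationals, keyed by sorted pair."""
    if scheme not in WEIGHTING_SCHEMES:
        raise ConfigurationError(f"unknown weighting scheme {scheme!r}; use one of {WEIGHTING_SCHEMES}")
    weights: dict[tuple[str, str], Fraction] = {}
    for team in teams:
        if team.size < 2:
            continue  # non-collaborative record: no ties
        contrib = Fraction(1) if scheme == "full_count" else Fraction(1, team.size - 1)
        for u, v in combinations(team.members, 2):
            key = (u, v) if u <= v else (v, u)
            weights[key] = weights.get(key, Fraction(0)) + contrib
    return weights


def build_cwn(teams: Sequence[Team], scheme: str = "hyperbolic") -> CollectorCoworkingNetwork:
    """Build the coworking network from record teams.

    All collectors become nodes; edges carry the chosen weighting.  One-person
    teams contribute nodes only.
    """
    weights = pair_weights(teams, scheme)  # validates scheme
    g = nx.Graph()
    for team in teams:
        g.add_nodes_from(team.members)
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=float(w))
    return CollectorCoworkingNetwork(g, scheme)


def individualists(cwn: CollectorCoworkingNetwork) -> set[str]:
    """Collectors with degree 0 — those who never co-authored a record."""
    return {n for n in cwn.graph.nodes if cwn.graph.degree(n) == 0}
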