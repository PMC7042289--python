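"""The species-collector network: a weighted bipartite interest graph.

A species-collector network (SCN) links the collectors of a dataset to the
taxa they recorded.  Formally it is a bipartite graph ``(S_col, S_sp, E)``
with collector nodes ``u_1..u_n``, taxon nodes ``v_1..v_m`` and undirected
weighted edges only between the two sets.  The weight ``a_ij`` of edge
``(u_i, v_j)`` counts the records in which collector ``u_i`` recorded taxon
``v_j``; the rectangular matrix ``A`` of these weights is the network's
biadjacency matrix (``a_ij != 0`` iff the edge exists).

Derived per-node vectors:

* a collector's **species bag** ``sigma_ui = [a_i1, ..., a_im]`` — row *i* of
  ``A``, the collector's taxonomic signature.  Its sum equals the number of
  records authored by that collector.
* a taxon's **quorum** ``iota_vj = [a_1j, ..., a_nj]`` — column *j* of ``A``,
  the taxon's collector signature.  Its sum counts (record, collector)
  incidences of the taxon, which equals the taxon's record count only when
  every record has a single collector.

All taxon nodes share one taxonomic rank, the network's *resolution*;
aggregating to a higher rank sums quorum vectors within each group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from colnet.errors import ColnetError, RecordRejectedError
from colnet.occurrence_io import OccurrenceRecord


@dataclass
class SpeciesBag:
    """Row of the biadjacency matrix for one collector."""

    collector: str
    taxa: tuple[str, ...]
    counts: np.ndarray  # aligned to taxa

    def total(self) -> int:
        return int(self.counts.sum())

    def nonzero(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(self.taxa, self.counts) if c}


@dataclass
class Quorum:
    """Column of the biadjacency matrix for one taxon."""

    taxon: str
    collectors: tuple[str, ...]
    counts: np.ndarray  # aligned to collectors

    def total(self) -> int:
        return int(self.counts.sum())

    def nonzero(self) -> dict[str, int]:
        return {c: int(v) for c, v in zip(self.collectors, self.counts) if v}


class SpeciesCollectorNetwork:
    """Bipartite weighted graph over collectors and taxa.

    Node order (and hence biadjacency row/column order) is fixed by first
    appearance in the source records, making exports deterministic.
    """

    COLLECTOR_PART = 0
    TAXON_PART = 1

    def __init__(self, collectors: Sequence[str], taxa: Sequence[str], resolution: str = "species"):
        self.collectors: list[str] = list(collectors)
        self.taxa: list[str] = list(taxa)
        self.resolution = resolution
        if set(self.collectors) & set(self.taxa):
            raise ColnetError("collector and taxon node sets must be disjoint")
        self._col_index = {c: i for i, c in enumerate(self.collectors)}
        self._taxon_index = {t: j for j, t in enumerate(self.taxa)}
        g = nx.Graph()
        g.add_nodes_from(self.collectors, bipartite=self.COLLECTOR_PART, part="collector")
        g.add_nodes_from(self.taxa, bipartite=self.TAXON_PART, part="taxon")
        self.graph = g

    # -- construction ----------------------------------------------------
    def _add(self, collector: str, taxon: str, weight: int = 1) -> None:
        if self.graph.has_edge(collector, taxon):
            self.graph[collector][taxon]["weight"] += weight
        else:
            self.graph.add_edge(collector, taxon, weight=weight)

    # -- views ------------------------------------------------------------
    @property
    def n_collectors(self) -> int:
        return len(self.collectors)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, collector: str, taxon: str) -> int:
        if self.graph.has_edge(collector, taxon):
            return self.graph[collector][taxon]["weight"]
        return 0

    def biadjacency(self) -> sp.csr_matrix:
        """The n×m biadjacency matrix A in first-appearance node order."""
        rows, cols, vals = [], [], []
        for i, c in enumerate(self.collectors):
            for taxon in self.graph.neighbors(c):
                rows.append(i)
                cols.append(self._taxon_index[taxon])
                vals.append(self.graph[c][taxon]["weight"])
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_collectors, self.n_taxa), dtype=np.int64
        )

    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def copy(self) -> "SpeciesCollectorNetwork":
        out = SpeciesCollectorNetwork(self.collectors, self.taxa, self.resolution)
        out.graph = self.graph.copy()
        return out


def build_scn(records: Iterable[OccurrenceRecord], resolution: str = "species") -> SpeciesCollectorNetwork:
    """Build an SCN from resolved occurrence records.

    For each record with *n* collectors, *n* collector–taxon links are
    created or strengthened, so ``a_ij`` ends up counting the records in
    which collector ``u_i`` and taxon ``v_j`` co-occur.

    Raises
    ------
    RecordRejectedError
        If any record lacks collector ids or a taxon name: such records
        violate the model precondition and must be filtered out upstream
        (see :meth:`RecordFilterConfig.for_scn`).
    """
    records = list(records)
    bad = [r.record_id for r in records if not r.collector_ids or not r.taxon_name]
    if bad:
        raise RecordRejectedError(
            f"{len(bad)} record(s) lack collectors or taxon and cannot enter the SCN", bad
        )
    collectors: list[str] = []
    taxa: list[str] = []
    seen_c: set[str] = set()
    seen_t: set[str] = set()
    for rec in records:
        for cid in rec.collector_ids:
            if cid not in seen_c:
                seen_c.add(cid)
                collectors.append(cid)
        if rec.taxon_name not in seen_t:
            seen_t.add(rec.taxon_name)
            taxa.append(rec.taxon_name)
    scn = SpeciesCollectorNetwork(collectors, taxa, resolution)
    for rec in records:
        for cid in rec.collector_ids:
            scn._add(cid, rec.taxon_name)
    return scn


def species_bag(scn: SpeciesCollectorNetwork, collector: str) -> SpeciesBag:
    """Return collector ``u_i``'s species bag (row *i* of the biadjacency)."""
    if collector not in scn._col_index:
        raise KeyError(f"unknown collector {collector!r}")
    counts = np.zeros(scn.n_taxa, dtype=np.int64)
    for taxon in scn.graph.neighbors(collector):
        counts[scn._taxon_index[taxon]] = scn.graph[collector][taxon]["weight"]
    return SpeciesBag(collector, tuple(scn.taxa), counts)


def quorum(scn: SpeciesCollectorNetwork, taxon: str) -> Quorum:
    """Return taxon ``v_j``'s quorum (column *j* of the biadjacency)."""
    if taxon not in scn._taxon_index:
        raise KeyError(f"unknown taxon {taxon!r}")
    counts = np.zeros(scn.n_collectors, dtype=np.int64)
    for collector in scn.graph.neighbors(taxon):
        counts[scn._col_index[collector]] = scn.graph[collector][taxon]["weight"]
    return Quorum(taxon, tuple(scn.collectors), counts)


def aggregate(
    scn: SpeciesCollectorNetwork, taxonomy: Mapping[str, str], rank: str
) -> SpeciesCollectorNetwork:
    """Aggregate taxon nodes to a higher rank.

    ``taxonomy`` maps every current taxon node to its ancestor at ``rank``
    (e.g. species → family).  The aggregated network keeps the collector set
    unchanged; the new column for group *g* is the element-wise sum of the
    quorum vectors of all taxa mapped to *g*, so total edge weight and every
    collector's row sum are conserved.

    Raises
    ------
    ColnetError
        If any taxon node is missing from the taxonomy (lists the orphans).
    """
    orphans = [t for t in scn.taxa if t not in taxonomy]
    if orphans:
        raise ColnetError(f"taxonomy does not cover {len(orphans)} taxa: {orphans[:10]}")
    groups: list[str] = []
    seen: set[str] = set()
    for t in scn.taxa:  # group order = first appearance of a member taxon
        g = taxonomy[t]
        if g not in seen:
            seen.add(g)
            groups.append(g)
    out = SpeciesCollectorNetwork(scn.collectors, groups, resolution=rank)
    for collector, taxon, data in scn.graph.edges(data=True):
        if scn.graph.nodes[collector]["part"] != "collector":
            collector, taxon = taxon, collector
        out._add(collector, taxonomy[taxon], data["weight"])
    return out


def filter_scn_edges(
    scn: SpeciesCollectorNetwork, min_weight: int, drop_isolates: bool = False
) -> SpeciesCollectorNetwork:
    """Remove edges with weight below ``min_weight``.

    With ``drop_isolates`` the nodes left without any edge are removed too
    (useful before plotting, as in the case-study figures).
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    out = scn.copy()
    weak = [
        (u, v) for u, v, d in out.graph.edges(data=True) if d["weight"] < min_weight
    ]
    out.graph.remove_edges_from(weak)
    if drop_isolates:
        isolated = list(nx.isolates(out.graph))
        out.graph.remove_nodes_from(isolated)
        dead = set(isolated)
        out.collectors = [c for c in out.collectors if c not in dead]
        out.taxa = [t for t in out.taxa if t not in dead]
        out._col_index = {c: i for i, c in enumerate(out.collectors)}
        out._taxon_index = {t: j for j, t in enumerate(out.taxa)}
    return out
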