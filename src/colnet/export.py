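"""Graph and table writers with deterministic, diffable output.

GraphML carries node attributes (part, record counts, community) and exact
edge weights; edge lists are three-column tab-separated with node ids sorted
so repeated runs produce identical bytes.  A GraphML round trip preserves
weights exactly (floats are serialized with full precision).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx

from colnet.cwn_model import CollectorCoworkingNetwork
from colnet.scn_model import SpeciesCollectorNetwork


def _graph_of(obj) -> nx.Graph:
    return obj.graph if hasattr(obj, "graph") and isinstance(obj.graph, nx.Graph) else obj


def write_graphml(network, path) -> None:
    g = _graph_of(network)
    nx.write_graphml(g, path, named_key_ids=True)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})


def write_edge_list(network, path, delimiter: str = "\t") -> int:
    """Write (node, node, weight) rows sorted by node ids; returns row count."""
    g = _graph_of(network)
    rows = sorted((min(u, v), max(u, v), d.get("weight", 1)) for u, v, d in g.edges(data=True))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["source", "target", "weight"])
        w.writerows(rows)
    return len(rows)


def write_node_table(
    network,
    path,
    record_counts: Optional[Mapping[str, int]] = None,
    communities: Optional[Mapping[str, int]] = None,
    centrality: Optional[Mapping[str, float]] = None,
    delimiter: str = "\t",
) -> None:
    """Node metadata table: part, degree, and any supplied per-node metrics."""
    g = _graph_of(network)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        header = ["node", "part", "degree"]
        if record_counts is not None:
            header.append("records")
        if communities is not None:
            header.append("community")
        if centrality is not None:
            header.append("betweenness")
        w.writerow(header)
        for node in sorted(g.nodes, key=str):
            row = [node, g.nodes[node].get("part", "collector"), g.degree(node)]
            if record_counts is not None:
                row.append(record_counts.get(node, 0))
            if communities is not None:
                row.append(communities.get(node, ""))
            if centrality is not None:
                row.append(repr(centrality.get(node, 0.0)))
            w.writerow(row)


def write_vector_table(vectors, path, delimiter: str = "\t") -> None:
    """Write species bags or quorums as labeled rows (owner, label, count)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["owner", "item", "count"])
        for vec in vectors:
            owner = getattr(vec, "collector", None) or getattr(vec, "taxon")
            for item, count in sorted(vec.nonzero().items()):
                w.writerow([owner, item, count])
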