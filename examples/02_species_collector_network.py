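"""Build a species-collector network and read bags, quorums and aggregates.

Eight records over three collectors produce a small bipartite interest graph;
edge weight counts how often each collector-species association appears.
"""

from colnet import aggregate, build_scn, filter_scn_edges, quorum, species_bag
from colnet.occurrence_io import OccurrenceRecord


def rec(rid, collectors, species):
    return OccurrenceRecord(rid, "; ".join(collectors), species, collector_ids=tuple(collectors))


records = [
    rec("r0", ["irwin,hs", "ratter,ja"], "Myrtia alba"),
    rec("r1", ["irwin,hs"], "Myrtia alba"),
    rec("r2", ["irwin,hs"], "Myrtia nitida"),
    rec("r3", ["irwin,hs"], "Fabia minor"),
    rec("r4", ["ratter,ja"], "Fabia minor"),
    rec("r5", ["proenca,ceb"], "Myrtia alba"),
    rec("r6", ["proenca,ceb"], "Fabia robusta"),
    rec("r7", ["proenca,ceb", "irwin,hs"], "Fabia robusta"),
]
scn = build_scn(records)
print(f"SCN: {scn.n_collectors} collectors x {scn.n_taxa} species, {scn.n_edges} edges")

bag = species_bag(scn, "irwin,hs")
print("species bag of irwin,hs:", bag.nonzero(), f"(sum={bag.total()} = his record count)")
print("quorum of Myrtia alba:", quorum(scn, "Myrtia alba").nonzero())

families = {"Myrtia alba": "Myrtaceae", "Myrtia nitida": "Myrtaceae",
            "Fabia minor": "Fabaceae", "Fabia robusta": "Fabaceae"}
fam = aggregate(scn, families, "family")
print("after family aggregation:", {c: species_bag(fam, c).nonzero() for c in fam.collectors})
print("total weight conserved:", fam.total_weight() == scn.total_weight())

strong = filter_scn_edges(fam, min_weight=3, drop_isolates=True)
print("ties seen >= 3 times:", list(strong.graph.edges(data="weight")))
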