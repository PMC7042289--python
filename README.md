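# colnet — network models for biological collections

Herbaria and other biological collections are assembled by people: a few
prolific collectors with strong taxonomic preferences can dominate a
collection's composition, and collecting itself is social — specimens are
recorded by field teams. `colnet` treats a species-occurrence table (rows in
Darwin Core vocabulary: `recordedBy`, `scientificName`, `taxonRank`, ...) as
the trace of that social process and builds two network views of it, for
biodiversity informaticians and collection curators who want to characterize
collector and taxonomic bias.

## The models

**Species-collector network (SCN).** A bipartite graph
`SCN = (S_col, S_sp, E)` with collector nodes `u_1..u_n`, taxon nodes
`v_1..v_m`, and weighted edges only between the two sets. Each record with
*n* collectors creates (or strengthens) *n* collector–taxon links, so the
biadjacency matrix `A` has `a_ij` = number of records in which collector
`u_i` recorded taxon `v_j`. Row *i* of `A` is collector `u_i`'s *species
bag* `σ_ui = [a_i1, ..., a_im]` (its sum is the collector's record count);
column *j* is taxon `v_j`'s *quorum* `ι_vj = [a_1j, ..., a_nj]`. Species
nodes can be aggregated to a higher taxonomic rank (genus, family) by
summing quorum vectors within each group, which conserves all weights.

**Collector coworking network (CWN).** A unipartite weighted graph over the
same collectors. Each record's *team* (its distinct collector list, size
`n_k`) is a collaboration act when `n_k ≥ 2`. Tie weights are either a full
count of shared records or the hyperbolic rule

```
w_ij = Σ_k  δ_i(k) δ_j(k) / (n_k − 1)
```

which gives a two-person record the maximum contribution of 1 and discounts
large teams (a size-`n` team spreads exactly `n/2` of total weight over its
pairs). One-person records create nodes but no ties; the adjacency matrix is
symmetric with a zero diagonal. Degree-0 nodes are the *individualist*
collectors.

Around the models the package ships the collector-name cleaning pipeline
(atomize → normalize → resolve, producing ids like `proenca,ceb`), the
analytics used to profile such networks (connected components, density on
the whole graph or the giant component, average degree, betweenness
centrality, seeded Louvain community detection, team-size statistics, island
filtering for display), deterministic GraphML/edge-list export, a thin
`colnet` CLI, and a synthetic occurrence-data generator with planted ground
truth (interest communities, individualist fraction, name-variant noise).

## Worked example

```python
from colnet import Team, build_cwn, individualists

teams = [
    Team("r0", ("irwin,hs", "ratter,ja")),
    Team("r1", ("irwin,hs", "ratter,ja")),
    Team("r2", ("proenca,ceb", "faria,jeq", "mendes,vc")),
    Team("r3", ("staggemeier,vg",)),
]
cwn = build_cwn(teams, scheme="hyperbolic")
print({(u, v): w for u, v, w in cwn.graph.edges(data="weight")})
print(individualists(cwn))
```

prints

```
{('irwin,hs', 'ratter,ja'): 2.0, ('proenca,ceb', 'faria,jeq'): 0.5,
 ('proenca,ceb', 'mendes,vc'): 0.5, ('faria,jeq', 'mendes,vc'): 0.5}
{'staggemeier,vg'}
```

— the two shared two-person records each contribute 1 to the
irwin–ratter tie; the trio's three pairs get `1/(3−1) = 0.5` each; the solo
collector becomes an isolated (individualist) node.

The scripts in `examples/` walk each capability: name cleaning, SCN bags /
quorums / aggregation, CWN weighting schemes, the full case-study analytics
pipeline on a 10,000-record synthetic dataset, and the CLI. Running
`examples/04_case_study_pipeline.py` ends with lines like

```
individualists: 39.5% of collectors, mean team size 1.73
Louvain: 83 communities, modularity 0.723, agreement with planted groups 1.00
```

meaning the cleaning + network pipeline recovered the generator's planted
coworking groups perfectly and reproduced its configured collaboration
statistics.

## Command line

```bash
colnet build --config run.yaml   # read → resolve → build SCN/CWN → export + run log
colnet stats out/cwn.graphml     # components, density, degree, betweenness, communities
```

The YAML run config covers column mapping, delimiters, a name map, the
weighting scheme, aggregation rank/taxonomy, and the display-filter
thresholds (minimum tie count, minimum edge weight, minimum island score) —
every threshold applied is echoed in the run log.

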