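# Methods

## Models

The species-collector network (SCN) is a weighted bipartite graph
`(S_col, S_sp, E)`. Building it is a single pass over resolved records: a
record with collectors `{u_a, u_b}` and taxon `v` increments `a_av` and
`a_bv`. The model is temporally and geographically invariant — dates and
coordinates are carried on records but never enter the graph — and assumes
each record's collector list has already been deduplicated and canonicalized
(the resolver guarantees this), otherwise weights would be inflated.

All taxon nodes carry one rank, the network's *resolution*. Aggregation to a
higher rank `T` maps each taxon to its group (user-supplied map or the
table's own `family` column), and sums quorum vectors per group. Two exact
identities follow and are asserted in tests: the total of `A` and each
collector's row sum are invariant under any grouping.

A note on the quorum sum: the sum of a taxon's quorum vector counts
(record, collector) incidences — each multi-collector record contributes
once per collector. It equals the taxon's record count only in a dataset of
single-collector records. The package implements the literal column-sum
semantics and does not reinterpret it as a record count.

The collector coworking network (CWN) is built from per-record teams. Two
identical collector lists on different records are two distinct
collaboration acts. The hyperbolic rule `w_ij = Σ_k δ_i δ_j / (n_k − 1)` has
a singularity at team size 1, so only teams of size ≥ 2 enter the sum;
size-1 teams are retained as isolated nodes because the share of
*individualist* collectors (degree 0) is itself an object of study. Weights
are accumulated in exact rational arithmetic (`fractions.Fraction`) and
stored on the graph as doubles; a size-`n` team contributes exactly
`n(n−1)/2 × 1/(n−1) = n/2` of total weight, which the tests check exactly.
Whether full-count or hyperbolic weighting is appropriate depends on the
question; both are exposed and every output is labelled with the scheme.

## Name cleaning

`recordedBy` strings are split on a configurable ordered delimiter set,
default `;`, `|`, `&`, `" e "`, `" and "`. A bare comma is deliberately
*not* a between-name delimiter: the dominant "Surname, Initials" layout uses
it inside one name, so treating it as a separator would shred most names.
"et al." markers denote unnamed secondary collectors; they are removed,
flagged in the report, and interpreted as the absence of co-collecting ties.

Normalization maps a name to `surname,initials`: lowercase, NFKD-stripped
diacritics, non-alphabetic characters removed from the surname (so
multi-part surnames concatenate), and one initial per given-name chunk, with
an unpunctuated all-caps run of ≤ 4 letters read as packed initials
("Irwin, HS" → `irwin,hs`). When no comma is present the last word is taken
as the surname. Tokens that leave either side empty, have fewer than two
alphabetic characters, are purely numeric, or sit on the stop list
(`s.n.`, `?`, ...) are rejected with a recorded reason rather than becoming
junk nodes. Two known limitations: bare surnames are rejected by default
(incomplete names cannot yield a well-formed id), and distinct people can
collide on one token — resolving either requires an external
variant→canonical name map, which the resolver applies before
deduplication.

## Analytics

Components use standard undirected connectivity with a deterministic order
(size descending, ties by lexicographically smallest member), so labels
`c_1, c_2, ...` are stable. Density is `|E|/(n·m)` for bipartite graphs and
`2|E|/(n(n−1))` otherwise, computable on the whole graph or the subgraph
induced by the giant component; single-node and empty graphs raise rather
than returning a silent 0. Betweenness is the Freeman/Brandes definition on
*unweighted* shortest paths, normalized by `(n−1)(n−2)/2` by default — tie
weights are interaction counts, not distances, so they are ignored for path
length. Community detection is Louvain modularity maximization (Newman
modularity, weights as strengths) via networkx's seeded implementation;
fixed seed gives bit-reproducible partitions, and community ids are
reassigned by each community's smallest member for stable labels. The
island filter drops edges below a weight threshold, recomputes components
("islands"), scores each island by summing a per-node weight — default
convention: the collector's total record count — and drops islands below a
score threshold; all three thresholds are explicit arguments.

## Synthetic data generator

The generator emulates the statistical features of herbarium occurrence
tables that matter to these models:

- **Team sizes** are i.i.d. from a log-decaying distribution over 1..6,
  default `P = (0.55, 0.28, 0.10, 0.04, 0.02, 0.01)` with mean 1.73 —
  single-collector records dominate, as in real collections.
- **Individualists**: a configurable fraction (default 0.395) of collectors
  is never placed in a team of size ≥ 2; every sociable collector is
  guaranteed at least one collaborative record (a size-2 record replaces a
  randomly chosen solo record if the draw left one out), so the realized
  individualist set equals the planted one and recovery can be asserted
  exactly. The replacement pass shifts the realized mean team size by at
  most `n_collectors / n_records`, which the sampling test budgets for.
- **Activity** per collector is heavy-tailed (Zipf-like, exponent 0.8), so
  hub collectors emerge.
- **Interest communities**: collectors are partitioned into groups; each
  group owns a disjoint set of families and each collector a preferred
  family within it. A record's species is drawn from a randomly chosen team
  member's preferred family with probability `species_concentration`
  (default 0.9), else uniformly. Teams of size ≥ 2 draw their members from
  the lead collector's community with probability `team_coherence` (default
  0.95), so coworking groups align with interest communities.
- **Name noise**: per-record delimiter choice among `; `, ` | `, ` & `;
  optional variant spellings (an initial dropped, with the matching
  variant→canonical entry emitted in the ground-truth name map, skipping
  variants that would collide with an existing id); optional "et al."
  truncation that keeps only the first name.

Everything is drawn from one `numpy` generator seeded by the config, so a
fixed config yields a byte-identical table. Ground truth records the true
member ids per record, community and preferred family per collector, the
realized individualist set, the name map and the species→family map.

What passing the recovery tests shows: the cleaning rules invert the
generator's noise model and the network pipeline recovers strong planted
structure. What it does not show: robustness to real-world defects outside
that noise model — swapped name orders, institution names in `recordedBy`,
OCR noise, taxonomic synonymy — which require curated name maps and
taxonomic backbones out of scope here.

Partition agreement (`ground_truth_eval`) is majority-label best-match
accuracy: each detected community maps to its most common planted label and
the score is the fraction of nodes matching their community's label. It is
permutation-invariant and tolerant of over-splitting (Louvain typically
splits a planted group into several dense modules; every fragment still maps
to the right label). Recovery is evaluated on collaborative (degree ≥ 1)
nodes, since isolated individualists carry no community signal.

## Numerical and design choices

- Hyperbolic weights: exact `Fraction` accumulation, float storage;
  full-count weights are integers stored as floats. GraphML serialization
  uses Python's shortest-round-trip float repr, so weights survive a
  write/read cycle bit-exactly.
- Biadjacency rows/columns follow first appearance in the input, making
  matrices and exports deterministic; edge lists are written sorted.
- Dominant-family checks treat a tie as a hit when the planted family is
  among the argmax set.
- Records whose collector list resolves to empty are flagged, never silently
  dropped; model builders raise on them, and the build pipeline filters them
  explicitly.
- The `issue` column is read but no issue value causes a drop by default;
  issue-pattern filtering is available but opt-in, since which quality flags
  warrant exclusion is dataset-specific.
- Problem sizes used by the validation suite — 200 random fixtures of ≤ 50
  records for oracle equivalence, graphs of ≤ 30 nodes for exhaustive
  betweenness, 10,000 records for planted recovery — are the package's
  chosen validation scale: large enough for the asserted properties to be
  non-trivial, small enough to verify exactly.
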