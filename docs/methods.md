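# Methods

## Workflow model

The package models the annotation of a phage proteome as a three-stage
procedure operating on externally computed artifacts: a pairwise sequence
alignment table, per-representative structure models (reduced to their
per-residue pLDDT tracks), and structure-vs-database search tables.  No
stage computes alignments or structures; the package owns the clustering
semantics, the filtering and transfer logic, and all summary statistics.

### Clustering

A similarity graph connects two proteins when some alignment row reaches
the identity threshold (default 0.5) and the coverage rule (default:
both query and target covered to ≥ 0.9; a target-only mode supports local
searches).  Thresholds are inclusive, matching the conventions of the
alignment tools whose output is consumed.  Clusters are carved by greedy
set cover over closed neighbourhoods: repeatedly select the node covering
the most still-uncovered nodes; it becomes a representative and its newly
covered neighbourhood joins its cluster.  Ties are broken by
lexicographically smallest id, which makes the procedure fully
deterministic — a requirement for testing, since the original tools leave
internal order unspecified.  A selected node that was already covered as an
ordinary member moves into the cluster it now represents; this keeps the
result a partition with each representative inside its own cluster.
Cascaded multi-stage clustering, a speed optimisation in the original
tools, is intentionally not reproduced: at the scales this package targets
the single-pass semantics is the definition.

A reassignment pass mirrors the original tools' `--cluster-reassign`:
members lacking a qualifying edge to their representative move to the
lexicographically smallest other representative they touch, or become new
singletons.  The pass is idempotent and preserves the partition property.

### Annotation transfer and rates

Structure hits are filtered at TM-score ≥ 0.5 and coverage ≥ 0.8
(bidirectional by default).  The best hit per query is the highest
TM-score, ties broken by lower E-value, then database precedence
PDB > AFDB_SwissProt > AFDB > other, then target id.  The precedence order
is this package's choice — searches span several databases without a
published combination rule — and prefers experimentally determined
structures over predicted ones.  Each representative's best-hit name is
transferred to every member of its cluster.

Rates follow the two formulas `(n_all − n_unannotated)/n_all` and
`(n_match − n_void)/n_all`.  `n_all` in the structure-based rate is the
full protein set, not just queried representatives: only on a shared
denominator are the two rates comparable.  Void matching is
case-insensitive substring search over a configurable term list
(default: putative, hypothetical, uncharacterized, domain of unknown
function); an absent or empty hit name is void.  Boundary semantics
follow the source phrasing: "set to" thresholds (0.5/0.8/0.9) are
inclusive, "above"/"greater than" thresholds (counter-defense TM 0.6,
pLDDT gate 90, predictor confidence 0.8, interaction screens 0.5/0.7) are
strict, and the High/Low pLDDT split at 70 is inclusive on the High side.

### Consistency statistics

Pfam consistency over a cluster averages the asymmetric pair score
`|pfam(ref) ∩ pfam(other)| / |pfam(ref)|` over ordered pairs of annotated
members; taking both directions makes the cluster score symmetric while
preserving the reference-normalised definition.  Accessions are compared
as sets (duplicates collapsed).  EC consistency applies the same pairwise
scheme per hierarchical level to members carrying exactly one EC code,
disregarding codes whose token at the evaluated level is `-`; with one
code per member a pair scores 1 exactly when the truncated codes match,
which makes the score monotone non-increasing in level on a fixed member
set.  Clusters need at least two eligible members to be scored.

The semantic-consistency check mechanises what was originally a manual
judgement: clusters whose representative's transferred annotation contains
an ambiguous term (hypothetical, membrane, structural, virion, putative)
are removed, then a member counts as consistent when its structure- and
sequence-based annotations are identical after case/whitespace
normalisation or fall in the same group of a user-supplied synonym
configuration.  The ambiguity filter examines the transferred (structural)
annotation because that is the annotation under evaluation.  Externalising
the equivalence classes to a versioned config keeps the judgement
reproducible and auditable.

### Taxonomy

The LCA of a taxid set is the deepest node on every member's root path;
depth is root-path length, with no majority or weighted variants (nothing
in the workflow calls for weighting).  Rank distributions ascend each item
to its ancestor at the requested rank, with items whose node lies above
that rank reported as "unassigned"; Sankey-style flow plots are replaced by
a rank-by-rank top-k count table (default k = 8).

### Interactions

The combined multimer confidence is `0.8·ipTM + 0.2·pTM`.  The screening
literature phrases the same screen both as this weighted score and as a
raw "ipTM + pTM" sum; the weighted reading is the default (it is how the
combined confidence is defined) with `screen_on="raw_sum"` available for
the other reading.  Duplicate (phage, host) pairs collapse to their
maximum score, the usual convention when several models exist per pair.
Heatmap cells divide per-category hit counts by the number of phages in
each phage group, making differently sized groups comparable.

## Synthetic corpus

The generator emulates every input dialect with planted ground truth.
Families are drawn from a geometric size distribution (p = 0.45, capped at
30), giving the many-singletons profile typical of phage protein
clusterings; within-family alignment identities are drawn from
(0.60, 0.95) and between-family rows from (0.05, 0.35), entirely separable
around the 0.5 threshold so the planted partition is the unique clustering
solution — the recovery test is exact, not approximate.  Default planted
fractions are chosen once to mirror the study conditions at desk scale:
66% hypothetical products (sequence rate ≈ 34%), 70% of representatives
with database hits of which 15% are void, mean pLDDT 77 (SD 10), and a
best-hit superkingdom mix dominated by bacteria
(≈ 69.5/15.9/10.2/4.4% for bacteria/eukaryota/viruses/archaea, the
published proportions renormalised to sum to one).  Planted counts use
deterministic rounding — `floor(fraction × n)` items chosen by a seeded
shuffle — so rate recovery is exact, not statistical.

Labels agree within a family with probability π (default 0.9): each member
keeps the family's canonical Pfam set and EC code with probability π, else
receives globally unique deviant labels.  Any pair involving a deviant
scores 0, so a cluster of m annotated members scores
`C(C−1)/(m(m−1))` with `C ~ Binomial(m, π)` and the expected cluster score
is exactly π².  `expected_values` returns this expectation together with a
99% Monte-Carlo interval computed from the realised family sizes.
Expected interaction-screen counts are computed exactly by integrating the
weighted-uniform score distribution, with a binomial standard deviation.

What the generator does **not** emulate: real sequence evolution (residue
strings are random and carry no signal — all pairwise statistics are
planted directly, since no pipeline stage computes alignments), structure
coordinates beyond CA-trace pLDDT stubs, correlated void/hit structure
within families, partial or conflicting taxonomies, and database-version
effects.  Passing tests therefore demonstrate that the implemented
semantics are correct, not that the published corpus-scale percentages are
reproduced; those depend on the 240k-protein corpus and versioned external
databases.

## Problem sizes and determinism

Default synthetic corpora use 40 families (~90 proteins), 200 interaction
pairs, and a four-superkingdom taxonomy with three uniform rank tiers —
large enough to exercise every code path and planted statistic while
keeping the full test suite in seconds.  All randomness flows from a
single integer seed through one RNG (`numpy.random.default_rng`);
regenerating with the same spec yields byte-identical files.  Oracle-based
tests (exhaustive greedy set cover up to 5 nodes, 1,000 random graphs up to
8 nodes, 1,000 random label clusters, LCA vs root-path intersection on
random trees up to 500 nodes) use independently coded brute-force
references.

## Known limitations

* The greedy selection rule's behaviour when a covered node wins (it moves
  into the new cluster it represents) is one of several defensible
  readings of the original tool's semantics; it was chosen for partition
  safety and guaranteed termination, and differs from the original only on
  contrived graphs.
* EC codes with `-` at an inner level but digits below it (e.g. `1.-.3.4`)
  are only disregarded at the `-` level itself, mirroring the stated rule;
  such codes are rare and arguably malformed.
* `read_plddt` takes one value per residue from the CA atom (first atom as
  fallback), the common convention for predicted models; sources that
  stored pLDDT elsewhere would need a custom reader.
* GFF coordinates are ignored entirely; only the id → product mapping is
  consumed.
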