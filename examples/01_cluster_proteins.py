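"""Cluster a handful of proteins from pairwise alignments.

Five proteins: three mutually similar tail proteins, a pair of lysins, and
the similarity thresholds (identity >= 0.5, bidirectional coverage >= 0.9)
decide which pairs count.  Greedy set cover then picks representatives.
"""

from scsh.cluster import (
    build_similarity_graph,
    cluster_size_summary,
    greedy_set_cover_cluster,
    reassign_members,
)
from scsh.types import AlignmentRecord


def aln(q, t, ident, cov=0.95):
    return AlignmentRecord(q, t, ident, cov, cov, 1e-20)


alignments = [
    aln("tailA", "tailB", 0.82),
    aln("tailA", "tailC", 0.74),
    aln("tailB", "tailC", 0.69),
    aln("lysA", "lysB", 0.91),
    aln("tailA", "lysA", 0.22),  # below the identity threshold: no edge
]

graph = build_similarity_graph(alignments, min_identity=0.5, min_coverage=0.9)
clustering = reassign_members(greedy_set_cover_cluster(graph), graph)

print("clusters (representative -> members):")
for rep, members in sorted(clustering.clusters.items()):
    print(f"  {rep}: {sorted(members)}")
print("size distribution:", dict(cluster_size_summary(clustering)))
# Two clusters: the tail-protein trio under 'tailA' and the lysin pair under
# 'lysA'.  The sub-threshold tailA-lysA alignment correctly creates no edge.
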