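"""Summarise the taxonomy of structural homologs by lowest common ancestor.

Each query's database hits are reduced to the deepest taxon shared by all
their lineages; best-hit taxa are summarised as a superkingdom breakdown.
"""

from scsh.taxonomy import lca, per_query_lca, rank_distribution
from scsh.types import AlignmentRecord, TaxonomyTree

tree = TaxonomyTree({
    1: (1, "no rank", "root"),
    2: (1, "superkingdom", "Bacteria"),
    3: (1, "superkingdom", "Eukaryota"),
    4: (2, "genus", "Mycobacterium"),
    5: (4, "species", "M. smegmatis"),
    6: (4, "species", "M. tuberculosis"),
    7: (3, "species", "S. cerevisiae"),
})


def hit(q, taxid):
    return AlignmentRecord(q, f"t{taxid}", 0.3, 0.9, 0.9, 1e-9,
                           tm_score=0.8, target_taxid=taxid)


print("lca of the two mycobacteria:", tree.name(lca(tree, [5, 6])))

results = per_query_lca(
    {"gp12": [hit("gp12", 5), hit("gp12", 6)],
     "gp43": [hit("gp43", 5), hit("gp43", 7)]},
    tree,
)
for r in results:
    print(f"  {r.query_id}: LCA {r.lca_name} (rank {r.lca_rank}, {r.n_hits} hits)")

dist = rank_distribution([5, 6, 7], tree)
print("superkingdom split of hits:", {k: f"{v:.1f}%" for k, v in dist.items()})
# gp12's hits stay within one genus; gp43 spans bacteria and eukaryotes so
# its LCA climbs to the root.  Two thirds of the hit taxa are bacterial.
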