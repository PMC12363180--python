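"""Lowest-common-ancestor analysis of structural-homolog hits.

Given the NCBI-style taxonomy of the hit targets, each query's hits are
reduced to their LCA (the deepest node lying on every hit's root path), and
hit sets are summarised as rank-level distributions — e.g. the share of
best hits falling in each superkingdom.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .types import AlignmentRecord, LcaResult, TaxonomyTree

log = logging.getLogger(__name__)

__all__ = ["lca", "per_query_lca", "rank_distribution", "rank_count_table"]


def lca(tree: TaxonomyTree, taxids: Iterable[int]) -> int:
    """Deepest node on the root path of every given taxid.

    A single taxid is its own LCA.  Unknown taxids raise ``ValueError``.
    """
    taxid_list = list(taxids)
    if not taxid_list:
        raise ValueError("lca of an empty taxid set is undefined")
    unknown = sorted(t for t in set(taxid_list) if t not in tree)
    if unknown:
        raise ValueError(f"taxids not in taxonomy: {unknown}")
    it = iter(set(taxid_list))
    common = tree.root_path(next(it))
    for t in it:
        path = tree.root_path(t)
        limit = min(len(common), len(path))
        i = 0
        while i < limit and common[i] == path[i]:
            i += 1
        common = common[:i]
    return common[-1]


def per_query_lca(
    hits_by_query: Mapping[str, Sequence[AlignmentRecord]],
    tree: TaxonomyTree,
) -> list[LcaResult]:
    """One LCA per query over its taxid-bearing hits.

    Hits without a taxid are skipped with a warning; queries left with no
    usable hits are omitted (counted in the log).
    """
    results: list[LcaResult] = []
    n_omitted = 0
    for query in sorted(hits_by_query):
        taxids = [
            h.target_taxid for h in hits_by_query[query] if h.target_taxid is not None
        ]
        n_skipped = len(hits_by_query[query]) - len(taxids)
        if n_skipped:
            log.warning("per_query_lca: %s: %d hits without taxid skipped", query, n_skipped)
        if not taxids:
            n_omitted += 1
            continue
        t = lca(tree, taxids)
        results.append(
            LcaResult(
                query_id=query,
                lca_taxid=t,
                lca_rank=tree.rank(t),
                lca_name=tree.name(t),
                n_hits=len(taxids),
            )
        )
    if n_omitted:
        log.info("per_query_lca: %d queries had no taxid-bearing hits", n_omitted)
    return results


def rank_distribution(
    items: Iterable[int] | Iterable[LcaResult],
    tree: TaxonomyTree,
    rank: str = "superkingdom",
) -> dict[str, float]:
    """Percentage of items per taxon at the requested rank.

    Items may be raw taxids (e.g. best-hit taxa) or :class:`LcaResult`
    objects (per-query LCAs); both entry points are supported because a
    distribution can legitimately be computed over either.  An item whose
    node lies above the requested rank lands in the ``"unassigned"``
    bucket.  Percentages sum to 100 up to rounding.
    """
    counts: Counter[str] = Counter()
    n = 0
    for item in items:
        taxid = item.lca_taxid if isinstance(item, LcaResult) else int(item)
        anc = tree.ancestor_at_rank(taxid, rank)
        counts[tree.name(anc) if anc is not None else "unassigned"] += 1
        n += 1
    if n == 0:
        return {}
    return {name: 100.0 * c / n for name, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))}


def rank_count_table(
    taxids: Iterable[int],
    tree: TaxonomyTree,
    ranks: Sequence[str] = ("superkingdom", "phylum", "class", "order", "family", "genus", "species"),
    top_k: int = 8,
) -> dict[str, list[tuple[str, int]]]:
    """Rank-by-rank counts of the largest ``top_k`` taxa per rank.

    A flat substitute for Sankey-style flow plots: for each rank, counts of
    items whose lineage passes through each taxon at that rank.
    """
    taxid_list = list(taxids)
    per_rank: dict[str, Counter[str]] = defaultdict(Counter)
    for t in taxid_list:
        for node in tree.root_path(t):
            r = tree.rank(node)
            if r in ranks:
                per_rank[r][tree.name(node)] += 1
    return {
        r: sorted(per_rank.get(r, Counter()).items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        for r in ranks
    }
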