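"""Greedy set-cover sequence clustering over precomputed pairwise alignments.

Mirrors the semantics of MMseqs2 ``cluster --cluster-mode 0`` at desk scale:
a similarity graph is built from alignment rows that pass identity and
coverage thresholds (defaults 0.5 identity, 0.9 bidirectional coverage),
clusters are carved greedily by largest uncovered neighbourhood, and a
reassignment pass moves members that lack an edge to their representative.
Cascaded clustering is a speed optimisation of the original tool, not part
of the definition, and is intentionally not reproduced.

All tie-breaking is lexicographic on protein id so results are fully
deterministic.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

from .types import AlignmentRecord, Clustering, PhageMetadata, SimilarityGraph

__all__ = [
    "build_similarity_graph",
    "greedy_set_cover_cluster",
    "reassign_members",
    "cluster_size_summary",
    "screen_mixed_lifestyle_clusters",
    "DEFAULT_SIZE_BINS",
]


def build_similarity_graph(
    alignments: Iterable[AlignmentRecord],
    min_identity: float = 0.5,
    min_coverage: float = 0.9,
    coverage_mode: str = "bidirectional",
) -> SimilarityGraph:
    """Build the undirected qualifying-pair graph.

    A pair (q, t) becomes an edge iff some record reaches ``min_identity``
    and satisfies the coverage rule: *bidirectional* requires both query and
    target coverage at or above ``min_coverage``; *target* requires only the
    target coverage.  Thresholds are inclusive, matching the conventions of
    the alignment tools whose output is consumed.  Self-alignments never
    produce edges.
    """
    if coverage_mode not in ("bidirectional", "target"):
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    if not (0.0 <= min_identity <= 1.0 and 0.0 <= min_coverage <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    graph = SimilarityGraph()
    for rec in alignments:
        graph.add_node(rec.query_id)
        graph.add_node(rec.target_id)
        if rec.query_id == rec.target_id:
            continue
        if rec.seq_identity < min_identity:
            continue
        if coverage_mode == "bidirectional":
            if rec.query_cov < min_coverage or rec.target_cov < min_coverage:
                continue
        else:
            if rec.target_cov < min_coverage:
                continue
        graph.add_edge(rec.query_id, rec.target_id)
    return graph


def greedy_set_cover_cluster(graph: SimilarityGraph) -> Clustering:
    """Partition the graph by greedy set cover over closed neighbourhoods.

    Repeatedly select the node whose closed neighbourhood covers the most
    still-uncovered nodes (ties broken by lexicographically smallest id).
    The winner becomes a representative; it and its currently uncovered
    neighbours form (or extend) its cluster.  A winner that was already
    covered as an ordinary member moves into the new cluster it represents,
    preserving the partition property.
    """
    uncovered = set(graph.node_ids)
    clusters: dict[str, set[str]] = {}
    member_of: dict[str, str] = {}

    while uncovered:
        best_id = None
        best_gain = 0
        for node in graph.node_ids:
            newly = ({node} | graph.neighbors(node)) & uncovered
            gain = len(newly)
            if gain > best_gain or (
                gain == best_gain and best_id is not None and gain > 0 and node < best_id
            ):
                best_gain = gain
                best_id = node
        assert best_id is not None and best_gain > 0
        newly = ({best_id} | graph.neighbors(best_id)) & uncovered
        if best_id in clusters:
            # already a representative: extend its cluster
            target = clusters[best_id]
        elif best_id in member_of:
            # covered as an ordinary member: move it into the cluster it now represents
            clusters[member_of[best_id]].discard(best_id)
            target = clusters.setdefault(best_id, set())
            target.add(best_id)
            member_of[best_id] = best_id
        else:
            target = clusters.setdefault(best_id, set())
        for n in newly | {best_id}:
            target.add(n)
            member_of[n] = best_id
        uncovered -= newly
    return Clustering(clusters, provenance="sequence")


def reassign_members(clustering: Clustering, graph: SimilarityGraph) -> Clustering:
    """Move members that lack an edge to their representative.

    Each offending non-representative member goes to the lexicographically
    smallest other representative it has an edge to; with no qualifying
    representative it becomes a new singleton cluster.  The operation is
    idempotent and preserves the partition property.
    """
    reps = sorted(clustering.clusters)
    rep_set = set(reps)
    new_clusters: dict[str, set[str]] = {r: {r} for r in reps}
    for rep in reps:
        for member in sorted(clustering.clusters[rep]):
            if member == rep:
                continue
            if graph.has_edge(member, rep):
                new_clusters[rep].add(member)
                continue
            candidates = [
                r for r in reps
                if r != rep and r != member and graph.has_edge(member, r)
            ]
            if candidates:
                new_clusters[min(candidates)].add(member)
            elif member in rep_set:
                # degenerate: member doubles as a representative elsewhere —
                # cannot happen for a partition, guarded for safety
                new_clusters[member].add(member)
            else:
                new_clusters[member] = {member}
    return Clustering(new_clusters, provenance=clustering.provenance)


#: (label, low, high) half-open size bins [low, high]; high=None means unbounded.
DEFAULT_SIZE_BINS: tuple[tuple[str, int, int | None], ...] = (
    ("1", 1, 1),
    ("2", 2, 2),
    ("3-5", 3, 5),
    ("6-10", 6, 10),
    ("11-20", 11, 20),
    ("21-50", 21, 50),
    ("51-100", 51, 100),
    (">100", 101, None),
)


def cluster_size_summary(
    clustering: Clustering,
    bins: Sequence[tuple[str, int, int | None]] = DEFAULT_SIZE_BINS,
) -> list[tuple[str, int]]:
    """Count clusters per size bin; counts sum to the number of clusters."""
    counts: Counter[str] = Counter()
    for members in clustering.clusters.values():
        size = len(members)
        for label, lo, hi in bins:
            if size >= lo and (hi is None or size <= hi):
                counts[label] += 1
                break
        else:
            raise ValueError(f"cluster size {size} falls in no bin")
    return [(label, counts.get(label, 0)) for label, _lo, _hi in bins]


def screen_mixed_lifestyle_clusters(
    clustering: Clustering,
    protein_to_phage: Mapping[str, str],
    metadata: Iterable[PhageMetadata],
) -> set[str]:
    """Representatives of non-singleton clusters spanning both lifestyles.

    A cluster qualifies when its members come from at least one temperate
    and at least one lytic phage.  Singleton clusters are excluded before
    screening.  Every member must map to a phage with known metadata.
    """
    lifestyle = {m.phage_id: m.lifestyle for m in metadata}
    missing = sorted(
        {m for ms in clustering.clusters.values() for m in ms}
        - set(protein_to_phage)
    )
    if missing:
        raise ValueError(f"proteins without a phage mapping: {missing}")
    unknown_phages = sorted(
        {protein_to_phage[m] for ms in clustering.clusters.values() for m in ms}
        - set(lifestyle)
    )
    if unknown_phages:
        raise ValueError(f"phages without metadata: {unknown_phages}")

    selected: set[str] = set()
    for rep, members in clustering.clusters.items():
        if len(members) < 2:
            continue
        styles = {lifestyle[protein_to_phage[m]] for m in members}
        if "temperate" in styles and "lytic" in styles:
            selected.add(rep)
    return selected
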