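"""Phage-host interaction scoring, screening, networks, and heatmaps.

Multimer structure predictors report two confidences per protein pair: the
interface score (ipTM) and the overall score (pTM).  They are combined as

    score = 0.8 * ipTM + 0.2 * pTM

and pairs are screened at a strict threshold (0.5 for the network view,
0.7 for the stringent candidate list).  Screened pairs become a bipartite
network: phage representatives sized by the number of proteins they stand
for, host proteins sized by how many phage proteins target them, edges
weighted by the score.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .types import InteractionRecord, ScoredInteraction

log = logging.getLogger(__name__)

__all__ = [
    "interaction_score",
    "score_interactions",
    "screen_interactions",
    "build_network",
    "network_to_graphml",
    "edge_list",
    "normalized_cluster_heatmap",
]


def interaction_score(iptm: float, ptm: float) -> float:
    """Weighted multimer confidence 0.8*ipTM + 0.2*pTM."""
    for name, v in (("iptm", iptm), ("ptm", ptm)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    return 0.8 * iptm + 0.2 * ptm


def score_interactions(
    records: Iterable[InteractionRecord],
) -> list[ScoredInteraction]:
    """Attach the weighted combined score to every record."""
    return [
        ScoredInteraction(
            r.phage_protein_id, r.host_protein_id, r.iptm, r.ptm,
            interaction_score(r.iptm, r.ptm),
        )
        for r in records
    ]


def screen_interactions(
    records: Iterable[InteractionRecord],
    threshold: float = 0.5,
    screen_on: str = "weighted",
) -> list[ScoredInteraction]:
    """Keep pairs whose score is strictly greater than ``threshold``.

    Defaults: 0.5 (network screen); pass 0.7 for the stringent list.
    ``screen_on='raw_sum'`` screens on the unweighted ipTM + pTM (a [0, 2]
    scale) while still reporting the weighted score; the weighted reading
    is the default because that is how the combined confidence is defined.
    """
    if screen_on not in ("weighted", "raw_sum"):
        raise ValueError(f"unknown screen_on {screen_on!r}")
    if screen_on == "weighted" and not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold!r}")
    scored = score_interactions(records)
    if screen_on == "raw_sum":
        return [s for s in scored if (s.iptm + s.ptm) > threshold]
    return [s for s in scored if s.score > threshold]


def build_network(
    screened: Sequence[ScoredInteraction],
    phage_rep_sizes: Mapping[str, int],
) -> nx.Graph:
    """Bipartite phage-host network from screened interactions.

    Node attributes: ``kind`` ('phage'/'host'), ``size`` = represented
    protein count for phage nodes, ``degree`` = interacting phage-protein
    count for host nodes.  Edge weight = interaction score.  Duplicate
    (phage, host) pairs are collapsed to their maximum score with a log
    message.  Every phage node must have a size entry.
    """
    best: dict[tuple[str, str], ScoredInteraction] = {}
    n_dups = 0
    for s in screened:
        key = (s.phage_protein_id, s.host_protein_id)
        if key in best:
            n_dups += 1
            if s.score > best[key].score:
                best[key] = s
        else:
            best[key] = s
    if n_dups:
        log.info("build_network: collapsed %d duplicate pairs to max score", n_dups)

    missing = sorted({p for p, _h in best} - set(phage_rep_sizes))
    if missing:
        raise ValueError(f"phage nodes without a size entry: {missing}")

    graph = nx.Graph()
    for phage, host in sorted(best):
        s = best[(phage, host)]
        if phage not in graph:
            graph.add_node(phage, kind="phage", size=int(phage_rep_sizes[phage]))
        if host not in graph:
            graph.add_node(host, kind="host")
        graph.add_edge(phage, host, weight=s.score, iptm=s.iptm, ptm=s.ptm)
    for node, data in graph.nodes(data=True):
        if data.get("kind") == "host":
            data["degree"] = graph.degree(node)
    return graph


def edge_list(graph: nx.Graph) -> list[tuple[str, str, float]]:
    """Deterministic (source, target, weight) rows, phage node first."""
    rows = []
    for a, b, data in graph.edges(data=True):
        if graph.nodes[a].get("kind") == "host":
            a, b = b, a
        rows.append((a, b, data["weight"]))
    return sorted(rows)


def network_to_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def normalized_cluster_heatmap(
    hit_counts: Mapping[tuple[str, str], int],
    phages_per_group: Mapping[str, int],
):
    """Per-phage-group normalised hit matrix.

    ``hit_counts`` maps (category, phage group) -> protein count; each cell
    is divided by the number of phages in the group, so groups of different
    sizes are comparable.  Missing (category, group) combinations are 0.
    Returns a pandas DataFrame (rows = categories, columns = groups).
    """
    import pandas as pd

    bad = sorted(g for g, n in phages_per_group.items() if n <= 0)
    if bad:
        raise ValueError(f"groups with non-positive phage counts: {bad}")
    unknown = sorted({g for (_c, g) in hit_counts} - set(phages_per_group))
    if unknown:
        raise ValueError(f"hit counts reference unknown groups: {unknown}")

    categories = sorted({c for (c, _g) in hit_counts})
    groups = sorted(phages_per_group)
    data = {
        g: [hit_counts.get((c, g), 0) / phages_per_group[g] for c in categories]
        for g in groups
    }
    return pd.DataFrame(data, index=categories, columns=groups)
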