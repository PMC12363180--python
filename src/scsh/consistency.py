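"""Cluster-purity and annotation-consistency statistics.

Structural purity is the per-cluster mean LDDT/TM of members aligned to
their representative.  Label consistency asks how often members of the same
cluster carry the same functional labels:

* Pfam: over all ordered pairs (ref, other) of annotated members, a pair
  scores |pfam(ref) ∩ pfam(other)| / |pfam(ref)|; the cluster score is the
  mean over pairs.  Averaging both directions makes the score symmetric
  while preserving the reference-normalised definition.
* EC: same pairwise scheme at each of the four hierarchical levels, on
  members carrying exactly one EC code, after disregarding codes whose
  token at the evaluated level is "-".  With one code per member, a pair
  scores 1 when the level-truncated codes are equal, else 0.

The module also scores an external EC predictor against reference labels
(levels 1-3), applies confidence/pLDDT gates, and mechanises the manual
semantic-equivalence check through a configurable synonym-group map.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    AlignmentRecord,
    Clustering,
    ClusterPurity,
    ConsistencyScore,
    FunctionalLabels,
)

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_AMBIGUOUS_TERMS",
    "structural_purity",
    "pfam_consistency",
    "ec_consistency",
    "cluster_consistency_scores",
    "consistency_vs_metric_binning",
    "deepfri_ec_agreement",
    "confidence_gate",
    "plddt_gate",
    "semantic_consistency",
]

#: Representative annotations containing these terms are dropped before the
#: semantic-consistency comparison.
DEFAULT_AMBIGUOUS_TERMS: tuple[str, ...] = (
    "hypothetical",
    "membrane",
    "structural",
    "virion",
    "putative",
)


# ---------------------------------------------------------------------------
# Structural purity


def structural_purity(
    clustering: Clustering,
    rep_vs_member_alignments: Iterable[AlignmentRecord],
) -> tuple[list[ClusterPurity], Optional[float], Optional[float]]:
    """Per-cluster mean LDDT and TM over representative-vs-member rows.

    Self-alignments (representative vs itself) are excluded; clusters with
    no non-self member alignments (singletons in particular) are omitted
    with a warning.  Returns the per-cluster list plus the global medians of
    the per-cluster means (``None`` when nothing was scored).
    """
    member_rows: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in rep_vs_member_alignments:
        if rec.query_id == rec.target_id:
            continue
        member_rows[rec.query_id].append(rec)

    purities: list[ClusterPurity] = []
    for rep in sorted(clustering.clusters):
        rows = [
            r for r in member_rows.get(rep, [])
            if r.target_id in clustering.clusters[rep]
        ]
        rows = [r for r in rows if r.lddt is not None and r.tm_score is not None]
        if not rows:
            if len(clustering.clusters[rep]) > 1:
                log.warning("structural_purity: cluster %s has no member alignments", rep)
            continue
        purities.append(
            ClusterPurity(
                representative_id=rep,
                mean_lddt=statistics.mean(r.lddt for r in rows),  # type: ignore[misc]
                mean_tm=statistics.mean(r.tm_score for r in rows),  # type: ignore[misc]
                n_members_aligned=len(rows),
            )
        )
    if purities:
        median_lddt = statistics.median(p.mean_lddt for p in purities)
        median_tm = statistics.median(p.mean_tm for p in purities)
    else:
        median_lddt = median_tm = None
    return purities, median_lddt, median_tm


# ---------------------------------------------------------------------------
# Label consistency


def pfam_consistency(
    representative_id: str,
    member_labels: Sequence[FunctionalLabels],
) -> Optional[ConsistencyScore]:
    """Mean ordered-pair Pfam agreement within one cluster.

    Members without Pfam annotations are excluded; clusters with fewer than
    two annotated members are not scored (returns ``None``).
    """
    annotated = [lab for lab in member_labels if lab.pfam_accessions]
    if len(annotated) < 2:
        return None
    pair_scores: list[float] = []
    for ref in annotated:
        for other in annotated:
            if ref.protein_id == other.protein_id:
                continue
            shared = ref.pfam_accessions & other.pfam_accessions
            pair_scores.append(len(shared) / len(ref.pfam_accessions))
    return ConsistencyScore(
        representative_id=representative_id,
        label_kind="pfam",
        score=statistics.mean(pair_scores),
        n_annotated_members=len(annotated),
    )


def ec_consistency(
    representative_id: str,
    member_labels: Sequence[FunctionalLabels],
    level: int,
) -> Optional[ConsistencyScore]:
    """Mean pairwise EC agreement at one hierarchical level (1-4).

    Members with multiple EC codes are excluded entirely; codes whose token
    at the evaluated level is "-" are disregarded at that level.  With
    fewer than two eligible members the cluster is skipped.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"EC level must be 1..4, got {level}")
    eligible: list[tuple[str, tuple[str, ...]]] = []
    for lab in member_labels:
        if len(lab.ec_numbers) != 1:
            continue
        code = lab.ec_numbers[0]
        if code[level - 1] == "-":
            continue
        eligible.append((lab.protein_id, code[:level]))
    if len(eligible) < 2:
        return None
    pair_scores: list[float] = []
    for i, (_pid_i, code_i) in enumerate(eligible):
        for j, (_pid_j, code_j) in enumerate(eligible):
            if i == j:
                continue
            pair_scores.append(1.0 if code_i == code_j else 0.0)
    return ConsistencyScore(
        representative_id=representative_id,
        label_kind=f"ec_level_{level}",
        score=statistics.mean(pair_scores),
        n_annotated_members=len(eligible),
    )


def cluster_consistency_scores(
    clustering: Clustering,
    labels: Iterable[FunctionalLabels],
    kinds: Sequence[str] = ("pfam", "ec_level_1", "ec_level_2", "ec_level_3", "ec_level_4"),
) -> list[ConsistencyScore]:
    """Score every cluster for the requested label kinds."""
    by_id = {lab.protein_id: lab for lab in labels}
    out: list[ConsistencyScore] = []
    for rep in sorted(clustering.clusters):
        member_labels = [
            by_id[m] for m in sorted(clustering.clusters[rep]) if m in by_id
        ]
        for kind in kinds:
            if kind == "pfam":
                score = pfam_consistency(rep, member_labels)
            elif kind.startswith("ec_level_"):
                score = ec_consistency(rep, member_labels, int(kind[-1]))
            else:
                raise ValueError(f"unknown label kind {kind!r}")
            if score is not None:
                out.append(score)
    return out


def consistency_vs_metric_binning(
    scores: Mapping[str, float],
    metric_values: Mapping[str, float],
    bin_edges: Sequence[float],
) -> list[dict]:
    """Summarise scores within half-open metric bins (lo, hi].

    ``scores`` and ``metric_values`` are keyed by representative id; every
    scored cluster must have a metric value inside some bin.  Each row
    reports the bin, the cluster count, the fraction of clusters whose
    score is exactly 1.0, and the mean score; empty bins report absent
    (``None``) statistics.
    """
    missing = sorted(set(scores) - set(metric_values))
    if missing:
        raise ValueError(f"scored clusters without a metric value: {missing}")
    bins = list(zip(bin_edges[:-1], bin_edges[1:]))
    assigned: dict[int, list[float]] = defaultdict(list)
    for rep, score in scores.items():
        v = metric_values[rep]
        for i, (lo, hi) in enumerate(bins):
            if lo < v <= hi:
                assigned[i].append(score)
                break
        else:
            raise ValueError(f"metric value {v} for {rep!r} falls outside all bins")
    rows: list[dict] = []
    for i, (lo, hi) in enumerate(bins):
        vals = assigned.get(i, [])
        rows.append(
            {
                "bin": (lo, hi),
                "n_clusters": len(vals),
                "fraction_fully_consistent": (
                    sum(1 for v in vals if v == 1.0) / len(vals) if vals else None
                ),
                "mean_score": statistics.mean(vals) if vals else None,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# External EC predictor benchmarking


def deepfri_ec_agreement(
    predicted: Mapping[str, tuple[tuple[str, str, str, str], float]],
    reference: Mapping[str, tuple[str, str, str, str]],
    levels: Sequence[int] = (1, 2, 3),
) -> dict[int, float]:
    """Fraction of proteins whose predicted and reference EC codes agree on
    the first ``level`` tokens, per level.

    Only proteins present in both maps enter the benchmark; at each level a
    protein counts only when both codes carry a non-"-" token there.
    """
    shared = sorted(set(predicted) & set(reference))
    if not shared:
        raise ValueError("no proteins shared between predicted and reference maps")
    out: dict[int, float] = {}
    for level in levels:
        n_eval = 0
        n_agree = 0
        for pid in shared:
            pred_code = predicted[pid][0]
            ref_code = reference[pid]
            if pred_code[level - 1] == "-" or ref_code[level - 1] == "-":
                continue
            n_eval += 1
            if pred_code[:level] == ref_code[:level]:
                n_agree += 1
        out[level] = (n_agree / n_eval) if n_eval else float("nan")
    return out


def confidence_gate(
    predictions: Mapping[str, tuple[tuple[str, str, str, str], float]],
    min_score: float = 0.8,
) -> tuple[dict[str, tuple[tuple[str, str, str, str], float]], int, int]:
    """Keep predictions with confidence strictly above ``min_score``.

    Returns (kept, n_retained, n_total).
    """
    kept = {pid: v for pid, v in predictions.items() if v[1] > min_score}
    return kept, len(kept), len(predictions)


def plddt_gate(
    mean_plddt_by_protein: Mapping[str, float],
    min_plddt: float = 90.0,
) -> tuple[set[str], int, int]:
    """Keep proteins whose mean pLDDT is strictly above ``min_plddt``.

    Returns (kept ids, n_retained, n_total).
    """
    kept = {pid for pid, v in mean_plddt_by_protein.items() if v > min_plddt}
    return kept, len(kept), len(mean_plddt_by_protein)


# ---------------------------------------------------------------------------
# Semantic consistency of structure- vs sequence-based annotations


def _normalize(text: str) -> str:
    return " ".join(text.lower().split())


def semantic_consistency(
    clustering: Clustering,
    transferred: Mapping[str, str],
    sequence_products: Mapping[str, str],
    synonym_groups: Sequence[Sequence[str]],
    ambiguous_terms: Sequence[str] = DEFAULT_AMBIGUOUS_TERMS,
) -> tuple[float, int, int]:
    """Fraction of members whose structure- and sequence-based annotations
    are semantically equivalent.

    ``transferred`` maps protein id -> structure-transferred name;
    ``sequence_products`` maps protein id -> GFF product.  Clusters whose
    representative's transferred annotation contains an ambiguous term are
    removed before scoring.  Two annotations are consistent when identical
    after whitespace/case normalisation or when both fall in the same
    synonym group.  Returns (fraction, n_consistent, n_members_retained).
    """
    if synonym_groups is None:
        raise ValueError(
            "semantic consistency requires a synonym-group config; provide a "
            "(possibly empty) list of equivalence classes"
        )
    group_of: dict[str, int] = {}
    for gi, group in enumerate(synonym_groups):
        for term in group:
            group_of[_normalize(term)] = gi

    n_members = 0
    n_consistent = 0
    for rep in sorted(clustering.clusters):
        rep_annot = transferred.get(rep)
        if rep_annot is None:
            continue  # nothing was transferred to this cluster
        lowered = rep_annot.lower()
        if any(term.lower() in lowered for term in ambiguous_terms):
            continue  # ambiguous representative annotation: cluster removed
        for member in sorted(clustering.clusters[rep]):
            struct_annot = transferred.get(member)
            seq_annot = sequence_products.get(member)
            if struct_annot is None:
                continue
            n_members += 1
            if seq_annot is None:
                continue
            a, b = _normalize(struct_annot), _normalize(seq_annot)
            if a == b:
                n_consistent += 1
            elif a in group_of and b in group_of and group_of[a] == group_of[b]:
                n_consistent += 1
    if n_members == 0:
        raise ValueError("no cluster members retained after the ambiguity filter")
    return n_consistent / n_members, n_consistent, n_members
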