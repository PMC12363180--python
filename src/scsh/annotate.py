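"""Structure-hit filtering, annotation transfer, and annotation rates.

Two rates summarise how well a proteome is annotated:

* sequence-based rate  = (n_all - n_unannotated) / n_all, where a protein is
  unannotated when its GenBank/GFF product contains "hypothetical protein"
  (or is empty);
* structure-based rate = (n_match - n_void) / n_all, where n_match counts
  proteins that received a transferred structural annotation and n_void the
  transferred names that are uninformative (putative / hypothetical /
  uncharacterized / domain of unknown function).

Both rates share the same denominator (every protein in the input set), so
they are directly comparable.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    TARGET_DBS,
    AlignmentRecord,
    AnnotationTally,
    BestHit,
    Clustering,
    PhageMetadata,
    ProductAnnotation,
    StructureModel,
)

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_VOID_TERMS",
    "filter_structure_hits",
    "select_best_hit",
    "best_hits_by_query",
    "classify_void",
    "is_sequence_unannotated",
    "transfer_annotations",
    "sequence_annotation_rate",
    "structure_annotation_rate",
    "per_group_rates",
    "mean_plddt",
    "classify_plddt",
    "counter_defense_screen",
]

#: Terms marking a structural hit's name as uninformative (a "void match").
DEFAULT_VOID_TERMS: tuple[str, ...] = (
    "putative",
    "hypothetical",
    "uncharacterized",
    "domain of unknown function",
)


def filter_structure_hits(
    alignments: Iterable[AlignmentRecord],
    min_tm: float = 0.5,
    min_coverage: float = 0.8,
    coverage_mode: str = "bidirectional",
) -> list[AlignmentRecord]:
    """Keep structural hits at or above the TM-score and coverage thresholds.

    ``coverage_mode='target'`` supports local searches where only the target
    must be covered.  Records lacking a TM-score are skipped with a warning.
    """
    if coverage_mode not in ("bidirectional", "target"):
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    kept: list[AlignmentRecord] = []
    n_skipped = 0
    for rec in alignments:
        if rec.tm_score is None:
            n_skipped += 1
            continue
        if rec.tm_score < min_tm:
            continue
        if coverage_mode == "bidirectional":
            if rec.query_cov < min_coverage or rec.target_cov < min_coverage:
                continue
        else:
            if rec.target_cov < min_coverage:
                continue
        kept.append(rec)
    if n_skipped:
        log.warning("filter_structure_hits: skipped %d records without tm_score", n_skipped)
    return kept


_DB_PRECEDENCE = {db: i for i, db in enumerate(TARGET_DBS)}


def select_best_hit(hits: Sequence[AlignmentRecord]) -> Optional[BestHit]:
    """Pick the winning hit for one query from threshold-filtered records.

    Ranking: highest TM-score, then lower E-value, then database precedence
    PDB > AFDB_SwissProt > AFDB > other, then lexicographic target id.
    Returns ``None`` for an empty hit list.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")

    def key(h: AlignmentRecord):
        tm = h.tm_score if h.tm_score is not None else -1.0
        return (-tm, h.evalue, _DB_PRECEDENCE.get(h.target_db, len(TARGET_DBS)), h.target_id)

    best = min(hits, key=key)
    return BestHit(
        query_id=best.query_id,
        target_id=best.target_id,
        target_name=best.target_name,
        target_db=best.target_db,
        tm_score=best.tm_score if best.tm_score is not None else 0.0,
        evalue=best.evalue,
    )


def best_hits_by_query(hits: Iterable[AlignmentRecord]) -> dict[str, BestHit]:
    """Group filtered hits by query and select each query's best hit."""
    grouped: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    out: dict[str, BestHit] = {}
    for q in sorted(grouped):
        best = select_best_hit(grouped[q])
        if best is not None:
            out[q] = best
    return out


def classify_void(
    target_name: Optional[str],
    void_terms: Sequence[str] = DEFAULT_VOID_TERMS,
) -> bool:
    """True when the hit name is uninformative.

    Matching is case-insensitive substring; an absent or empty name is void.
    """
    if not target_name:
        return True
    lowered = target_name.lower()
    return any(term.lower() in lowered for term in void_terms)


def is_sequence_unannotated(product: str) -> bool:
    """True when a GFF product marks the protein as unannotated
    ("hypothetical protein", case-insensitive, or empty)."""
    if not product:
        return True
    return "hypothetical protein" in product.lower()


def transfer_annotations(
    clustering: Clustering,
    rep_best_hits: Mapping[str, BestHit],
) -> list[ProductAnnotation]:
    """Propagate each representative's best-hit name to its whole cluster.

    Clusters whose representative has no hit contribute no records.
    """
    unknown = sorted(set(rep_best_hits) - set(clustering.clusters))
    if unknown:
        raise ValueError(f"best-hit keys are not representatives: {unknown}")
    out: list[ProductAnnotation] = []
    for rep in sorted(clustering.clusters):
        hit = rep_best_hits.get(rep)
        if hit is None:
            continue
        product = hit.target_name or ""
        for member in sorted(clustering.clusters[rep]):
            out.append(
                ProductAnnotation(
                    protein_id=member, product=product, source="structure_transfer"
                )
            )
    return out


def sequence_annotation_rate(
    products: Sequence[ProductAnnotation],
) -> tuple[AnnotationTally, float]:
    """(n_all - n_unannotated) / n_all over GFF product annotations."""
    if not products:
        raise ValueError("undefined rate: no products given")
    n_all = len(products)
    n_un = sum(1 for p in products if is_sequence_unannotated(p.product))
    tally = AnnotationTally(n_all=n_all, n_unannotated=n_un)
    return tally, (n_all - n_un) / n_all


def structure_annotation_rate(
    all_ids: Iterable[str],
    transferred: Sequence[ProductAnnotation],
    void_terms: Sequence[str] = DEFAULT_VOID_TERMS,
) -> tuple[AnnotationTally, float]:
    """(n_match - n_void) / n_all over transferred structural annotations.

    ``all_ids`` is the full protein set (the same denominator the sequence
    rate uses); ``transferred`` are the structure-transferred products.
    """
    ids = set(all_ids)
    if not ids:
        raise ValueError("undefined rate: empty protein set")
    stray = sorted({t.protein_id for t in transferred} - ids)
    if stray:
        raise ValueError(f"transferred ids outside the protein set: {stray}")
    n_all = len(ids)
    n_match = len(transferred)
    n_void = sum(1 for t in transferred if classify_void(t.product, void_terms))
    tally = AnnotationTally(n_all=n_all, n_match=n_match, n_void=n_void)
    return tally, (n_match - n_void) / n_all


def per_group_rates(
    products: Sequence[ProductAnnotation],
    transferred: Sequence[ProductAnnotation],
    protein_to_phage: Mapping[str, str],
    metadata: Iterable[PhageMetadata],
    void_terms: Sequence[str] = DEFAULT_VOID_TERMS,
) -> dict:
    """Per-phage, per-group, and overall annotation rates, both ways.

    Returns a dict with:

    * ``per_phage``: phage id -> (sequence rate, structure rate)
    * ``per_group_averaged``: group -> mean of member-phage rates
    * ``overall_averaged``: unweighted mean over phages (each genome counts
      once, regardless of proteome size)
    * ``overall_pooled``: rates over the pooled protein set
    """
    group_of = {m.phage_id: m.group for m in metadata}
    unmapped = sorted({p.protein_id for p in products} - set(protein_to_phage))
    if unmapped:
        raise ValueError(f"proteins without a phage mapping: {unmapped}")

    by_phage_products: dict[str, list[ProductAnnotation]] = defaultdict(list)
    for p in products:
        by_phage_products[protein_to_phage[p.protein_id]].append(p)
    by_phage_transferred: dict[str, list[ProductAnnotation]] = defaultdict(list)
    for t in transferred:
        phage = protein_to_phage.get(t.protein_id)
        if phage is None:
            raise ValueError(f"transferred protein {t.protein_id!r} has no phage mapping")
        by_phage_transferred[phage].append(t)

    per_phage: dict[str, tuple[float, float]] = {}
    for phage, prods in sorted(by_phage_products.items()):
        _t, seq_rate = sequence_annotation_rate(prods)
        ids = [p.protein_id for p in prods]
        _t, struct_rate = structure_annotation_rate(
            ids, by_phage_transferred.get(phage, []), void_terms
        )
        per_phage[phage] = (seq_rate, struct_rate)

    groups: dict[str, list[tuple[float, float]]] = defaultdict(list)
    for phage, rates in per_phage.items():
        groups[group_of.get(phage, "unknown")].append(rates)
    per_group = {
        g: (
            statistics.mean(r[0] for r in rates),
            statistics.mean(r[1] for r in rates),
        )
        for g, rates in sorted(groups.items())
    }

    overall_avg = (
        statistics.mean(r[0] for r in per_phage.values()),
        statistics.mean(r[1] for r in per_phage.values()),
    )
    _t, pooled_seq = sequence_annotation_rate(products)
    _t, pooled_struct = structure_annotation_rate(
        [p.protein_id for p in products], transferred, void_terms
    )
    return {
        "per_phage": per_phage,
        "per_group_averaged": per_group,
        "overall_averaged": overall_avg,
        "overall_pooled": (pooled_seq, pooled_struct),
    }


def mean_plddt(model: StructureModel) -> float:
    """Arithmetic mean of the per-residue pLDDT track."""
    return sum(model.per_residue_plddt) / len(model.per_residue_plddt)


def classify_plddt(mean: float, high_cutoff: float = 70.0) -> str:
    """'High_pLDDT' when the mean is at or above the cutoff, else 'Low_pLDDT'."""
    return "High_pLDDT" if mean >= high_cutoff else "Low_pLDDT"


def counter_defense_screen(
    alignments: Iterable[AlignmentRecord],
    min_tm: float = 0.6,
) -> list[AlignmentRecord]:
    """Hits against a counter-defense library with TM-score strictly above
    the threshold (default 0.6)."""
    return [
        rec for rec in alignments
        if rec.tm_score is not None and rec.tm_score > min_tm
    ]
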