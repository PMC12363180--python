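"""Seeded synthetic corpora with planted ground truth.

No stage of this package computes alignments, structures, or database
searches — those arrive as files from external tools.  The generator
therefore plants every pairwise statistic directly in the emitted tables:

* protein families with separable identity ranges, so threshold clustering
  recovers the planted partition exactly;
* GFF products with an exact planted fraction of "hypothetical protein";
* representative database hits with exact planted hit/void fractions, so
  both annotation rates are known in closed form;
* Pfam/EC labels agreeing within a family with probability ``pi`` (a pair
  agrees only when both members kept the family's canonical label, so the
  expected cluster consistency is ``pi**2``);
* per-residue pLDDT tracks, a small NCBI-style taxonomy with planted
  superkingdom proportions for hit targets, and a phage-host interaction
  table mixing positive and negative score distributions.

Sequences themselves are decorative random strings.  Regenerating with the
same spec yields byte-identical bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .types import (
    AlignmentRecord,
    Clustering,
    FunctionalLabels,
    InteractionRecord,
    PhageMetadata,
    ProductAnnotation,
    SequenceRecord,
    StructureModel,
    TaxonomyTree,
)

__all__ = ["FixtureSpec", "FixtureBundle", "generate", "expected_values", "write_bundle"]

#: Informative product vocabulary; each name pairs with a synonym variant so
#: the semantic-consistency step has a nontrivial config to work with.
VOCABULARY: tuple[tuple[str, str], ...] = (
    ("terminase large subunit", "phage terminase, large subunit"),
    ("major capsid protein", "capsid protein"),
    ("portal protein", "phage portal protein"),
    ("tail assembly chaperone", "tail chaperone protein"),
    ("minor tail protein", "phage tail protein"),
    ("endolysin", "lysin A"),
    ("holin", "class II holin"),
    ("DNA polymerase III subunit epsilon", "DnaQ-like DNA polymerase III subunit"),
    ("integrase", "tyrosine integrase"),
    ("helicase", "replicative DNA helicase"),
)

#: Void hit names carrying each of the uninformative terms.
VOID_NAMES: tuple[str, ...] = (
    "hypothetical protein XYZ_001",
    "putative DNA-binding protein",
    "uncharacterized protein",
    "domain of unknown function DUF1234",
)

SUPERKINGDOMS: tuple[str, ...] = ("Bacteria", "Eukaryota", "Viruses", "Archaea")


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the generator, with study-scale defaults.

    Defaults mirror the study conditions at desk scale: mostly small
    clusters with many singletons, a two-thirds hypothetical proteome
    (sequence annotation rate ~34%), representative hit and void fractions
    that push the structure-based rate above the sequence-based one, mean
    pLDDT near 77, and a best-hit superkingdom mix dominated by bacteria.
    """

    seed: int = 0
    n_families: int = 40
    family_size_distribution: tuple[str, float] = ("geometric", 0.45)
    max_family_size: int = 30
    within_identity_range: tuple[float, float] = (0.60, 0.95)
    between_identity_range: tuple[float, float] = (0.05, 0.35)
    frac_hypothetical: float = 0.66
    frac_void_hits: float = 0.15
    frac_reps_with_hits: float = 0.70
    label_agreement_pi: float = 0.90
    plddt_mean_sd: tuple[float, float] = (77.0, 10.0)
    taxonomy_shape: tuple[int, int] = (3, 3)  # (levels below superkingdom, branching)
    superkingdom_weights: tuple[float, float, float, float] = (
        0.6947, 0.1590, 0.1018, 0.0445
    )  # Bacteria, Eukaryota, Viruses, Archaea (normalised)
    n_phages: int = 24
    n_hosts: int = 12
    n_interactions: int = 200
    frac_true_pairs: float = 0.30
    positive_iptm_range: tuple[float, float] = (0.40, 0.90)
    positive_ptm_range: tuple[float, float] = (0.40, 0.90)
    negative_iptm_range: tuple[float, float] = (0.05, 0.55)
    negative_ptm_range: tuple[float, float] = (0.05, 0.60)

    def __post_init__(self) -> None:
        if self.within_identity_range[0] <= self.between_identity_range[1]:
            raise ValueError(
                "within_identity_range must lie entirely above "
                "between_identity_range (separability)"
            )
        for name in ("frac_hypothetical", "frac_void_hits", "frac_reps_with_hits",
                     "label_agreement_pi", "frac_true_pairs"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if abs(sum(self.superkingdom_weights) - 1.0) > 1e-9:
            raise ValueError("superkingdom_weights must sum to 1")


@dataclass
class FixtureBundle:
    """Everything the pipeline consumes, plus the planted ground truth."""

    spec: FixtureSpec
    sequences: list[SequenceRecord]
    alignments: list[AlignmentRecord]          # sequence all-vs-all rows
    rep_member_alignments: list[AlignmentRecord]  # rep-vs-member structural rows
    hit_table: list[AlignmentRecord]           # rep-vs-database structural hits
    planted_clustering: Clustering
    products: list[ProductAnnotation]
    labels: list[FunctionalLabels]
    models: list[StructureModel]
    taxonomy: TaxonomyTree
    interactions: list[InteractionRecord]
    metadata: list[PhageMetadata]
    protein_to_phage: dict[str, str]
    synonym_groups: list[list[str]]
    ground_truth: dict = field(default_factory=dict)


def _exact_subset(rng: np.random.Generator, items: list, fraction: float) -> set:
    """Deterministic-count subset: floor(fraction*n) items, chosen by a
    seeded shuffle."""
    k = math.floor(fraction * len(items))
    order = list(items)
    rng.shuffle(order)
    return set(order[:k])


def _exact_allocation(n: int, weights: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items to weights (exact sum)."""
    raw = [n * w for w in weights]
    counts = [math.floor(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _build_taxonomy(spec: FixtureSpec) -> tuple[TaxonomyTree, dict[str, list[int]]]:
    """Uniform tree: root -> 4 superkingdoms -> `levels` rank tiers of
    `branching` children each.  Returns the tree and the species-level
    leaves per superkingdom."""
    levels, branching = spec.taxonomy_shape
    rank_names = ["phylum", "genus", "species", "strain", "isolate"][:levels]
    nodes: dict[int, tuple[int, str, str]] = {1: (1, "no rank", "root")}
    leaves: dict[str, list[int]] = {}
    next_id = 2
    for sk in SUPERKINGDOMS:
        sk_id = next_id
        next_id += 1
        nodes[sk_id] = (1, "superkingdom", sk)
        frontier = [sk_id]
        for li, rank in enumerate(rank_names):
            new_frontier = []
            for parent in frontier:
                for b in range(branching):
                    nodes[next_id] = (parent, rank, f"{sk}_{rank}_{next_id}")
                    new_frontier.append(next_id)
                    next_id += 1
            frontier = new_frontier
        leaves[sk] = frontier
    return TaxonomyTree(nodes), leaves


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build the full corpus for one spec.  Same spec -> identical bundle."""
    rng = np.random.default_rng(spec.seed)

    # --- families and ids ------------------------------------------------
    dist_name, dist_param = spec.family_size_distribution
    if dist_name != "geometric":
        raise ValueError(f"unknown family size distribution {dist_name!r}")
    sizes = [
        int(min(rng.geometric(dist_param), spec.max_family_size))
        for _ in range(spec.n_families)
    ]
    families: list[list[str]] = []
    for fi, size in enumerate(sizes):
        families.append([f"F{fi:03d}_M{mi:02d}" for mi in range(size)])
    all_ids = [pid for fam in families for pid in fam]
    reps = [fam[0] for fam in families]  # lexicographically smallest member

    planted = Clustering({fam[0]: set(fam) for fam in families})

    # --- sequences (decorative) ------------------------------------------
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    sequences = []
    for pid in all_ids:
        length = int(rng.integers(80, 300))
        seq = "".join(rng.choice(aa, size=length))
        sequences.append(SequenceRecord(pid, pid, seq))

    # --- sequence alignment table (clustering input) ----------------------
    lo_w, hi_w = spec.within_identity_range
    lo_b, hi_b = spec.between_identity_range
    alignments: list[AlignmentRecord] = []
    for fam in families:
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                alignments.append(
                    AlignmentRecord(
                        query_id=fam[i], target_id=fam[j],
                        seq_identity=float(rng.uniform(lo_w, hi_w)),
                        query_cov=float(rng.uniform(0.92, 1.0)),
                        target_cov=float(rng.uniform(0.92, 1.0)),
                        evalue=float(10 ** -rng.uniform(5, 50)),
                    )
                )
    # sparse sub-threshold rows across families
    n_between = spec.n_families
    for _ in range(n_between):
        fi, fj = rng.choice(spec.n_families, size=2, replace=False)
        q = families[fi][int(rng.integers(len(families[fi])))]
        t = families[fj][int(rng.integers(len(families[fj])))]
        alignments.append(
            AlignmentRecord(
                query_id=q, target_id=t,
                seq_identity=float(rng.uniform(lo_b, hi_b)),
                query_cov=float(rng.uniform(0.5, 1.0)),
                target_cov=float(rng.uniform(0.5, 1.0)),
                evalue=float(10 ** -rng.uniform(0, 4)),
            )
        )
    # make singletons visible to the graph builder
    for fam in families:
        if len(fam) == 1:
            alignments.append(
                AlignmentRecord(
                    query_id=fam[0], target_id=fam[0],
                    seq_identity=1.0, query_cov=1.0, target_cov=1.0, evalue=0.0,
                )
            )

    # --- rep-vs-member structural alignments (purity input) ---------------
    rep_member_alignments: list[AlignmentRecord] = []
    for fam in families:
        rep = fam[0]
        for member in fam[1:]:
            rep_member_alignments.append(
                AlignmentRecord(
                    query_id=rep, target_id=member,
                    seq_identity=float(rng.uniform(lo_w, hi_w)),
                    query_cov=float(rng.uniform(0.9, 1.0)),
                    target_cov=float(rng.uniform(0.9, 1.0)),
                    evalue=float(10 ** -rng.uniform(5, 50)),
                    tm_score=float(rng.uniform(0.82, 1.0)),
                    lddt=float(rng.uniform(0.85, 1.0)),
                )
            )

    # --- products with exact hypothetical fraction -------------------------
    hypothetical_ids = _exact_subset(rng, list(all_ids), spec.frac_hypothetical)
    products = []
    vocab_names = [v[0] for v in VOCABULARY]
    for pid in all_ids:
        if pid in hypothetical_ids:
            product = "hypothetical protein"
        else:
            product = vocab_names[int(rng.integers(len(vocab_names)))]
        products.append(ProductAnnotation(pid, product, source="sequence"))

    # --- representative hits with exact hit and void fractions ------------
    taxonomy, leaves = _build_taxonomy(spec)
    reps_with_hits = sorted(_exact_subset(rng, list(reps), spec.frac_reps_with_hits))
    void_reps = _exact_subset(rng, list(reps_with_hits), spec.frac_void_hits)
    # exact superkingdom allocation over hit-bearing reps
    sk_counts = _exact_allocation(len(reps_with_hits), spec.superkingdom_weights)
    sk_of_rep: dict[str, str] = {}
    shuffled = list(reps_with_hits)
    rng.shuffle(shuffled)
    pos = 0
    for sk, count in zip(SUPERKINGDOMS, sk_counts):
        for rep in shuffled[pos:pos + count]:
            sk_of_rep[rep] = sk
        pos += count

    synonym_variant = dict(VOCABULARY)
    hit_table: list[AlignmentRecord] = []
    dbs = ("PDB", "AFDB_SwissProt", "AFDB")
    for rep in reps_with_hits:
        sk = sk_of_rep[rep]
        n_rows = int(rng.integers(1, 4))
        if rep in void_reps:
            names = [VOID_NAMES[int(rng.integers(len(VOID_NAMES)))] for _ in range(n_rows)]
        else:
            base = vocab_names[int(rng.integers(len(vocab_names)))]
            # top row carries the synonym variant of an informative name
            names = [synonym_variant[base]] + [
                vocab_names[int(rng.integers(len(vocab_names)))]
                for _ in range(n_rows - 1)
            ]
        tms = sorted((float(rng.uniform(0.55, 0.95)) for _ in range(n_rows)), reverse=True)
        for k in range(n_rows):
            leaf_pool = leaves[sk]
            hit_table.append(
                AlignmentRecord(
                    query_id=rep,
                    target_id=f"T_{rep}_{k}",
                    seq_identity=float(rng.uniform(0.1, 0.6)),
                    query_cov=float(rng.uniform(0.85, 1.0)),
                    target_cov=float(rng.uniform(0.85, 1.0)),
                    evalue=float(10 ** -rng.uniform(3, 30)),
                    tm_score=tms[k],
                    lddt=float(rng.uniform(0.6, 1.0)),
                    target_name=names[k],
                    target_db=dbs[int(rng.integers(len(dbs)))],
                    target_taxid=int(leaf_pool[int(rng.integers(len(leaf_pool)))]),
                )
            )

    # --- labels with planted agreement probability pi ----------------------
    labels: list[FunctionalLabels] = []
    deviant_counter = 0
    canonical_draws = rng.random(len(all_ids))
    idx = 0
    for fi, fam in enumerate(families):
        canon_pfam = frozenset({f"PF{10000 + fi}"})
        canon_ec = (str(1 + fi % 6), str(1 + fi % 9), str(1 + fi % 20), str(1 + fi))
        for pid in fam:
            if canonical_draws[idx] < spec.label_agreement_pi:
                labels.append(FunctionalLabels(pid, canon_pfam, (canon_ec,)))
            else:
                deviant_counter += 1
                dev_pfam = frozenset({f"PF{90000 + deviant_counter}"})
                dev_ec = (str(100 + deviant_counter), "1", "1", "1")
                labels.append(FunctionalLabels(pid, dev_pfam, (dev_ec,)))
            idx += 1

    # --- pLDDT models for representatives ----------------------------------
    mean, sd = spec.plddt_mean_sd
    models = []
    for rep in reps:
        length = int(rng.integers(50, 200))
        track = np.clip(rng.normal(mean, sd, size=length), 0.0, 100.0)
        models.append(StructureModel(rep, tuple(float(round(v, 2)) for v in track)))

    # --- phages -------------------------------------------------------------
    group_letters = [chr(ord("A") + i % 8) for i in range(spec.n_phages)]
    metadata = [
        PhageMetadata(
            phage_id=f"PHG{i:03d}",
            group=group_letters[i],
            lifestyle="temperate" if i % 2 == 0 else "lytic",
        )
        for i in range(spec.n_phages)
    ]
    phage_ids = [m.phage_id for m in metadata]
    protein_to_phage = {
        pid: phage_ids[int(rng.integers(spec.n_phages))] for pid in all_ids
    }

    # --- interactions -------------------------------------------------------
    phage_side = [reps[int(rng.integers(len(reps)))] for _ in range(spec.n_interactions)]
    host_side = [f"H{int(rng.integers(spec.n_hosts)):03d}" for _ in range(spec.n_interactions)]
    true_idx = _exact_subset(rng, list(range(spec.n_interactions)), spec.frac_true_pairs)
    interactions = []
    for i in range(spec.n_interactions):
        if i in true_idx:
            iptm = float(rng.uniform(*spec.positive_iptm_range))
            ptm = float(rng.uniform(*spec.positive_ptm_range))
        else:
            iptm = float(rng.uniform(*spec.negative_iptm_range))
            ptm = float(rng.uniform(*spec.negative_ptm_range))
        interactions.append(InteractionRecord(phage_side[i], host_side[i], iptm, ptm))

    synonym_groups = [[a, b] for a, b in VOCABULARY]

    n_all = len(all_ids)
    size_of = {fam[0]: len(fam) for fam in families}
    n_match = sum(size_of[r] for r in reps_with_hits)
    n_void = sum(size_of[r] for r in void_reps)
    ground_truth = {
        "n_proteins": n_all,
        "n_families": spec.n_families,
        "family_sizes": sizes,
        "n_hypothetical": len(hypothetical_ids),
        "sequence_rate": (n_all - len(hypothetical_ids)) / n_all,
        "n_match": n_match,
        "n_void": n_void,
        "structure_rate": (n_match - n_void) / n_all,
        "reps_with_hits": list(reps_with_hits),
        "void_reps": sorted(void_reps),
        "superkingdom_counts": dict(zip(SUPERKINGDOMS, sk_counts)),
        "n_true_pairs": len(true_idx),
        "label_agreement_pi": spec.label_agreement_pi,
    }

    return FixtureBundle(
        spec=spec,
        sequences=sequences,
        alignments=alignments,
        rep_member_alignments=rep_member_alignments,
        hit_table=hit_table,
        planted_clustering=planted,
        products=products,
        labels=labels,
        models=models,
        taxonomy=taxonomy,
        interactions=interactions,
        metadata=metadata,
        protein_to_phage=protein_to_phage,
        synonym_groups=synonym_groups,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# Analytic expectations


def _p_weighted_sum_above(
    threshold: float,
    iptm_range: tuple[float, float],
    ptm_range: tuple[float, float],
) -> float:
    """Exact P(0.8 X + 0.2 Y > t) for independent uniform X, Y."""
    from scipy.integrate import quad

    a, b = iptm_range
    c, d = ptm_range

    def inner(x: float) -> float:
        y_min = (threshold - 0.8 * x) / 0.2
        if y_min <= c:
            return 1.0
        if y_min >= d:
            return 0.0
        return (d - y_min) / (d - c)

    val, _err = quad(inner, a, b, limit=200)
    return val / (b - a)


def consistency_interval(
    family_sizes: list[int],
    pi: float,
    n_rep: int = 4000,
    seed: int = 0,
    coverage: float = 0.99,
) -> tuple[float, float]:
    """Monte-Carlo interval for the mean per-cluster label consistency.

    Each cluster of size m >= 2 contributes C(C-1)/(m(m-1)) with
    C ~ Binomial(m, pi); singleton families never enter (no pairs).
    """
    rng = np.random.default_rng(seed)
    sizes = np.array([m for m in family_sizes if m >= 2])
    if sizes.size == 0:
        raise ValueError("no families with >= 2 members")
    means = np.empty(n_rep)
    for r in range(n_rep):
        c = rng.binomial(sizes, pi)
        scores = c * (c - 1) / (sizes * (sizes - 1))
        means[r] = scores.mean()
    alpha = (1.0 - coverage) / 2.0
    return (float(np.quantile(means, alpha)), float(np.quantile(means, 1.0 - alpha)))


def expected_values(spec: FixtureSpec, bundle: Optional[FixtureBundle] = None) -> dict:
    """Closed-form (or planted-exact) expectations for every downstream
    statistic, with Monte-Carlo intervals where the statistic is random."""
    if bundle is None:
        bundle = generate(spec)
    gt = bundle.ground_truth
    n = gt["n_proteins"]

    p_pos = _p_weighted_sum_above(0.5, spec.positive_iptm_range, spec.positive_ptm_range)
    p_neg = _p_weighted_sum_above(0.5, spec.negative_iptm_range, spec.negative_ptm_range)
    n_true = gt["n_true_pairs"]
    n_false = spec.n_interactions - n_true
    exp_screened = n_true * p_pos + n_false * p_neg
    sd_screened = math.sqrt(
        n_true * p_pos * (1 - p_pos) + n_false * p_neg * (1 - p_neg)
    )

    pi = spec.label_agreement_pi
    lo, hi = consistency_interval(
        gt["family_sizes"], pi, seed=(spec.seed + 7919) % (2**31)
    )
    total_sk = sum(gt["superkingdom_counts"].values())
    return {
        "sequence_rate": gt["sequence_rate"],
        "structure_rate": gt["structure_rate"],
        "n_clusters": spec.n_families,
        "mean_consistency": pi * pi,
        "mean_consistency_interval_99": (lo, hi),
        "superkingdom_percentages": {
            sk: 100.0 * c / total_sk for sk, c in gt["superkingdom_counts"].items()
        },
        "expected_screened_count": exp_screened,
        "screened_count_sd": sd_screened,
        "mean_plddt": spec.plddt_mean_sd[0],
    }


# ---------------------------------------------------------------------------
# Emit every file dialect the pipeline consumes


def write_bundle(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write the bundle as the on-disk corpus the CLI pipeline reads."""
    from . import io as scsh_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "proteins.fasta"
    scsh_io.write_fasta(bundle.sequences, paths["fasta"])

    paths["alignments"] = outdir / "seq_alignments.tsv"
    scsh_io.write_alignment_table(bundle.alignments, paths["alignments"])

    paths["rep_member"] = outdir / "rep_member_struct.tsv"
    scsh_io.write_alignment_table(bundle.rep_member_alignments, paths["rep_member"])

    paths["hits"] = outdir / "structure_hits.tsv"
    scsh_io.write_alignment_table(bundle.hit_table, paths["hits"])

    paths["planted_clusters"] = outdir / "planted_clusters.tsv"
    scsh_io.write_cluster_tsv(bundle.planted_clustering, paths["planted_clusters"])

    paths["gff"] = outdir / "products.gff3"
    _write_products_gff(bundle, paths["gff"])

    paths["labels"] = outdir / "labels.tsv"
    scsh_io.write_labels_tsv(bundle.labels, paths["labels"])

    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    for model in bundle.models:
        _write_plddt_pdb(model, models_dir / f"{model.model_id}.pdb")
    paths["models_dir"] = models_dir

    paths["nodes"] = outdir / "nodes.dmp"
    paths["names"] = outdir / "names.dmp"
    scsh_io.write_taxdump(bundle.taxonomy, paths["nodes"], paths["names"])

    paths["interactions"] = outdir / "interactions.tsv"
    scsh_io.write_tsv(
        [
            (r.phage_protein_id, r.host_protein_id, f"{r.iptm:.4f}", f"{r.ptm:.4f}")
            for r in bundle.interactions
        ],
        paths["interactions"],
        header=("phage_protein_id", "host_protein_id", "iptm", "ptm"),
    )

    paths["metadata"] = outdir / "phage_metadata.tsv"
    scsh_io.write_tsv(
        [(m.phage_id, m.group, m.lifestyle) for m in bundle.metadata],
        paths["metadata"],
        header=("phage_id", "group", "lifestyle"),
    )

    paths["protein_phage"] = outdir / "protein_phage.tsv"
    scsh_io.write_tsv(
        sorted(bundle.protein_to_phage.items()),
        paths["protein_phage"],
        header=("protein_id", "phage_id"),
    )

    paths["synonyms"] = outdir / "synonyms.yaml"
    import yaml

    with open(paths["synonyms"], "w", encoding="utf-8") as fh:
        yaml.safe_dump({"synonym_groups": bundle.synonym_groups}, fh, sort_keys=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)

    paths["spec"] = outdir / "fixture_spec.json"
    with open(paths["spec"], "w", encoding="utf-8") as fh:
        json.dump(asdict(bundle.spec), fh, indent=1, sort_keys=True)
    return paths


def _write_products_gff(bundle: FixtureBundle, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        pos: dict[str, int] = {}
        for i, prod in enumerate(bundle.products):
            phage = bundle.protein_to_phage[prod.protein_id]
            start = pos.get(phage, 1)
            end = start + 299
            pos[phage] = end + 1
            attrs = f"ID={prod.protein_id}"
            if prod.product:
                attrs += f";product={prod.product}"
            fh.write(
                f"{phage}\tsynthetic\tCDS\t{start}\t{end}\t.\t+\t0\t{attrs}\n"
            )


def _write_plddt_pdb(model: StructureModel, path: Path) -> None:
    """Minimal CA-trace PDB whose B-factor column carries pLDDT."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, plddt in enumerate(model.per_residue_plddt, start=1):
            x = float(i) * 3.8
            fh.write(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{plddt:6.2f}"
                f"           C\n"
            )
        fh.write("END\n")
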