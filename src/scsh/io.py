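"""Readers and writers for every external artifact the pipeline touches.

All parsers normalise dialect quirks (Foldseek column orders, MMseqs2
cluster TSVs, NCBI taxdump pipes, URL-encoded GFF attributes) into the
domain types in :mod:`scsh.types`.  Everything is UTF-8 and
locale-independent: decimal points only, scientific notation accepted for
E-values.
"""

from __future__ import annotations

import csv
import logging
import urllib.parse
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .types import (
    TARGET_DBS,
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

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a protein FASTA into :class:`SequenceRecord` objects.

    Residues are upper-cased; duplicate ids are rejected.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: expected FASTA header '>' as first record line"
                )
            break
        else:
            raise ParseError(f"{path}:1: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                protein_id=rec.id,
                description=rec.description,
                residues=str(rec.seq).upper(),
            )
        )
    if not records:
        raise ParseError(f"{path}:1: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            header = r.description if r.description.startswith(r.protein_id) else (
                f"{r.protein_id} {r.description}".strip()
            )
            fh.write(f">{header}\n{r.residues}\n")


# ---------------------------------------------------------------------------
# Alignment tables (Foldseek/MMseqs2 tabular output)

#: Column order of ``--format-output
#: query,target,fident,qcov,tcov,evalue,alntmscore,lddt,theader,taxid``.
DEFAULT_COLUMN_MAP: dict[str, int] = {
    "query_id": 0,
    "target_id": 1,
    "seq_identity": 2,
    "query_cov": 3,
    "target_cov": 4,
    "evalue": 5,
    "tm_score": 6,
    "lddt": 7,
    "target_name": 8,
    "target_taxid": 9,
    "target_db": 10,  # extension column; absent in stock Foldseek output
}

_REQUIRED_FIELDS = ("query_id", "target_id", "seq_identity", "query_cov",
                    "target_cov", "evalue")
_FRACTIONAL_FIELDS = ("seq_identity", "query_cov", "target_cov", "tm_score", "lddt")


def read_alignment_table(
    path: PathLike,
    column_map: Optional[Mapping[str, int]] = None,
    target_db: str = "other",
) -> list[AlignmentRecord]:
    """Read a tab-separated alignment file into :class:`AlignmentRecord` rows.

    ``column_map`` maps field names to 0-based column indices; fields left
    unmapped (or mapped past a short row's end) become absent.  ``target_db``
    tags every record unless a ``target_db`` column is mapped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    missing = [f for f in _REQUIRED_FIELDS if f not in cmap]
    if missing:
        raise ParseError(f"column_map lacks required fields: {missing}")

    records: list[AlignmentRecord] = []
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for row_idx, line in enumerate(fh):
            line = line.rstrip("\n")
            if line == "" or line.startswith("#"):
                continue
            cols = line.split("\t")

            def get(field: str) -> Optional[str]:
                i = cmap.get(field)
                if i is None or i >= len(cols) or cols[i] == "":
                    return None
                return cols[i]

            try:
                values: dict[str, object] = {}
                for f in _REQUIRED_FIELDS:
                    raw = get(f)
                    if raw is None:
                        raise ParseError(f"missing required field {f!r}")
                    values[f] = raw if f in ("query_id", "target_id") else float(raw)
                for f in ("tm_score", "lddt"):
                    raw = get(f)
                    values[f] = None if raw is None else float(raw)
                raw = get("target_taxid")
                values["target_taxid"] = None if raw is None else int(raw)
                values["target_name"] = get("target_name")
                db = get("target_db") or target_db
                if db not in TARGET_DBS:
                    db = "other"
                values["target_db"] = db
                for f in _FRACTIONAL_FIELDS:
                    v = values[f]
                    if v is not None and not (0.0 <= float(v) <= 1.0):  # type: ignore[arg-type]
                        raise ParseError(f"{f} = {v} outside [0, 1]")
                records.append(AlignmentRecord(**values))  # type: ignore[arg-type]
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}: row {row_idx}: {exc}") from exc
    return records


def write_alignment_table(
    records: Iterable[AlignmentRecord], path: PathLike
) -> None:
    """Write records in the default Foldseek-style column order."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.target_id,
                        f"{r.seq_identity:.4f}",
                        f"{r.query_cov:.4f}",
                        f"{r.target_cov:.4f}",
                        f"{r.evalue:.3e}",
                        "" if r.tm_score is None else f"{r.tm_score:.4f}",
                        "" if r.lddt is None else f"{r.lddt:.4f}",
                        r.target_name or "",
                        "" if r.target_taxid is None else str(r.target_taxid),
                        r.target_db,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Cluster TSV (MMseqs2/Foldseek dialect: representative TAB member)


def read_cluster_tsv(path: PathLike, provenance: str = "sequence") -> Clustering:
    """Read a two-column (representative, member) TSV into a partition.

    The representative is conventionally listed as its own member; it is
    added if the file omits that row.  A member under two representatives
    violates the partition property and raises :class:`ParseError`.
    """
    clusters: dict[str, set[str]] = {}
    owner: dict[str, str] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            rep, member = parts
            if member in owner and owner[member] != rep:
                raise ParseError(
                    f"{path}:{lineno}: member {member!r} listed under both "
                    f"{owner[member]!r} and {rep!r} (not a partition)"
                )
            owner[member] = rep
            clusters.setdefault(rep, set()).add(member)
    for rep in clusters:
        if rep in owner and owner[rep] != rep:
            raise ParseError(
                f"{path}: representative {rep!r} is also a member of {owner[rep]!r}"
            )
        clusters[rep].add(rep)
    return Clustering(clusters, provenance=provenance)


def write_cluster_tsv(clustering: Clustering, path: PathLike) -> None:
    """Write the MMseqs2-style two-column TSV, representatives first."""
    with open(path, "w", encoding="utf-8") as fh:
        for rep in sorted(clustering.clusters):
            members = clustering.clusters[rep]
            fh.write(f"{rep}\t{rep}\n")
            for m in sorted(members - {rep}):
                fh.write(f"{rep}\t{m}\n")


# ---------------------------------------------------------------------------
# Model coordinates -> per-residue pLDDT


def read_plddt(path: PathLike) -> StructureModel:
    """Extract the per-residue pLDDT track from a PDB/mmCIF model.

    Predicted models store pLDDT in the B-factor column.  One value is taken
    per residue, from the CA atom when present, else the residue's first
    atom.  Values outside [0, 100] are clamped with a logged warning.
    """
    import gemmi

    path = Path(path)
    structure = gemmi.read_structure(str(path))
    values: list[float] = []
    model_id = structure.name or path.stem
    for model in structure:
        for chain in model:
            for residue in chain:
                atom = residue.find_atom("CA", "*")
                if atom is None:
                    if len(residue) == 0:
                        continue
                    atom = residue[0]
                b = atom.b_iso
                if not (0.0 <= b <= 100.0):
                    clamped = min(max(b, 0.0), 100.0)
                    log.warning(
                        "%s: residue %s B-factor %.2f outside [0, 100]; clamped to %.2f",
                        path, residue.seqid, b, clamped,
                    )
                    b = clamped
                values.append(b)
        break  # first model only
    if not values:
        raise ParseError(f"{path}: no residues with atoms found")
    return StructureModel(model_id=model_id, per_residue_plddt=tuple(values))


# ---------------------------------------------------------------------------
# GFF3 products


def read_products_from_gff(path: PathLike) -> list[ProductAnnotation]:
    """Extract (protein id, product) pairs from the CDS features of a GFF3.

    Coordinates are ignored; only the identity->product mapping matters.
    The id is the CDS ``ID`` attribute, falling back to ``locus_tag``.
    Attribute values are URL-decoded.  A CDS without a ``product``
    attribute yields an empty product (counted as unannotated downstream).
    """
    import gffutils

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []  # a feature-less GFF3 is valid and yields no products
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises various internal errors
        raise ParseError(f"{path}: failed to parse GFF3: {exc}") from exc

    annotations: list[ProductAnnotation] = []
    for feature in db.features_of_type("CDS", order_by=("seqid", "start")):
        attrs = feature.attributes
        ids = attrs.get("ID") or attrs.get("locus_tag")
        if not ids:
            raise ParseError(
                f"{path}: CDS at line with start {feature.start} lacks ID/locus_tag"
            )
        protein_id = urllib.parse.unquote(ids[0])
        products = attrs.get("product")
        product = urllib.parse.unquote(products[0]) if products else ""
        annotations.append(
            ProductAnnotation(protein_id=protein_id, product=product, source="sequence")
        )
    return annotations


# ---------------------------------------------------------------------------
# NCBI taxdump


def _split_dmp(line: str) -> list[str]:
    # taxdump rows are "field\t|\tfield\t|\t...\t|\n"
    return [f.strip() for f in line.rstrip("\n").rstrip("|").split("\t|")]


def read_taxdump(nodes_path: PathLike, names_path: PathLike) -> TaxonomyTree:
    """Read pipe-delimited ``nodes.dmp``/``names.dmp`` into a validated tree.

    Only scientific names are kept.  Exactly one self-parented root is
    required; cycles and orphan parents are structural errors.
    """
    names: dict[int, str] = {}
    with open(names_path, encoding="utf-8") as fh:
        for line in fh:
            fields = _split_dmp(line)
            if len(fields) < 4:
                continue
            taxid, name, _unique, name_class = fields[:4]
            if name_class == "scientific name":
                names[int(taxid)] = name

    nodes: dict[int, tuple[int, str, str]] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise ParseError(f"{nodes_path}:{lineno}: expected >= 3 fields")
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            nodes[taxid] = (parent, rank, names.get(taxid, f"taxid:{taxid}"))
    try:
        return TaxonomyTree(nodes)
    except ValueError as exc:
        raise ParseError(f"{nodes_path}: {exc}") from exc


def write_taxdump(tree: TaxonomyTree, nodes_path: PathLike, names_path: PathLike) -> None:
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for taxid in sorted(tree.nodes):
            parent, rank, _name = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for taxid in sorted(tree.nodes):
            _parent, _rank, name = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")


# ---------------------------------------------------------------------------
# Simple TSV tables: interactions, phage metadata, labels, protein->phage


def read_interactions_tsv(path: PathLike) -> list[InteractionRecord]:
    """Read (phage_protein_id, host_protein_id, iptm, ptm) rows; a header
    line starting with 'phage' is skipped."""
    out: list[InteractionRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row_idx, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            if row_idx == 0 and row[0].lower().startswith("phage"):
                continue
            try:
                out.append(
                    InteractionRecord(row[0], row[1], float(row[2]), float(row[3]))
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: row {row_idx}: {exc}") from exc
    return out


def read_phage_metadata(path: PathLike) -> list[PhageMetadata]:
    """Read (phage_id, group, lifestyle) rows; header starting with 'phage'
    is skipped."""
    out: list[PhageMetadata] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row_idx, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            if row_idx == 0 and row[0].lower() == "phage_id":
                continue
            try:
                out.append(PhageMetadata(row[0], row[1], row[2] if len(row) > 2 else "unknown"))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: row {row_idx}: {exc}") from exc
    return out


def read_protein_to_phage(path: PathLike) -> dict[str, str]:
    """Read a two-column (protein_id, phage_id) TSV mapping."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row_idx, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: row {row_idx}: expected 2 columns")
            mapping[row[0]] = row[1]
    return mapping


def read_labels_tsv(path: PathLike) -> list[FunctionalLabels]:
    """Read (protein_id, comma-separated Pfam accessions, comma-separated EC
    numbers) rows.  Empty fields are allowed."""
    out: list[FunctionalLabels] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row_idx, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            try:
                pfams = frozenset(
                    p for p in (row[1].split(",") if len(row) > 1 and row[1] else []) if p
                )
                ecs = tuple(
                    FunctionalLabels.parse_ec(e)
                    for e in (row[2].split(",") if len(row) > 2 and row[2] else [])
                    if e
                )
                out.append(FunctionalLabels(row[0], pfams, ecs))
            except ValueError as exc:
                raise ParseError(f"{path}: row {row_idx}: {exc}") from exc
    return out


def write_labels_tsv(labels: Iterable[FunctionalLabels], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tpfam\tec\n")
        for lab in labels:
            pf = ",".join(sorted(lab.pfam_accessions))
            ec = ",".join(".".join(code) for code in lab.ec_numbers)
            fh.write(f"{lab.protein_id}\t{pf}\t{ec}\n")


def write_tsv(rows: Sequence[Sequence[object]], path: PathLike,
              header: Optional[Sequence[str]] = None) -> None:
    """Write generic rows as a TSV (used by report exporters)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header:
            writer.writerow(header)
        writer.writerows(rows)
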