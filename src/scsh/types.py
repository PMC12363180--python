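"""Domain types shared across the SCSH pipeline.

The workflow annotates phage proteomes in three steps: cluster proteins by
pairwise sequence similarity, predict/search structures for each cluster
representative, and transfer the representative's best structural hit to all
cluster members.  Every stage exchanges the small value types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "SequenceRecord",
    "AlignmentRecord",
    "StructureModel",
    "ProductAnnotation",
    "FunctionalLabels",
    "TaxonomyTree",
    "PhageMetadata",
    "InteractionRecord",
    "Clustering",
    "SimilarityGraph",
    "BestHit",
    "AnnotationTally",
    "ClusterPurity",
    "ConsistencyScore",
    "LcaResult",
    "ScoredInteraction",
    "TARGET_DBS",
]

#: Recognised structural-database tags, in tie-breaking precedence order.
TARGET_DBS = ("PDB", "AFDB_SwissProt", "AFDB", "counter_defense", "other")

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


def _check_fraction(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: stable id, free-text description, residues."""

    protein_id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be nonempty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.protein_id}: empty residue string")
        bad = set(self.residues.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: unexpected residue letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class AlignmentRecord:
    """A pairwise sequence-or-structure alignment row.

    Fractional fields (identity, coverages, TM-score, LDDT) live in [0, 1].
    Structure-only fields are ``None`` for plain sequence alignments.
    """

    query_id: str
    target_id: str
    seq_identity: float
    query_cov: float
    target_cov: float
    evalue: float
    tm_score: Optional[float] = None
    lddt: Optional[float] = None
    target_name: Optional[str] = None
    target_db: str = "other"
    target_taxid: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.query_id or not self.target_id:
            raise ValueError("query_id and target_id must be nonempty")
        for name in ("seq_identity", "query_cov", "target_cov", "tm_score", "lddt"):
            _check_fraction(name, getattr(self, name))
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue!r}")
        if self.target_db not in TARGET_DBS:
            raise ValueError(f"unknown target_db tag {self.target_db!r}")


@dataclass(frozen=True)
class StructureModel:
    """A predicted model reduced to its per-residue pLDDT track (0-100)."""

    model_id: str
    per_residue_plddt: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.per_residue_plddt) == 0:
            raise ValueError(f"{self.model_id}: model has no residues")
        for v in self.per_residue_plddt:
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.model_id}: pLDDT {v!r} outside [0, 100]")


@dataclass(frozen=True)
class ProductAnnotation:
    """A free-text functional annotation attached to one protein.

    ``source`` distinguishes the GenBank/GFF ``product=`` field (``sequence``)
    from names transferred off a representative's structural hit
    (``structure_transfer``).
    """

    protein_id: str
    product: str
    source: str = "sequence"

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be nonempty")
        if self.source not in ("sequence", "structure_transfer"):
            raise ValueError(f"unknown annotation source {self.source!r}")


@dataclass(frozen=True)
class FunctionalLabels:
    """Per-protein Pfam accessions and EC numbers.

    EC numbers are stored as 4-tuples of tokens; ``-`` marks an unspecified
    hierarchical level (e.g. ``("3", "6", "1", "-")``).
    """

    protein_id: str
    pfam_accessions: frozenset[str] = frozenset()
    ec_numbers: tuple[tuple[str, str, str, str], ...] = ()

    def __post_init__(self) -> None:
        for code in self.ec_numbers:
            if len(code) != 4:
                raise ValueError(
                    f"{self.protein_id}: EC code {code!r} does not have 4 tokens"
                )

    @staticmethod
    def parse_ec(text: str) -> tuple[str, str, str, str]:
        """Parse ``'3.6.1.-'`` into its 4 tokens, validating arity."""
        tokens = tuple(t.strip() for t in text.strip().split("."))
        if len(tokens) != 4 or any(t == "" for t in tokens):
            raise ValueError(f"EC code {text!r} must have exactly 4 dot-separated tokens")
        for t in tokens:
            if t != "-" and not t.isdigit():
                raise ValueError(f"EC token {t!r} in {text!r} is neither a number nor '-'")
        return tokens  # type: ignore[return-value]


class TaxonomyTree:
    """A rooted taxonomy: taxid -> (parent, rank, name), validated acyclic.

    The root is the unique node whose parent is itself (NCBI taxdump
    convention, taxid 1) or absent.
    """

    def __init__(self, nodes: dict[int, tuple[int, str, str]]):
        if not nodes:
            raise ValueError("taxonomy has no nodes")
        roots = [t for t, (p, _r, _n) in nodes.items() if p == t]
        orphans = [
            t for t, (p, _r, _n) in nodes.items() if p != t and p not in nodes
        ]
        if orphans:
            raise ValueError(f"nodes reference absent parents: taxids {sorted(orphans)}")
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found taxids {sorted(roots)}")
        self.nodes = dict(nodes)
        self.root = roots[0]
        self._check_acyclic()
        self._depth_cache: dict[int, int] = {self.root: 0}

    def _check_acyclic(self) -> None:
        seen_ok: set[int] = {self.root}
        for start in self.nodes:
            path = []
            t = start
            on_path = set()
            while t not in seen_ok:
                if t in on_path:
                    raise ValueError(f"taxonomy contains a cycle through taxid {t}")
                on_path.add(t)
                path.append(t)
                t = self.nodes[t][0]
            seen_ok.update(path)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid][0]

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid][1]

    def name(self, taxid: int) -> str:
        return self.nodes[taxid][2]

    def depth(self, taxid: int) -> int:
        """Root-path length (root has depth 0)."""
        stack = []
        t = taxid
        while t not in self._depth_cache:
            stack.append(t)
            t = self.nodes[t][0]
        d = self._depth_cache[t]
        for t in reversed(stack):
            d += 1
            self._depth_cache[t] = d
        return self._depth_cache[taxid]

    def root_path(self, taxid: int) -> list[int]:
        """Path from the root down to ``taxid`` inclusive."""
        if taxid not in self.nodes:
            raise KeyError(f"taxid {taxid} not in taxonomy")
        path = [taxid]
        t = taxid
        while t != self.root:
            t = self.nodes[t][0]
            path.append(t)
        return path[::-1]

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """The ancestor-or-self of ``taxid`` carrying ``rank``, or None."""
        for t in reversed(self.root_path(taxid)):
            if self.nodes[t][1] == rank:
                return t
        return None


@dataclass(frozen=True)
class PhageMetadata:
    """Genome-level phage record: nucleotide-similarity group and lifestyle.

    The group letter (A, B, ... or 'singleton') is the classic phage-cluster
    label and is distinct from the protein clusters this package builds.
    """

    phage_id: str
    group: str
    lifestyle: str = "unknown"

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError(f"{self.phage_id}: group must be nonempty")
        if self.lifestyle not in ("temperate", "lytic", "unknown"):
            raise ValueError(f"{self.phage_id}: unknown lifestyle {self.lifestyle!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """One phage-host protein pair with multimer confidence scores."""

    phage_protein_id: str
    host_protein_id: str
    iptm: float
    ptm: float

    def __post_init__(self) -> None:
        _check_fraction("iptm", self.iptm)
        _check_fraction("ptm", self.ptm)


class SimilarityGraph:
    """Undirected graph over protein ids; an edge means the pair passed the
    identity/coverage thresholds.  Self-edges are never stored (every node is
    trivially similar to itself)."""

    def __init__(self, node_ids: set[str] | frozenset[str] = frozenset(),
                 edges: set[frozenset[str]] | None = None):
        self.node_ids: set[str] = set(node_ids)
        self.adj: dict[str, set[str]] = {n: set() for n in self.node_ids}
        for e in edges or ():
            a, b = tuple(e)
            self.add_edge(a, b)

    def add_node(self, n: str) -> None:
        self.node_ids.add(n)
        self.adj.setdefault(n, set())

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            return
        for n in (a, b):
            self.add_node(n)
        self.adj[a].add(b)
        self.adj[b].add(a)

    def has_edge(self, a: str, b: str) -> bool:
        return b in self.adj.get(a, ())

    def neighbors(self, n: str) -> set[str]:
        return self.adj.get(n, set())

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, nbrs in self.adj.items() for b in nbrs}

    def __len__(self) -> int:
        return len(self.node_ids)


class Clustering:
    """A partition of protein ids into clusters, each with a representative.

    Invariants enforced on construction: member sets are disjoint, and each
    representative is a member of its own cluster.
    """

    def __init__(self, clusters: dict[str, set[str]], provenance: str = "sequence"):
        seen: set[str] = set()
        for rep, members in clusters.items():
            if rep not in members:
                raise ValueError(f"representative {rep!r} not in its own member set")
            overlap = seen & members
            if overlap:
                raise ValueError(
                    f"not a partition: ids in multiple clusters: {sorted(overlap)}"
                )
            seen |= members
        self.clusters: dict[str, set[str]] = {r: set(m) for r, m in clusters.items()}
        self.provenance = provenance

    @property
    def members(self) -> set[str]:
        return {m for ms in self.clusters.values() for m in ms}

    def representative_of(self, protein_id: str) -> str:
        for rep, members in self.clusters.items():
            if protein_id in members:
                return rep
        raise KeyError(protein_id)

    def member_to_rep(self) -> dict[str, str]:
        return {m: r for r, ms in self.clusters.items() for m in ms}

    def __len__(self) -> int:
        return len(self.clusters)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clustering):
            return NotImplemented
        return self.clusters == other.clusters

    def sizes(self) -> dict[str, int]:
        return {r: len(ms) for r, ms in self.clusters.items()}


@dataclass(frozen=True)
class BestHit:
    """The winning structural hit for one query after threshold filtering."""

    query_id: str
    target_id: str
    target_name: Optional[str]
    target_db: str
    tm_score: float
    evalue: float


@dataclass
class AnnotationTally:
    """Counters feeding the two annotation-rate formulas.

    sequence rate  = (n_all - n_unannotated) / n_all
    structure rate = (n_match - n_void) / n_all
    """

    n_all: int
    n_unannotated: int = 0
    n_match: int = 0
    n_void: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_unannotated <= self.n_all):
            raise ValueError("need 0 <= n_unannotated <= n_all")
        if not (0 <= self.n_void <= self.n_match <= self.n_all):
            raise ValueError("need 0 <= n_void <= n_match <= n_all")


@dataclass(frozen=True)
class ClusterPurity:
    """Mean structural similarity of a cluster's members to its representative."""

    representative_id: str
    mean_lddt: float
    mean_tm: float
    n_members_aligned: int


@dataclass(frozen=True)
class ConsistencyScore:
    """Label-agreement score of one cluster (Pfam or one EC level)."""

    representative_id: str
    label_kind: str  # "pfam" or "ec_level_1".."ec_level_4"
    score: float
    n_annotated_members: int


@dataclass(frozen=True)
class LcaResult:
    """Lowest common ancestor of all qualifying hits of one query."""

    query_id: str
    lca_taxid: int
    lca_rank: str
    lca_name: str
    n_hits: int


@dataclass(frozen=True)
class ScoredInteraction:
    """An interaction record with its combined confidence 0.8*ipTM + 0.2*pTM."""

    phage_protein_id: str
    host_protein_id: str
    iptm: float
    ptm: float
    score: float

    def __post_init__(self) -> None:
        expected = 0.8 * self.iptm + 0.2 * self.ptm
        if abs(self.score - expected) > 1e-12:
            raise ValueError(
                f"score {self.score!r} != 0.8*iptm + 0.2*ptm = {expected!r}"
            )
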