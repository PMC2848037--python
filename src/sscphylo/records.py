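"""Core domain types shared across the pipeline.

The pipeline moves sequence records, alignments, BLAST hits and per-gene
annotation between stages.  Everything here is a plain dataclass with
eager validation: invalid objects cannot be constructed, so downstream
code never re-checks invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "SOURCE_TYPES",
    "SOURCE_PREFERENCE",
    "GO_NAMESPACES",
    "SequenceRecord",
    "Alignment",
    "BlastHit",
    "TaxonMetadata",
    "AnnotationRecord",
    "ValidationError",
    "FormatError",
]

# IUPAC nucleotide codes, gap and the supermatrix missing symbol.
NUC_ALPHABET = frozenset("ACGTURYSWKMBDHVN-?")
# Amino acids incl. ambiguity (B, Z, X), stop (*), gap and missing.
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO*-?")

SOURCE_TYPES = ("genome", "transcript_assembly", "est_singleton", "finished_cdna")

#: Preference order used when discarding redundant identical sequences and
#: when choosing a supermatrix representative (lower rank = preferred).
SOURCE_PREFERENCE = {
    "transcript_assembly": 0,
    "finished_cdna": 1,
    "genome": 2,
    "est_singleton": 3,
}

GO_NAMESPACES = ("cellular_component", "molecular_function", "biological_process")


class ValidationError(ValueError):
    """An object violates a stated invariant."""


class FormatError(ValueError):
    """An external file cannot be parsed."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single (possibly aligned) sequence with its provenance.

    ``source_type`` matters for curation: identical sequences are
    de-duplicated with preference for transcript assemblies over EST
    singletons, and supermatrix representatives are chosen the same way.
    """

    id: str
    residues: str
    taxon: str = ""
    source_type: str = "est_singleton"
    molecule: str = "nucleotide"

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        if self.source_type not in SOURCE_TYPES:
            raise ValidationError(
                f"sequence {self.id!r}: unknown source_type {self.source_type!r}"
            )
        if self.molecule not in ("nucleotide", "protein"):
            raise ValidationError(
                f"sequence {self.id!r}: molecule must be nucleotide or protein"
            )
        if not self.taxon:
            object.__setattr__(self, "taxon", self.id)
        alphabet = NUC_ALPHABET if self.molecule == "nucleotide" else PROT_ALPHABET
        bad = set(self.residues.upper()) - alphabet
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: residues {sorted(bad)} not valid for "
                f"{self.molecule}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "").replace("?", "")

    def with_residues(self, residues: str) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=residues,
            taxon=self.taxon,
            source_type=self.source_type,
            molecule=self.molecule,
        )


class Alignment:
    """An ordered collection of equal-length sequence records.

    The gap character is ``-``; the supermatrix additionally uses ``?``
    for wholly missing gene blocks.  Column coordinates in logs and
    outputs are 1-based inclusive.
    """

    def __init__(self, records: Iterable[SequenceRecord]):
        # An empty alignment is permitted: curation can legitimately
        # remove every sequence, and callers are warned when it does.
        self.records: list[SequenceRecord] = list(records)
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValidationError(
                f"aligned records differ in length: {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence id(s): {', '.join(dup)}")

    @property
    def length(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, i: int) -> str:
        """Column ``i`` (0-based internal indexing)."""
        return "".join(r.residues[i] for r in self.records)

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        return Alignment(r for r in self.records if r.id in keep)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self.records == other.records

    def __repr__(self) -> str:
        return f"<Alignment {len(self)} x {self.length}>"


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular protein-vs-protein search output."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value"
            )
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: percent identity "
                f"{self.pct_identity} outside [0, 100]"
            )


@dataclass(frozen=True)
class TaxonMetadata:
    """Taxon-level metadata used by curation and presence counting."""

    taxon: str
    lineage_group: str = ""
    is_hybrid: bool = False

    def __post_init__(self):
        if not self.taxon:
            raise ValidationError("taxon label must be non-empty")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-gene functional and structural annotation.

    ``go_slim`` maps each of the three GO namespaces to a flat set of
    slim-category labels (no DAG propagation).
    """

    gene_id: str
    go_slim: Mapping[str, frozenset] = field(default_factory=dict)
    exon_count: int = 1
    domain_count: int = 0
    cdna_length: int = 0

    def __post_init__(self):
        bad_ns = set(self.go_slim) - set(GO_NAMESPACES)
        if bad_ns:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown GO namespace(s) {sorted(bad_ns)}"
            )
        object.__setattr__(
            self,
            "go_slim",
            {ns: frozenset(cats) for ns, cats in self.go_slim.items()},
        )
        if self.exon_count < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: exon_count must be >= 1"
            )
        if self.domain_count < 0 or self.cdna_length < 0:
            raise ValidationError(
                f"gene {self.gene_id!r}: counts must be non-negative"
            )
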