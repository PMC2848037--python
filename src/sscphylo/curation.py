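"""EST alignment curation and supermatrix assembly.

Curated nucleotide alignments are produced by threading coding sequence
onto a given protein alignment, applying six ordered sequence-elimination
criteria, and excising alignment columns gapped in exactly one sequence.
Gene trees screened for duplication events decide which genes enter the
concatenated multi-gene supermatrix; per-species representatives are
chosen by source preference, coverage and branch length.

Elimination criteria (applied in order):

1. the sequence is from a non-seed plant (fern, moss, alga, ...);
2. the sequence contains at least five ambiguous bases (N);
3. the sequence has low similarity to the rest of the alignment
   (quantified as ungapped identity to the column-majority consensus
   below a configurable threshold, 50% by default);
4. 50 or more aligned bp are missing from the 5' or 3' end of the
   alignment (the alignment span is anchored by the start codon at the
   5' end and the stop codon at the 3' end);
5. the sequence is identical to another (transcript assemblies are
   preferred over EST singletons when discarding);
6. the sequence is from a hybrid taxon.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import dendropy
import numpy as np

from .records import (
    Alignment,
    SOURCE_PREFERENCE,
    SequenceRecord,
    TaxonMetadata,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CurationCriteria",
    "RemovalLog",
    "RemovalEntry",
    "DuplicationEvent",
    "SupermatrixSpec",
    "AlignmentStats",
    "backtranslate_alignment",
    "filter_sequences",
    "strip_private_gap_columns",
    "detect_duplications",
    "select_supermatrix",
    "alignment_stats",
]

#: Lineage-group labels treated as non-seed plants (criterion 1).
NON_SEED_GROUPS = frozenset(
    {"Green Algae", "Mosses", "Liverworts", "Hornworts", "Ferns", "Lycophytes",
     "Charophytes", "Non-seed Plants"}
)

DEFAULT_DEDUP_PREFERENCE = (
    "transcript_assembly",
    "finished_cdna",
    "genome",
    "est_singleton",
)


@dataclass(frozen=True)
class CurationCriteria:
    max_ambiguous: int = 5
    end_trunc_bp: int = 50
    min_similarity_pct: float = 50.0
    drop_non_seed: bool = True
    drop_hybrids: bool = True
    dedup_preference: tuple = DEFAULT_DEDUP_PREFERENCE
    non_seed_groups: frozenset = NON_SEED_GROUPS

    def __post_init__(self):
        if self.max_ambiguous <= 0 or self.end_trunc_bp <= 0:
            raise ValidationError("thresholds must be positive")
        if not (0 < self.min_similarity_pct <= 100):
            raise ValidationError("min_similarity_pct must be in (0, 100]")

    def source_rank(self, source_type: str) -> int:
        try:
            return self.dedup_preference.index(source_type)
        except ValueError:
            return len(self.dedup_preference)


class RemovalEntry(NamedTuple):
    seq_id: str
    criterion: int  # 1..6
    detail: str


@dataclass
class RemovalLog:
    entries: list = field(default_factory=list)

    def add(self, seq_id: str, criterion: int, detail: str) -> None:
        self.entries.append(RemovalEntry(seq_id, criterion, detail))

    def removed_ids(self) -> set:
        return {e.seq_id for e in self.entries}

    def by_criterion(self, criterion: int) -> list:
        return [e for e in self.entries if e.criterion == criterion]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\tcriterion\tdetail\n")
            for e in self.entries:
                fh.write(f"{e.seq_id}\t{e.criterion}\t{e.detail}\n")


@dataclass(frozen=True)
class DuplicationEvent:
    """A duplication inferred from a gene tree.

    ``species_specific`` iff exactly one taxon is involved (its multiple
    sequences are more closely related to each other than to any other
    taxon's); ``shared`` means parallel taxon-spanning duplicate clades.
    """

    gene_id: str
    taxa: frozenset
    classification: str  # species_specific | shared
    clade_description: str = ""

    def __post_init__(self):
        if self.classification not in ("species_specific", "shared"):
            raise ValidationError(f"bad classification {self.classification!r}")
        if (self.classification == "species_specific") != (len(self.taxa) == 1):
            raise ValidationError(
                "species_specific events involve exactly one taxon"
            )


@dataclass
class SupermatrixSpec:
    min_genes_per_taxon: int = 6
    partitions: list = field(default_factory=list)  # (gene_id, start, end) 1-based
    excluded_genes: list = field(default_factory=list)  # (gene_id, reason)

    @property
    def width(self) -> int:
        return sum(end - start + 1 for _, start, end in self.partitions)


# ---------------------------------------------------------------------------
# Codon threading

_STOPS = ("TAA", "TAG", "TGA")
_VALID_NUC = set("ACGTURYSWKMBDHVN")


def backtranslate_alignment(
    protein_alignment: Alignment,
    cds_records: Mapping[str, str] | Iterable[SequenceRecord],
) -> Alignment:
    """Force CDS onto a protein alignment: one codon per amino-acid column.

    Protein gaps become ``---``.  Each protein's ungapped length x 3 must
    equal its CDS length (a trailing stop codon on the CDS is stripped
    first); a mismatch raises an error naming the sequence.
    """
    if not isinstance(cds_records, Mapping):
        cds_records = {r.id: r.residues for r in cds_records}
    else:
        cds_records = {
            k: (v.residues if isinstance(v, SequenceRecord) else v)
            for k, v in cds_records.items()
        }
    out = []
    for rec in protein_alignment:
        if rec.id not in cds_records:
            raise ValidationError(f"no CDS provided for {rec.id!r}")
        cds = cds_records[rec.id].upper().replace("-", "")
        if len(cds) >= 3 and cds[-3:] in _STOPS:
            cds = cds[:-3]
        bad = set(cds) - _VALID_NUC
        if bad:
            raise ValidationError(
                f"{rec.id}: CDS contains non-IUPAC character(s) {sorted(bad)}"
            )
        n_aa = len(rec.residues.replace("-", "").replace("?", ""))
        if 3 * n_aa != len(cds):
            raise ValidationError(
                f"{rec.id}: ungapped protein length {n_aa} x 3 != CDS length "
                f"{len(cds)}"
            )
        codons = []
        k = 0
        for aa in rec.residues:
            if aa in "-?":
                codons.append("---")
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        out.append(
            SequenceRecord(
                id=rec.id,
                residues="".join(codons),
                taxon=rec.taxon,
                source_type=rec.source_type,
                molecule="nucleotide",
            )
        )
    return Alignment(out)


# ---------------------------------------------------------------------------
# Sequence elimination


def _consensus(records: list[SequenceRecord]) -> str:
    """Column-majority consensus over unambiguous bases (ties to the
    alphabetically smallest base); '-' where a column has no base."""
    if not records:
        return ""
    length = len(records[0].residues)
    cols = []
    for i in range(length):
        counter = Counter(
            r.residues[i] for r in records if r.residues[i] in "ACGT"
        )
        if not counter:
            cols.append("-")
        else:
            best = max(counter.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
            cols.append(best[0])
    return "".join(cols)


def _identity_to_consensus(rec: SequenceRecord, consensus: str) -> float:
    matches = comparable = 0
    for res, cons in zip(rec.residues, consensus):
        if res in "-?" or cons == "-":
            continue
        comparable += 1
        if res == cons:
            matches += 1
    return 100.0 * matches / comparable if comparable else 0.0


def _end_gap_runs(residues: str) -> tuple[int, int]:
    lead = len(residues) - len(residues.lstrip("-?"))
    trail = len(residues) - len(residues.rstrip("-?"))
    return lead, trail


def filter_sequences(
    alignment: Alignment,
    taxon_metadata: Mapping[str, TaxonMetadata],
    criteria: CurationCriteria | None = None,
) -> tuple[Alignment, RemovalLog]:
    """Apply the six elimination criteria in order; log every removal.

    Criterion 3 (consensus similarity) is iterated to a fixed point so a
    second pass over the output removes nothing.  Removing every
    sequence is legal: a warning is logged and an empty alignment
    returned.
    """
    criteria = criteria or CurationCriteria()
    for rec in alignment:
        if rec.taxon not in taxon_metadata:
            raise ValidationError(f"taxon {rec.taxon!r} missing from metadata")

    log = RemovalLog()
    current = list(alignment)

    # 1) non-seed plants
    if criteria.drop_non_seed:
        kept = []
        for rec in current:
            group = taxon_metadata[rec.taxon].lineage_group
            if group in criteria.non_seed_groups:
                log.add(rec.id, 1, f"non-seed plant ({group})")
            else:
                kept.append(rec)
        current = kept

    # 2) ambiguous bases
    kept = []
    for rec in current:
        n_amb = rec.residues.upper().count("N")
        if n_amb >= criteria.max_ambiguous:
            log.add(rec.id, 2, f"{n_amb} ambiguous bases")
        else:
            kept.append(rec)
    current = kept

    # 3) low similarity to the rest of the alignment (fixed point)
    while True:
        if not current:
            break
        consensus = _consensus(current)
        low = [
            (rec, _identity_to_consensus(rec, consensus))
            for rec in current
            if _identity_to_consensus(rec, consensus) < criteria.min_similarity_pct
        ]
        if not low:
            break
        for rec, ident in low:
            log.add(rec.id, 3, f"{ident:.1f}% identity to consensus")
        dropped = {rec.id for rec, _ in low}
        current = [r for r in current if r.id not in dropped]

    # 4) end truncation (aligned bp missing inside the anchored span)
    kept = []
    for rec in current:
        lead, trail = _end_gap_runs(rec.residues)
        if lead >= criteria.end_trunc_bp or trail >= criteria.end_trunc_bp:
            log.add(rec.id, 4, f"missing {lead} bp at 5' / {trail} bp at 3'")
        else:
            kept.append(rec)
    current = kept

    # 5) identical sequences; keep one per group by source preference
    groups: dict[str, list[SequenceRecord]] = defaultdict(list)
    for rec in current:
        groups[rec.residues].append(rec)
    kept = []
    for recs in groups.values():
        recs_sorted = sorted(
            recs, key=lambda r: (criteria.source_rank(r.source_type), r.id)
        )
        kept.append(recs_sorted[0])
        for rec in recs_sorted[1:]:
            log.add(rec.id, 5, f"identical to {recs_sorted[0].id}")
    kept_ids = {r.id for r in kept}
    current = [r for r in current if r.id in kept_ids]

    # 6) hybrids
    if criteria.drop_hybrids:
        kept = []
        for rec in current:
            if taxon_metadata[rec.taxon].is_hybrid:
                log.add(rec.id, 6, "hybrid taxon")
            else:
                kept.append(rec)
        current = kept

    if not current:
        logger.warning("all sequences eliminated; returning empty alignment")
    return Alignment(current), log


def strip_private_gap_columns(alignment: Alignment) -> Alignment:
    """Excise columns in which exactly one sequence is gapped.

    Gaps shared between two or more sequences are retained.
    """
    if len(alignment) == 0:
        raise ValidationError("empty alignment")
    arr = np.array([list(r.residues) for r in alignment])
    gap_counts = (arr == "-").sum(axis=0)
    keep = gap_counts != 1
    out = [
        rec.with_residues("".join(arr[i, keep]))
        for i, rec in enumerate(alignment)
    ]
    return Alignment(out)


# ---------------------------------------------------------------------------
# Duplication screening


def detect_duplications(
    gene_tree: dendropy.Tree,
    taxon_of_sequence: Mapping[str, str],
    gene_id: str = "",
) -> list[DuplicationEvent]:
    """Classify duplications visible in a gene tree.

    A taxon whose multiple sequences form a clade to the exclusion of
    all other taxa carries a species-specific duplication.  Two disjoint
    clades spanning the same set of >= 2 multi-copy taxa (parallel
    duplicate clades) evidence a shared duplication predating their
    divergence.  Remaining non-monophyletic multi-copy taxa are reported
    as shared events over the taxa of the smallest clade containing all
    their copies.
    """
    tips = [leaf.taxon.label for leaf in gene_tree.leaf_node_iter()]
    missing = [t for t in tips if t not in taxon_of_sequence]
    if missing:
        raise ValidationError(f"tip(s) without taxon mapping: {missing}")

    seqs_of: dict[str, set] = defaultdict(set)
    for tip in tips:
        seqs_of[taxon_of_sequence[tip]].add(tip)
    multi = {t: s for t, s in seqs_of.items() if len(s) >= 2}
    if not multi:
        return []

    all_tips = frozenset(tips)
    sides: set[frozenset] = set()
    for node in gene_tree.preorder_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if 0 < len(clade) < len(all_tips):
            sides.add(clade)
            sides.add(all_tips - clade)

    def taxa_of(side: frozenset) -> frozenset:
        return frozenset(taxon_of_sequence[t] for t in side)

    events: dict[tuple, DuplicationEvent] = {}

    # Species-specific duplications: any clade of >= 2 sequences drawn
    # from a single taxon (nested duplicate pairs count even when the
    # taxon carries further copies elsewhere in the tree).
    for taxon in sorted(multi):
        if any(taxa_of(s) == {taxon} and len(s) >= 2 for s in sides):
            events[("species_specific", frozenset([taxon]))] = DuplicationEvent(
                gene_id=gene_id,
                taxa=frozenset([taxon]),
                classification="species_specific",
                clade_description=f"clade of duplicate copies of {taxon}",
            )

    # Effective copies: collapse each maximal single-taxon clade to one
    # lineage; only taxa with >= 2 effective copies can witness a shared
    # duplication (a lone multi-copy taxon never evidences one).
    def effective_copies(taxon: str) -> int:
        own = {s for s in sides if taxa_of(s) == {taxon}}
        maximal = [
            s for s in own if not any(s < o for o in own)
        ]
        covered = set().union(*maximal) if maximal else set()
        return len(maximal) + len(multi[taxon] - covered)

    multi_eff = {t for t in multi if effective_copies(t) >= 2}

    if multi_eff:
        # parallel taxon-spanning duplicate clades
        candidates = [
            s for s in sides
            if taxa_of(s) <= multi_eff and len(taxa_of(s)) >= 2
        ]
        by_taxa: dict[frozenset, list[frozenset]] = defaultdict(list)
        for s in candidates:
            by_taxa[taxa_of(s)].append(s)
        explained: set = set()
        pairs_by_taxa: dict[frozenset, list] = {}
        for taxa, sds in by_taxa.items():
            disjoint = sorted(
                (
                    (a, b)
                    for i, a in enumerate(sds)
                    for b in sds[i + 1 :]
                    if not (a & b)
                ),
                key=lambda p: (len(p[0]) + len(p[1]), sorted(p[0]), sorted(p[1])),
            )
            if disjoint:
                pairs_by_taxa[taxa] = disjoint

        # A nested parallel pair whose two clades are mirror images lying
        # in the two clades of a larger event is the same duplication seen
        # through subsequent speciations, not a second event; a genuine
        # nested duplication has both its clades inside one larger clade.
        def is_mirror(small, big) -> bool:
            (sa, sb), (ba, bb) = small, big
            return (sa <= ba and sb <= bb) or (sa <= bb and sb <= ba)

        chosen: dict[frozenset, tuple] = {}
        for taxa in sorted(pairs_by_taxa, key=lambda t: (-len(t), sorted(t))):
            non_mirror = [
                p for p in pairs_by_taxa[taxa]
                if not any(
                    taxa < other and is_mirror(p, chosen[other])
                    for other in chosen
                )
            ]
            if not non_mirror:
                explained.update(taxa)
                continue
            a, b = non_mirror[0]
            chosen[taxa] = (a, b)
            events[("shared", taxa)] = DuplicationEvent(
                gene_id=gene_id,
                taxa=taxa,
                classification="shared",
                clade_description=f"parallel clades {sorted(a)} | {sorted(b)}",
            )
            explained.update(taxa)

        # fallback for intermingled copies without clean parallel clades
        for taxon in sorted(multi_eff - explained):
            spanning = [s for s in sides if frozenset(multi[taxon]) <= s]
            smallest = min(spanning, key=len) if spanning else all_tips
            involved = frozenset(taxa_of(smallest) & multi_eff)
            if len(involved) >= 2:
                events.setdefault(
                    ("shared", involved),
                    DuplicationEvent(
                        gene_id=gene_id,
                        taxa=involved,
                        classification="shared",
                        clade_description=(
                            f"copies of {taxon} intermingled with "
                            f"{sorted(involved)}"
                        ),
                    ),
                )
            else:
                events.setdefault(
                    ("species_specific", frozenset([taxon])),
                    DuplicationEvent(
                        gene_id=gene_id,
                        taxa=frozenset([taxon]),
                        classification="species_specific",
                        clade_description=(
                            f"duplicate copies confined to {taxon}"
                        ),
                    ),
                )
    return sorted(
        events.values(), key=lambda e: (e.classification, sorted(e.taxa))
    )


# ---------------------------------------------------------------------------
# Supermatrix assembly


def _coverage(residues: str) -> int:
    return sum(1 for c in residues if c not in "-?")


def select_supermatrix(
    gene_alignments: Mapping[str, Alignment],
    duplication_flags: Mapping[str, bool] | None = None,
    spec: SupermatrixSpec | None = None,
    branch_lengths: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[Alignment, SupermatrixSpec]:
    """Concatenate curated gene alignments into a supermatrix.

    Genes flagged for shared duplications are excluded; one sequence per
    species per gene is chosen by (source preference, most non-gap
    columns, shortest tip branch, id); taxa with fewer than
    ``min_genes_per_taxon`` genes are dropped and the gene-exclusion /
    taxon-threshold pair re-checked to a fixed point.  Missing gene
    blocks are filled with ``?``.
    """
    duplication_flags = duplication_flags or {}
    spec = spec or SupermatrixSpec()
    branch_lengths = branch_lengths or {}
    criteria = CurationCriteria()

    included = []
    out_spec = SupermatrixSpec(min_genes_per_taxon=spec.min_genes_per_taxon)
    for gene in sorted(gene_alignments):
        if duplication_flags.get(gene, False):
            out_spec.excluded_genes.append((gene, "shared duplication"))
        else:
            included.append(gene)
    if not included:
        raise ValidationError("no genes remain after duplication screening")

    # per gene per taxon: pick a representative sequence
    reps: dict[str, dict[str, SequenceRecord]] = {}
    for gene in included:
        bl = branch_lengths.get(gene, {})
        by_taxon: dict[str, list[SequenceRecord]] = defaultdict(list)
        for rec in gene_alignments[gene]:
            by_taxon[rec.taxon].append(rec)
        reps[gene] = {
            taxon: min(
                recs,
                key=lambda r: (
                    criteria.source_rank(r.source_type),
                    -_coverage(r.residues),
                    bl.get(r.id, 0.0),
                    r.id,
                ),
            )
            for taxon, recs in by_taxon.items()
        }

    taxa = sorted({t for gene in included for t in reps[gene]})
    while True:
        counts = {
            t: sum(1 for gene in included if t in reps[gene]) for t in taxa
        }
        drop = [t for t in taxa if counts[t] < spec.min_genes_per_taxon]
        if not drop:
            break
        taxa = [t for t in taxa if t not in drop]
        if not taxa:
            raise ValidationError(
                "no taxon retains the minimum number of gene sequences"
            )

    records = []
    start = 1
    for gene in included:
        width = gene_alignments[gene].length
        out_spec.partitions.append((gene, start, start + width - 1))
        start += width
    for taxon in taxa:
        parts = []
        for gene in included:
            width = gene_alignments[gene].length
            rec = reps[gene].get(taxon)
            parts.append(rec.residues if rec is not None else "?" * width)
        records.append(
            SequenceRecord(
                id=taxon, residues="".join(parts), taxon=taxon,
                molecule="nucleotide",
            )
        )
    return Alignment(records), out_spec


# ---------------------------------------------------------------------------
# Alignment statistics


class AlignmentStats(NamedTuple):
    n_seq: int
    n_columns: int
    n_variable: int
    n_parsimony_informative: int
    pct_parsimony_informative: int


def alignment_stats(alignment: Alignment) -> AlignmentStats:
    """Sequence/column counts, variable and parsimony-informative sites.

    Variable: >= 2 distinct unambiguous bases in the column (gaps and
    ambiguity codes ignored).  Parsimony-informative: >= 2 bases each
    present in >= 2 sequences.  The PI percentage is rounded to the
    nearest integer to match the usual tabular reporting.
    """
    if len(alignment) == 0 or alignment.length == 0:
        raise ValidationError("empty alignment")
    arr = np.array([list(r.residues.upper()) for r in alignment])
    counts = np.stack([(arr == b).sum(axis=0) for b in "ACGT"])  # 4 x cols
    n_distinct = (counts > 0).sum(axis=0)
    variable = int((n_distinct >= 2).sum())
    pi = int(((counts >= 2).sum(axis=0) >= 2).sum())
    n_cols = alignment.length
    return AlignmentStats(
        n_seq=len(alignment),
        n_columns=n_cols,
        n_variable=variable,
        n_parsimony_informative=pi,
        pct_parsimony_informative=int(round(100.0 * pi / n_cols)),
    )
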