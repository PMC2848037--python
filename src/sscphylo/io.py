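"""Readers and writers for the external formats the pipeline touches.

FASTA records carry metadata in pipe-delimited headers (``id|taxon|source_type``);
absent fields default to ``taxon = id`` and ``source_type = est_singleton``.
Trees and alignments in NEXUS / relaxed PHYLIP / Newick go through dendropy.
All writer/reader pairs round-trip: topology, branch lengths (to 1e-9),
support labels and alignment content are preserved exactly.
"""

from __future__ import annotations

import csv
import io as _io
import math
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO

from .records import (
    Alignment,
    AnnotationRecord,
    BlastHit,
    FormatError,
    SequenceRecord,
    TaxonMetadata,
    ValidationError,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_genome_map",
    "write_genome_map",
    "read_taxon_metadata",
    "read_annotation_table",
    "write_annotation_table",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "log_stage",
]


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str) -> tuple[str, str, str]:
    fields = header.split("|")
    seq_id = fields[0].strip()
    taxon = fields[1].strip() if len(fields) > 1 and fields[1].strip() else seq_id
    source = fields[2].strip() if len(fields) > 2 and fields[2].strip() else "est_singleton"
    return seq_id, taxon, source


def read_fasta(path, molecule: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Raises :class:`FormatError` on an empty file and
    :class:`ValidationError` on duplicate ids (naming the id).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, taxon, source = _parse_header(rec.description)
        if seq_id in seen:
            raise ValidationError(f"duplicate sequence id {seq_id!r} in {path}")
        seen.add(seq_id)
        records.append(
            SequenceRecord(
                id=seq_id,
                residues=str(rec.seq).upper(),
                taxon=taxon,
                source_type=source,
                molecule=molecule,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}|{r.taxon}|{r.source_type}\n")
            for i in range(0, len(r.residues), 70):
                fh.write(r.residues[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# BLAST 12-column tabular

def read_blast_tab(path) -> list[BlastHit]:
    """Read standard 12-column tabular hit output.

    Columns 1, 2, 3, 4, 11, 12 map to query, subject, percent identity,
    alignment length, E-value and bit score.  A line with the wrong
    column count raises :class:`FormatError` naming the line number.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        aln_len=int(cols[3]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_len),
                        "0", "0", "1", str(h.aln_len), "1", str(h.aln_len),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables

def read_genome_map(path) -> dict[str, str]:
    """TSV of ``gene_id<TAB>genome`` (header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (lineno == 1 and row[0].lower() in ("gene_id", "gene")):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected gene_id<TAB>genome")
            gene, genome = row[0].strip(), row[1].strip()
            if gene in mapping:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            mapping[gene] = genome
    return mapping


def write_genome_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgenome\n")
        for gene, genome in mapping.items():
            fh.write(f"{gene}\t{genome}\n")


def read_taxon_metadata(path) -> dict[str, TaxonMetadata]:
    """TSV with header ``taxon  lineage_group  is_hybrid``."""
    out: dict[str, TaxonMetadata] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"taxon", "lineage_group", "is_hybrid"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: header must contain {sorted(required)}"
            )
        for row in reader:
            taxon = row["taxon"].strip()
            if taxon in out:
                raise ValidationError(f"{path}: duplicate taxon {taxon!r}")
            out[taxon] = TaxonMetadata(
                taxon=taxon,
                lineage_group=row["lineage_group"].strip(),
                is_hybrid=row["is_hybrid"].strip().lower() in ("1", "true", "yes"),
            )
    return out


_ANNOT_COLS = [
    "gene_id",
    "go_cellular_component",
    "go_molecular_function",
    "go_biological_process",
    "exon_count",
    "domain_count",
    "cdna_length",
]

_NS_BY_COL = {
    "go_cellular_component": "cellular_component",
    "go_molecular_function": "molecular_function",
    "go_biological_process": "biological_process",
}


def read_annotation_table(path) -> dict[str, AnnotationRecord]:
    """Read the per-gene annotation TSV.

    Header: ``gene_id``, one column per GO namespace holding
    semicolon-separated slim categories (empty cell = no annotation),
    then ``exon_count``, ``domain_count``, ``cdna_length``.
    """
    out: dict[str, AnnotationRecord] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_ANNOT_COLS) <= set(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {_ANNOT_COLS}")
        for lineno, row in enumerate(reader, start=2):
            gene = row["gene_id"].strip()
            if gene in out:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene!r}")
            go = {}
            for col, ns in _NS_BY_COL.items():
                cell = (row[col] or "").strip()
                go[ns] = frozenset(
                    c.strip() for c in cell.split(";") if c.strip()
                )
            try:
                out[gene] = AnnotationRecord(
                    gene_id=gene,
                    go_slim=go,
                    exon_count=int(row["exon_count"]),
                    domain_count=int(row["domain_count"]),
                    cdna_length=int(row["cdna_length"]),
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_annotation_table(annotations: Mapping[str, AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLS) + "\n")
        for gene, a in annotations.items():
            cells = [gene]
            for col, ns in _NS_BY_COL.items():
                cells.append(";".join(sorted(a.go_slim.get(ns, ()))))
            cells += [str(a.exon_count), str(a.domain_count), str(a.cdna_length)]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Alignments (FASTA / NEXUS / relaxed PHYLIP) and trees (Newick / NEXUS)

_ALN_SCHEMAS = {"fasta", "nexus", "phylip"}


def read_alignment(path, schema: str = "fasta", molecule: str = "nucleotide") -> Alignment:
    """Read an alignment; NEXUS and relaxed PHYLIP go through dendropy.

    Metadata beyond the sequence label is only representable in the
    FASTA header convention; other schemas yield default taxon/source.
    """
    schema = schema.lower()
    if schema not in _ALN_SCHEMAS:
        raise ValueError(f"unsupported alignment schema {schema!r}")
    if schema == "fasta":
        return Alignment(read_fasta(path, molecule=molecule))
    cls = (
        dendropy.DnaCharacterMatrix
        if molecule == "nucleotide"
        else dendropy.ProteinCharacterMatrix
    )
    try:
        mat = cls.get(path=str(path), schema=schema)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise FormatError(f"{path}: cannot parse {schema}: {exc}") from exc
    records = [
        SequenceRecord(
            id=taxon.label.replace(" ", "_"),
            residues=str(mat[taxon]).upper(),
            molecule=molecule,
        )
        for taxon in mat
    ]
    if not records:
        raise FormatError(f"{path}: empty {schema} alignment")
    return Alignment(records)


def write_alignment(alignment: Alignment, path, schema: str = "fasta") -> None:
    schema = schema.lower()
    if schema not in _ALN_SCHEMAS:
        raise ValueError(f"unsupported alignment schema {schema!r}")
    if schema == "fasta":
        write_fasta(alignment.records, path)
        return
    molecule = alignment.records[0].molecule
    cls = (
        dendropy.DnaCharacterMatrix
        if molecule == "nucleotide"
        else dendropy.ProteinCharacterMatrix
    )
    d = {r.id: r.residues for r in alignment}
    mat = cls.from_dict(d)
    mat.write(path=str(path), schema=schema)


def read_tree(path, schema: str = "newick") -> dendropy.Tree:
    """Read a tree, preserving branch lengths and internal (support) labels."""
    try:
        return dendropy.Tree.get(
            path=str(path),
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse {schema} tree: {exc}") from exc


def write_tree(tree: dendropy.Tree, path, schema: str = "newick") -> None:
    tree.write(
        path=str(path),
        schema=schema,
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def parse_newick(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"cannot parse newick: {exc}") from exc


# ---------------------------------------------------------------------------
# Run log

def log_stage(path, stage: str, **params) -> None:
    """Append one line recording a pipeline stage and its parameters.

    Seeds passed by callers are recorded like any other parameter, so a
    run log is sufficient to reproduce a pipeline invocation.
    """
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    with open(path, "a") as fh:
        fh.write(f"stage={stage} {kv}\n".rstrip() + "\n")
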