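"""Synthetic data generators with known planted truth.

Every stage of the pipeline is testable without external downloads:
planted-family similarity graphs emulate all-vs-all protein hit
structure with known per-genome copy numbers; gene families are evolved
along a species tree under a birth-death duplication/loss process;
sequences evolve by Jukes-Cantor substitution; EST-style degradation
(end truncation, ambiguity runs, redundant identical variants) is
applied with a defect log predicting which curation criterion each
defect triggers.  All generators are pure functions of their spec and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .clustering import CopyNumberProfile, SimilarityGraph
from .curation import CurationCriteria, DuplicationEvent
from .records import Alignment, BlastHit, SequenceRecord, TaxonMetadata, ValidationError

__all__ = [
    "FamilySpec",
    "EvolutionSpec",
    "DegradationSpec",
    "ToyStudy",
    "gen_planted_graph",
    "graph_to_hits",
    "evolve_gene_family",
    "evolve_gene_families",
    "simulate_jc_alignment",
    "degrade_to_ests",
    "make_toy_study",
]


# ---------------------------------------------------------------------------
# Planted-family similarity graphs


@dataclass(frozen=True)
class FamilySpec:
    """Planted gene families over a set of genomes.

    ``copy_counts`` gives per-genome copy numbers: either one mapping
    applied to every family or one mapping per family.  Within-family
    edge weights must stochastically dominate between-family weights.
    """

    n_families: int = 10
    genomes: tuple = ("Ath", "Ptr", "Vvi", "Osa")
    copy_counts: Mapping[str, int] | Sequence[Mapping[str, int]] | None = None
    within_mean: float = 60.0
    within_sd: float = 5.0
    between_mean: float = 5.0
    between_sd: float = 2.0
    evalue_floor: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValidationError("need at least one family")
        if self.within_mean <= self.between_mean:
            raise ValidationError("within mean must exceed between mean")
        for counts in self.family_counts():
            if any(c < 0 for c in counts.values()):
                raise ValidationError("copy counts must be >= 0")

    def family_counts(self) -> list[dict]:
        if self.copy_counts is None:
            return [{g: 1 for g in self.genomes}] * self.n_families
        if isinstance(self.copy_counts, Mapping):
            return [dict(self.copy_counts)] * self.n_families
        counts = [dict(c) for c in self.copy_counts]
        if len(counts) != self.n_families:
            raise ValidationError("one copy-count mapping per family required")
        return counts


def gen_planted_graph(
    spec: FamilySpec,
) -> tuple[SimilarityGraph, list[frozenset], list[CopyNumberProfile]]:
    """Generate a similarity graph with planted families.

    Gene names are deterministic (``F<k>_<genome>_c<i>``).  Within-family
    weights are drawn from N(within_mean, within_sd), between-family from
    N(between_mean, between_sd); draws are clipped to [0, evalue_floor]
    and non-positive between-family draws produce no edge.
    """
    rng = np.random.default_rng(spec.seed)
    sg = SimilarityGraph(evalue_floor=spec.evalue_floor)
    families: list[list[str]] = []
    profiles: list[CopyNumberProfile] = []
    for f, counts in enumerate(spec.family_counts()):
        members = []
        for genome in spec.genomes:
            for c in range(counts.get(genome, 0)):
                gene = f"F{f:03d}_{genome}_c{c}"
                sg.add_gene(gene, genome)
                members.append(gene)
        families.append(members)
        profiles.append(
            CopyNumberProfile(
                tribe_id=f"F{f:03d}",
                counts={g: counts.get(g, 0) for g in spec.genomes},
            )
        )

    cap = spec.evalue_floor
    for f, members in enumerate(families):
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                w = float(rng.normal(spec.within_mean, spec.within_sd))
                sg.add_edge(members[i], members[j], min(max(w, 0.0), cap))
        for g in range(f + 1, len(families)):
            for a in members:
                for b in families[g]:
                    w = float(rng.normal(spec.between_mean, spec.between_sd))
                    if w > 0:
                        sg.add_edge(a, b, min(w, cap))
    partition = [frozenset(m) for m in families if m]
    return sg, partition, profiles


def graph_to_hits(graph: SimilarityGraph) -> list[BlastHit]:
    """Render a similarity graph as a directional 12-column-style hit list
    (both directions, E = 10**-weight)."""
    hits = []
    for a in graph.nodes:
        for b in sorted(graph.graph.neighbors(a)):
            w = graph.weight(a, b)
            hits.append(
                BlastHit(
                    query_id=a, subject_id=b,
                    pct_identity=min(99.9, 40.0 + w / 4.0),
                    aln_len=200,
                    evalue=10.0 ** (-w),
                    bitscore=50.0 + 2 * w,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Gene-family evolution (duplication/loss birth-death along a species tree)


@dataclass(frozen=True)
class EvolutionSpec:
    """Birth-death gene-family evolution along a species tree.

    ``species_tree`` is a newick string with branch lengths in expected
    substitutions/site; duplication and loss rates are events per unit
    branch length.
    """

    species_tree: str = "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.0;"
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    sequence_length: int = 1000
    seed: int = 0
    retry_cap: int = 100

    def __post_init__(self):
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.sequence_length < 1:
            raise ValidationError("sequence length must be positive")


class _GeneNode:
    __slots__ = ("children", "length", "label", "dup_branch", "alive")

    def __init__(self):
        self.children: list[_GeneNode] = []
        self.length = 0.0
        self.label: str | None = None
        self.dup_branch: str | None = None  # species branch of a duplication
        self.alive = True


def _species_root(tree: dendropy.Tree) -> dendropy.Node:
    return tree.seed_node


def _evolve_lineage(gn, remaining, rate_d, rate_l, rng, branch_label, events):
    """Evolve one gene lineage along a species-tree edge segment."""
    total = rate_d + rate_l
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if wait >= remaining:
            gn.length += remaining
            return [gn]
        gn.length += wait
        remaining -= wait
        if rng.random() < rate_d / total:
            gn.dup_branch = branch_label
            events.append(gn)
            left, right = _GeneNode(), _GeneNode()
            gn.children = [left, right]
            out = _evolve_lineage(left, remaining, rate_d, rate_l, rng,
                                  branch_label, events)
            out += _evolve_lineage(right, remaining, rate_d, rate_l, rng,
                                   branch_label, events)
            return out
        gn.alive = False
        return []


def _prune_and_collect(root: _GeneNode) -> _GeneNode | None:
    """Drop dead subtrees and suppress unifurcations (lengths merge)."""
    if not root.children:
        return root if (root.alive and root.label is not None) else None
    kept = []
    for ch in root.children:
        p = _prune_and_collect(ch)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += root.length
        return child
    root.children = kept
    return root


def _to_dendropy(root: _GeneNode) -> dendropy.Tree:
    def newick(n: _GeneNode) -> str:
        if not n.children:
            return f"{n.label}:{n.length:.8f}"
        inner = ",".join(newick(c) for c in n.children)
        return f"({inner}):{n.length:.8f}"

    tree = dendropy.Tree.get(
        data=newick(root) + ";", schema="newick", preserve_underscores=True
    )
    return tree


def evolve_gene_family(
    spec: EvolutionSpec, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, dict[str, int], list[DuplicationEvent]]:
    """Simulate one gene family; returns (gene tree, per-taxon copy
    numbers, observable planted duplication events).

    An event is species-specific when the duplication occurred on a
    terminal species branch (or survives only within one taxon), and
    shared over the taxa in which both duplicate lineages survive.
    Duplications whose surviving copies no longer overlap in any taxon
    leave no observable signature and are omitted from the truth list.
    """
    rng = rng or np.random.default_rng(spec.seed)
    sp = dendropy.Tree.get(
        data=spec.species_tree, schema="newick", preserve_underscores=True
    )
    for attempt in range(spec.retry_cap):
        events: list[_GeneNode] = []
        counters: dict[str, int] = {}

        def walk(sp_node, gene_nodes):
            for child in sp_node.child_nodes():
                blen = child.edge.length or 0.0
                label = (
                    child.taxon.label
                    if child.is_leaf()
                    else f"internal_{id(child)}"
                )
                survivors = []
                entering = []
                for gn in gene_nodes:
                    nxt = _GeneNode()
                    gn.children.append(nxt)
                    entering.append(nxt)
                for gn in entering:
                    survivors.extend(
                        _evolve_lineage(
                            gn, blen, spec.duplication_rate, spec.loss_rate,
                            rng, label, events,
                        )
                    )
                if child.is_leaf():
                    taxon = child.taxon.label
                    for gn in survivors:
                        counters[taxon] = counters.get(taxon, 0) + 1
                        gn.label = f"{taxon}_g{counters[taxon]}"
                else:
                    walk(child, survivors)

        root = _GeneNode()
        walk(_species_root(sp), [root])
        pruned = _prune_and_collect(root)
        if pruned is None or not counters:
            continue
        if sum(counters.values()) < 2:
            continue

        terminal_labels = {leaf.taxon.label for leaf in sp.leaf_node_iter()}
        truth: list[DuplicationEvent] = []
        for dn in events:
            if len(dn.children) != 2:
                continue
            sides = []
            for ch in dn.children:
                taxa = set()
                stack = [ch]
                while stack:
                    x = stack.pop()
                    if not x.children:
                        if x.alive and x.label is not None:
                            taxa.add(x.label.rsplit("_g", 1)[0])
                    else:
                        stack.extend(x.children)
                sides.append(taxa)
            left, right = sides
            if not left or not right:
                continue  # one duplicate lineage fully lost: unobservable
            common = left & right
            if dn.dup_branch in terminal_labels:
                truth.append(
                    DuplicationEvent(
                        gene_id="", taxa=frozenset([dn.dup_branch]),
                        classification="species_specific",
                        clade_description="terminal-branch duplication",
                    )
                )
            elif len(common) >= 2:
                truth.append(
                    DuplicationEvent(
                        gene_id="", taxa=frozenset(common),
                        classification="shared",
                        clade_description=f"duplication on {dn.dup_branch}",
                    )
                )
            elif len(common) == 1:
                truth.append(
                    DuplicationEvent(
                        gene_id="", taxa=frozenset(common),
                        classification="species_specific",
                        clade_description="survives in one taxon only",
                    )
                )
        tree = _to_dendropy(pruned)
        taxa_counts = {
            leaf.taxon.label: 0 for leaf in sp.leaf_node_iter()
        }
        taxa_counts.update(counters)
        return tree, taxa_counts, truth
    raise ValidationError(
        f"all gene lineages lost in {spec.retry_cap} attempts; "
        "reduce the loss rate"
    )


def evolve_gene_families(
    spec: EvolutionSpec, n_families: int
) -> list[tuple[dendropy.Tree, dict[str, int], list[DuplicationEvent]]]:
    rng = np.random.default_rng(spec.seed)
    return [evolve_gene_family(spec, rng) for _ in range(n_families)]


# ---------------------------------------------------------------------------
# Jukes-Cantor sequence simulation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_jc_alignment(
    tree: dendropy.Tree,
    length_bp: int,
    seed: int | np.random.Generator = 0,
    source_type: str = "transcript_assembly",
) -> Alignment:
    """Evolve i.i.d. sites under Jukes-Cantor down ``tree``.

    Branch lengths are expected substitutions/site; the probability a
    site differs across a branch of length t is (3/4)(1 - e^(-4t/3)).
    The root sequence is uniform over {A, C, G, T}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    records = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = rng.integers(0, 4, size=length_bp, dtype=np.int8)
        else:
            t = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
            parent = seqs[id(node.parent_node)]
            seq = parent.copy()
            mask = rng.random(length_bp) < p_change
            n_mut = int(mask.sum())
            if n_mut:
                # substitute with one of the three other bases uniformly
                shift = rng.integers(1, 4, size=n_mut, dtype=np.int8)
                seq[mask] = (seq[mask] + shift) % 4
            seqs[id(node)] = seq
        if node.is_leaf():
            residues = bytes(_BASES[seqs[id(node)]]).decode("ascii")
            records.append(
                SequenceRecord(
                    id=node.taxon.label,
                    residues=residues,
                    taxon=node.taxon.label.rsplit("_g", 1)[0],
                    source_type=source_type,
                    molecule="nucleotide",
                )
            )
    return Alignment(records)


# ---------------------------------------------------------------------------
# EST-style degradation


@dataclass(frozen=True)
class DegradationSpec:
    """EST defect model.

    Per record, independently: end truncation (with ``p_truncate`` per
    end, missing length uniform on [trunc_min, trunc_max] aligned bp),
    per-base ambiguity (N) substitution at ``ambiguity_rate``, and with
    ``p_redundant`` an identical EST-singleton variant is appended.
    Taxa named in ``hybrid_taxa`` are expected to fall to the hybrid
    criterion.  Rates are probabilities in [0, 1].
    """

    p_truncate: float = 0.0
    trunc_min: int = 50
    trunc_max: int = 120
    ambiguity_rate: float = 0.0
    p_redundant: float = 0.0
    hybrid_taxa: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        for r in (self.p_truncate, self.ambiguity_rate, self.p_redundant):
            if not (0.0 <= r <= 1.0):
                raise ValidationError("rates must lie in [0, 1]")
        if self.trunc_min < 1 or self.trunc_max < self.trunc_min:
            raise ValidationError("invalid truncation range")


def degrade_to_ests(
    records: Iterable[SequenceRecord],
    spec: DegradationSpec,
    criteria: CurationCriteria | None = None,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Apply EST-style defects; return (records, planted defect log).

    The defect log maps sequence id -> the elimination criterion (2, 4,
    5 or 6) the defect should trigger, mirroring the criteria's order of
    application; clean records are absent from the log.
    """
    criteria = criteria or CurationCriteria()
    rng = np.random.default_rng(spec.seed)
    out: list[SequenceRecord] = []
    log: dict[str, int] = {}

    degraded: list[SequenceRecord] = []
    for rec in records:
        res = np.array(list(rec.residues))
        if spec.p_truncate > 0 and rng.random() < spec.p_truncate:
            n = int(rng.integers(spec.trunc_min, spec.trunc_max + 1))
            if rng.random() < 0.5:
                res[:n] = "-"
            else:
                res[len(res) - n :] = "-"
        if spec.ambiguity_rate > 0:
            mask = (rng.random(len(res)) < spec.ambiguity_rate) & (res != "-")
            res[mask] = "N"
        degraded.append(rec.with_residues("".join(res)))

    for rec in degraded:
        out.append(rec)
        if spec.p_redundant > 0 and rng.random() < spec.p_redundant:
            out.append(
                SequenceRecord(
                    id=rec.id + "_dup",
                    residues=rec.residues,
                    taxon=rec.taxon,
                    source_type="est_singleton",
                    molecule="nucleotide",
                )
            )

    # predict the first criterion each record falls to (2, 4, 5, 6)
    seen_residues: dict[str, str] = {}
    survivors: list[SequenceRecord] = []
    for rec in out:
        n_amb = rec.residues.count("N")
        lead = len(rec.residues) - len(rec.residues.lstrip("-?"))
        trail = len(rec.residues) - len(rec.residues.rstrip("-?"))
        if n_amb >= criteria.max_ambiguous:
            log[rec.id] = 2
        elif lead >= criteria.end_trunc_bp or trail >= criteria.end_trunc_bp:
            log[rec.id] = 4
        else:
            survivors.append(rec)
    ranked: dict[str, SequenceRecord] = {}
    for rec in survivors:
        prev = ranked.get(rec.residues)
        if prev is None:
            ranked[rec.residues] = rec
        else:
            keep, drop = sorted(
                (prev, rec),
                key=lambda r: (criteria.source_rank(r.source_type), r.id),
            )
            ranked[rec.residues] = keep
            log[drop.id] = 5
    for rec in ranked.values():
        if rec.taxon in spec.hybrid_taxa:
            log[rec.id] = 6
    return out, log


# ---------------------------------------------------------------------------
# End-to-end toy study


@dataclass
class ToyStudy:
    """A small end-to-end fixture with all planted truths attached."""

    hits: list
    genome_map: dict
    genomes: tuple
    planted_partition: list
    planted_profiles: list
    planted_ssc: list
    species_tree: str
    gene_alignments: dict  # gene id -> Alignment (degraded)
    gene_taxon_maps: dict  # gene id -> {seq id -> taxon}
    planted_defects: dict  # gene id -> {seq id -> criterion}
    taxon_metadata: dict
    annotations: dict
    ssc_genes: list
    background_genes: list
    enriched_category: str


_TOY_SPECIES_TREE = (
    "(((T1:0.05,T2:0.05):0.05,(T3:0.05,T4:0.05):0.05):0.05,"
    "((T5:0.05,T6:0.05):0.05,(T7:0.05,T8:0.05):0.05):0.05):0.0;"
)


def make_toy_study(seed: int = 0) -> ToyStudy:
    """Deterministic end-to-end bundle: a planted similarity graph over
    four genomes, JC gene alignments with EST degradation over eight
    taxa, GO-slim annotations with one planted over-represented
    category, and taxon metadata including a hybrid."""
    rng = np.random.default_rng(seed)
    genomes = ("Ath", "Ptr", "Vvi", "Osa")
    counts = [{g: 1 for g in genomes} for _ in range(9)]
    counts += [
        {"Ath": 2, "Ptr": 1, "Vvi": 1, "Osa": 1},
        {"Ath": 1, "Ptr": 1, "Vvi": 0, "Osa": 1},
        {"Ath": 1, "Ptr": 3, "Vvi": 1, "Osa": 2},
    ]
    fam_spec = FamilySpec(
        n_families=len(counts),
        genomes=genomes,
        copy_counts=counts,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    graph, partition, profiles = gen_planted_graph(fam_spec)
    hits = graph_to_hits(graph)
    genome_map = {g: graph.genome_of(g) for g in graph.nodes}
    planted_ssc = [
        p.tribe_id for p in profiles if all(p.count(g) == 1 for g in genomes)
    ]

    # gene alignments over 8 taxa for 6 genes; one gene carries a shared
    # duplication, one a species-specific duplication
    gene_alignments = {}
    gene_taxon_maps = {}
    planted_defects = {}
    evo = EvolutionSpec(species_tree=_TOY_SPECIES_TREE, sequence_length=400)
    for k in range(6):
        if k == 4:
            spec_k = EvolutionSpec(
                species_tree=_TOY_SPECIES_TREE, duplication_rate=1.2,
                loss_rate=0.0, sequence_length=400,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            spec_k = EvolutionSpec(
                species_tree=_TOY_SPECIES_TREE, sequence_length=400,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        gtree, _, _ = evolve_gene_family(spec_k)
        aln = simulate_jc_alignment(
            gtree, evo.sequence_length, rng
        )
        deg_spec = DegradationSpec(
            p_truncate=0.1, ambiguity_rate=0.005, p_redundant=0.1,
            hybrid_taxa=frozenset({"T8"}),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        degraded, defects = degrade_to_ests(aln, deg_spec)
        gene_alignments[f"gene{k}"] = Alignment(degraded)
        gene_taxon_maps[f"gene{k}"] = {r.id: r.taxon for r in degraded}
        planted_defects[f"gene{k}"] = defects

    taxon_metadata = {
        f"T{i}": TaxonMetadata(
            taxon=f"T{i}",
            lineage_group="Eurosids" if i <= 4 else "Monocots",
            is_hybrid=(i == 8),
        )
        for i in range(1, 9)
    }

    # annotations with a planted over-represented category among SSC genes
    ssc_genes = [f"F{int(t[1:]):03d}_Ath_c0" for t in planted_ssc]
    background_genes = [f"BG{i:04d}" for i in range(300)]
    enriched = "chloroplast"
    annotations = {}
    cats_cc = ["chloroplast", "nucleus", "other membranes"]
    cats_mf = ["kinase activity", "other enzyme activity"]
    cats_bp = ["transport", "DNA or RNA metabolism"]
    for g in ssc_genes:
        cc = {enriched} if rng.random() < 0.8 else {str(rng.choice(cats_cc))}
        annotations[g] = _random_annotation(g, rng, cc, cats_mf, cats_bp,
                                            exon_boost=4)
    for g in background_genes:
        cc = {enriched} if rng.random() < 0.2 else {str(rng.choice(cats_cc))}
        annotations[g] = _random_annotation(g, rng, cc, cats_mf, cats_bp,
                                            exon_boost=0)

    return ToyStudy(
        hits=hits,
        genome_map=genome_map,
        genomes=genomes,
        planted_partition=partition,
        planted_profiles=profiles,
        planted_ssc=planted_ssc,
        species_tree=_TOY_SPECIES_TREE,
        gene_alignments=gene_alignments,
        gene_taxon_maps=gene_taxon_maps,
        planted_defects=planted_defects,
        taxon_metadata=taxon_metadata,
        annotations=annotations,
        ssc_genes=ssc_genes,
        background_genes=background_genes,
        enriched_category=enriched,
    )


def _random_annotation(gene, rng, cc, cats_mf, cats_bp, exon_boost):
    from .records import AnnotationRecord

    return AnnotationRecord(
        gene_id=gene,
        go_slim={
            "cellular_component": frozenset(cc),
            "molecular_function": frozenset({str(rng.choice(cats_mf))}),
            "biological_process": frozenset({str(rng.choice(cats_bp))}),
        },
        exon_count=1 + exon_boost + int(rng.poisson(3)),
        domain_count=int(rng.poisson(1)),
        cdna_length=600 + int(rng.integers(0, 1800)),
    )
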