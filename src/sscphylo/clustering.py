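"""Circumscription of gene "tribes" from all-vs-all protein similarity.

The substrate is a symmetric graph whose edge weights are averaged
directional ``-log10 E``-values.  Tribes — an operational approximation
of gene families — are read off a Markov clustering (MCL) of that graph:
alternating expansion (matrix squaring) and inflation (entrywise
powering with column renormalisation) drives the column-stochastic flow
matrix to a near-idempotent limit whose attractor basins are the
clusters.  A tribe is *shared single copy* over a genome subset when it
contains exactly one member from every genome in the subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .records import BlastHit, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityGraph",
    "MCLSettings",
    "Tribe",
    "CopyNumberProfile",
    "build_similarity_graph",
    "mcl_cluster",
    "copy_number_profiles",
    "shared_single_copy",
    "presence_counts",
]


class SimilarityGraph:
    """Symmetric weighted gene graph (clustering substrate).

    Node attribute ``genome`` carries the source genome; edge weights are
    the mean of the available directional ``-log10 E``-values, capped at
    ``evalue_floor`` (the value substituted when E = 0).  No self-edges.
    """

    def __init__(self, evalue_floor: float = 200.0):
        self.graph = nx.Graph()
        self.evalue_floor = float(evalue_floor)

    def add_gene(self, gene: str, genome: str) -> None:
        self.graph.add_node(gene, genome=genome)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValidationError(f"self-edge on {a!r} not allowed")
        if not (0.0 <= weight <= self.evalue_floor):
            raise ValidationError(
                f"weight {weight} for ({a},{b}) outside [0, {self.evalue_floor}]"
            )
        self.graph.add_edge(a, b, weight=float(weight))

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def genome_of(self, gene: str) -> str:
        return self.graph.nodes[gene]["genome"]

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def to_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense symmetric weight matrix over nodes in sorted order."""
        order = self.nodes
        index = {g: i for i, g in enumerate(order)}
        w = np.zeros((len(order), len(order)))
        for a, b, data in self.graph.edges(data=True):
            i, j = index[a], index[b]
            w[i, j] = w[j, i] = data["weight"]
        return w, order


@dataclass(frozen=True)
class MCLSettings:
    """Markov clustering parameters; inflation 3.0 is the tribe default
    ("medium stringency")."""

    inflation: float = 3.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    convergence_tolerance: float = 1e-6
    max_iterations: int = 100

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValidationError("inflation must be > 1")
        if self.expansion < 2:
            raise ValidationError("expansion power must be >= 2")
        if self.prune_threshold <= 0 or self.convergence_tolerance <= 0:
            raise ValidationError("thresholds must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass(frozen=True)
class Tribe:
    tribe_id: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"tribe {self.tribe_id} has no members")


@dataclass(frozen=True)
class CopyNumberProfile:
    tribe_id: str
    counts: Mapping[str, int]

    def count(self, genome: str) -> int:
        return self.counts.get(genome, 0)

    @property
    def size(self) -> int:
        return sum(self.counts.values())


def build_similarity_graph(
    hits: Iterable[BlastHit],
    genome_map: Mapping[str, str],
    edge_cutoff_evalue: float = 1e-5,
    evalue_floor: float = 200.0,
) -> SimilarityGraph:
    """Convert directional hits into the averaged -log10 E similarity graph.

    Self-hits are dropped; hits with E above ``edge_cutoff_evalue`` are
    dropped; for each ordered pair only the best (lowest-E) hit is kept;
    E = 0 maps to ``evalue_floor``, and weights are capped there.  The
    undirected weight is the mean of the directions present (a single
    direction is used as-is).
    """
    best: dict[tuple[str, str], float] = {}
    genes: set[str] = set()
    for h in hits:
        for g in (h.query_id, h.subject_id):
            if g not in genome_map:
                raise ValidationError(f"gene {g!r} missing from genome map")
        genes.update((h.query_id, h.subject_id))
        if h.query_id == h.subject_id:
            continue
        if h.evalue > edge_cutoff_evalue:
            continue
        key = (h.query_id, h.subject_id)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue

    sg = SimilarityGraph(evalue_floor=evalue_floor)
    for g in sorted(genes):
        sg.add_gene(g, genome_map[g])

    done: set[tuple[str, str]] = set()
    for (q, s), ev in best.items():
        pair = (min(q, s), max(q, s))
        if pair in done:
            continue
        done.add(pair)
        vals = []
        for key in ((q, s), (s, q)):
            if key in best:
                e = best[key]
                vals.append(evalue_floor if e == 0.0 else min(-math.log10(e), evalue_floor))
        sg.add_edge(pair[0], pair[1], sum(vals) / len(vals))
    return sg


# ---------------------------------------------------------------------------
# MCL


def _inflate(m: np.ndarray, power: float, prune: float) -> np.ndarray:
    # renormalize before pruning so the threshold acts on the stochastic
    # scale; raw entrywise powers underflow at high inflation
    m = np.power(m, power)
    m = m / m.sum(axis=0)
    m[m < prune] = 0.0
    return m / m.sum(axis=0)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    return m / m.sum(axis=0)


def mcl_matrix(
    weights: np.ndarray, settings: MCLSettings
) -> tuple[np.ndarray, bool]:
    """Run the MCL iteration on a dense symmetric weight matrix.

    Self-loops equal to each node's maximum incident weight (1.0 for an
    isolated node) are added before column normalisation.  Returns the
    limit matrix and a convergence flag.
    """
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValidationError("weight matrix must be square")
    if not np.allclose(weights, weights.T):
        raise ValidationError("weight matrix must be symmetric")
    n = weights.shape[0]
    m = weights.astype(float).copy()
    np.fill_diagonal(m, 0.0)
    loops = m.max(axis=0)
    loops[loops == 0.0] = 1.0
    m[np.diag_indices(n)] = loops
    m = _normalize_columns(m)

    converged = False
    for _ in range(settings.max_iterations):
        expanded = np.linalg.matrix_power(m, settings.expansion)
        new = _inflate(expanded, settings.inflation, settings.prune_threshold)
        if np.max(np.abs(new - m)) < settings.convergence_tolerance:
            m = new
            converged = True
            break
        m = new
    return m, converged


def _clusters_from_limit(limit: np.ndarray, prune: float) -> list[list[int]]:
    """Read clusters off the (near-)idempotent limit matrix.

    Attractors are nodes with positive self-flow; attractor systems are
    merged when they feed a common column; every node joins the system of
    the attractor granting it the largest steady-state mass, ties going
    to the system with the smallest attractor index.
    """
    n = limit.shape[0]
    attractors = [i for i in range(n) if limit[i, i] > prune]
    if not attractors:  # pathological; treat every node as its own attractor
        attractors = list(range(n))
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for j in range(n):
        supp = [a for a in attractors if limit[a, j] > prune]
        for a, b in zip(supp, supp[1:]):
            union(a, b)

    systems: dict[int, list[int]] = {}
    assignment: dict[int, int] = {}
    for j in range(n):
        supp = [a for a in attractors if limit[a, j] > prune]
        if supp:
            # largest mass, ties to the smallest attractor index
            a_best = max(supp, key=lambda a: (limit[a, j], -a))
            assignment[j] = find(a_best)
        else:
            assignment[j] = find(attractors[0]) if j not in parent else find(j)
    for j, root in assignment.items():
        systems.setdefault(root, []).append(j)
    return sorted(systems.values(), key=lambda c: min(c))


def mcl_cluster(
    graph: SimilarityGraph, settings: MCLSettings | None = None
) -> list[Tribe]:
    """Cluster the similarity graph into tribes.

    The output is always a partition of the node set; a non-converged
    iteration logs a warning and clusters are read from the final matrix.
    Tribe ids are assigned deterministically, ordered by each tribe's
    smallest member id.
    """
    if len(graph) == 0:
        raise ValidationError("cannot cluster an empty graph")
    settings = settings or MCLSettings()
    weights, order = graph.to_matrix()
    limit, converged = mcl_matrix(weights, settings)
    if not converged:
        logger.warning(
            "MCL did not converge within %d iterations; clustering the "
            "final matrix",
            settings.max_iterations,
        )
    clusters = _clusters_from_limit(limit, settings.prune_threshold)
    member_sets = sorted(
        (frozenset(order[i] for i in c) for c in clusters),
        key=lambda s: min(s),
    )
    width = max(4, len(str(len(member_sets))))
    return [
        Tribe(tribe_id=f"T{k:0{width}d}", members=s)
        for k, s in enumerate(member_sets, start=1)
    ]


# ---------------------------------------------------------------------------
# Copy-number logic


def copy_number_profiles(
    tribes: Iterable[Tribe], genome_map: Mapping[str, str]
) -> list[CopyNumberProfile]:
    """Exact per-genome member counts for each tribe."""
    out = []
    for tribe in tribes:
        counts: dict[str, int] = {}
        for gene in tribe.members:
            if gene not in genome_map:
                raise ValidationError(
                    f"gene {gene!r} in tribe {tribe.tribe_id} missing from genome map"
                )
            counts[genome_map[gene]] = counts.get(genome_map[gene], 0) + 1
        out.append(CopyNumberProfile(tribe_id=tribe.tribe_id, counts=counts))
    return out


def shared_single_copy(
    profiles: Iterable[CopyNumberProfile],
    genome_subset: Sequence[str],
    require_absent_elsewhere: bool = False,
) -> list[str]:
    """Tribes with exactly one member in every genome of the subset.

    By default genomes outside the subset are unconstrained (matching
    per-subset intersection counting); with ``require_absent_elsewhere``
    they must contribute zero members.
    """
    subset = list(genome_subset)
    if not subset:
        raise ValidationError("genome subset must be non-empty")
    profiles = list(profiles)
    known = {g for p in profiles for g in p.counts}
    unknown = [g for g in subset if g not in known]
    if unknown:
        raise ValidationError(f"unknown genome label(s): {', '.join(unknown)}")
    out = []
    for p in profiles:
        if any(p.count(g) != 1 for g in subset):
            continue
        if require_absent_elsewhere and any(
            c > 0 for g, c in p.counts.items() if g not in subset
        ):
            continue
        out.append(p.tribe_id)
    return out


def presence_counts(
    single_copy_tribes: Iterable[str],
    hit_table: Mapping[str, Iterable[str]],
    taxon_metadata: Mapping[str, "TaxonMetadata"],
) -> dict[str, int]:
    """Per lineage group, the number of tribes hit by >= 1 taxon of that group.

    ``hit_table`` maps tribe id -> taxa with at least one hit.  A tribe
    hit by several taxa of one group counts once for that group.
    """
    tribes = set(single_copy_tribes)
    counts: dict[str, int] = {}
    for tribe, taxa in hit_table.items():
        if tribe not in tribes:
            continue
        groups = set()
        for taxon in taxa:
            if taxon not in taxon_metadata:
                raise ValidationError(f"taxon {taxon!r} missing from metadata")
            groups.add(taxon_metadata[taxon].lineage_group)
        for g in groups:
            counts[g] = counts.get(g, 0) + 1
    return counts
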