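# Methods

This note records the models, conventions and design decisions behind
`sscphylo`, in the order the pipeline runs.

## Similarity graph and tribe circumscription

The clustering substrate is an undirected graph over genes. For each
ordered pair of genes only the best (lowest-E) hit is kept — multiple
HSPs for the same pair carry no extra information for clustering — and
hits with E above an inclusion cutoff (default 1e-5, configurable) are
discarded, as are self-hits. Each direction contributes −log₁₀ E; the
undirected edge weight is the mean of the directions present, so a
one-sided hit is used as-is. E = 0 is replaced by a cap (default 200,
roughly the −log₁₀ of the smallest E-value search tools print
distinguishably), which also bounds all weights.

MCL is run on the dense column-stochastic matrix: self-loops equal to
each node's maximum incident weight (1.0 for isolated nodes) are added
before normalization — the standard way to damp odd-length alternation —
then expansion (matrix squaring) alternates with inflation (entrywise
power I, default 3.0, then column renormalization). Entries are pruned
below 1e-5 *after* renormalization: pruning raw powered values would
empty whole columns at high inflation, where uniform columns legally
fall below any absolute threshold. Iteration stops when the max
entrywise change drops below 1e-6 or after 100 iterations (then a
warning is logged and clusters are read from the final matrix).
Clusters are attractor-reachability components: attractors are nodes
with positive self-flow; attractors feeding a common column are merged;
every node joins the attractor granting it the largest steady-state
mass, ties to the smallest attractor index. Tribe ids are assigned by
sorting clusters on their smallest member id, so output is a
deterministic partition of the node set.

A tribe is *shared single copy* over a genome subset when it has exactly
one member from each subset genome. Genomes outside the subset are
unconstrained by default (this matches per-subset intersection
counting, and makes the count antitone in the subset); a flag switches
to requiring zero members elsewhere. Lineage-presence counting is set
semantics: a tribe counts once per lineage group with at least one
hitting taxon.

## Characterization statistics

Enrichment uses the plain Pearson χ² on each category's 2×2 table
(single-copy in/not-in category vs background in/not-in), without
Yates' continuity correction — the tables involved are large enough
that the correction only biases the statistic. GO-slim categories are
flat labels; no DAG propagation. A gene without annotation in a
namespace counts as "not in category" for every category of that
namespace, and "unknown" categories, when present in the table, are
ordinary categories. The family-wise level (default 0.05) is Bonferroni
divided by the number of categories *within each namespace*, since the
three namespaces ask separate questions. Direction is the sign of the
focal-vs-background proportion difference.

Structural comparisons (exon count, domain count, cDNA length) use
Welch's unequal-variance two-tailed t-test with the Welch–Satterthwaite
degrees of freedom, at a 0.01 cutoff; an option removes intronless
(exon_count = 1) genes from both groups first, to separate the exon
signal from possible retrotransposition. Identical degenerate groups
(zero variance in both) are reported as t = 0, p = 1.

## EST curation

Codon threading maps each amino-acid column to one codon column; a
trailing stop codon on the CDS is stripped before the 3×-length check,
since the protein alignment never contains the stop.

The six elimination criteria run strictly in order: (1) non-seed
plants, resolved through a configurable set of non-seed lineage-group
labels; (2) at least five Ns (threshold configurable); (3) low
similarity, quantified as <50% ungapped identity to the column-majority
consensus — no published number exists for "low", so the threshold is
explicit and configurable; (4) ≥50 aligned bp missing at the 5' or 3'
end, counted as leading/trailing gap-run length within the
start/stop-anchored alignment span (the boundary is inclusive: 50 is
removed, 49 kept); (5) identical sequences deduplicated with preference
transcript_assembly > finished_cdna > genome > est_singleton, ties by
id; (6) hybrid taxa. Criterion 3 is iterated to a fixed point
(consensus recomputed after each removal round): this makes the whole
filter idempotent by construction, which would not hold if a single
consensus were used. Every removal is logged with its criterion and a
detail string; removed and retained records always partition the input.
Removing everything is legal and returns an empty alignment with a
warning.

Private-gap columns — gapped in exactly one sequence — are excised
whole: single-sequence indels in EST data are usually sequencing
artifacts, and removing residues rather than columns would break
columnar homology. Columns with zero or ≥2 gaps are kept.

Duplication screening reads an NJ gene tree. A clade of ≥2 sequences
from a single taxon is a species-specific event (nested duplicate pairs
count even when the taxon has further copies elsewhere). For shared
events, each maximal single-taxon clade is collapsed to one effective
copy; only taxa with ≥2 effective copies can witness a shared
duplication, which is called when two disjoint clades span the same set
of ≥2 such taxa ("parallel clades"). A nested parallel pair whose two
clades are mirror images inside the two clades of a larger event is the
same duplication seen through later speciations and is suppressed; a
genuine nested duplication has both its clades inside one larger clade.
Multi-copy taxa with intermingled copies but no parallel structure fall
back to a shared event over the multi-copy taxa of their smallest
spanning clade, or to species-specific if no other multi-copy taxon is
involved — with a single duplicated taxon there is never evidence for a
shared event.

Supermatrix assembly excludes genes flagged with shared duplications,
chooses one sequence per species per gene by (source preference, most
non-gap columns, shortest tip branch, id), drops taxa with fewer than
`min_genes_per_taxon` (default 6) genes, and re-checks to a fixed point
in the order gene-exclusion → taxon-threshold. Missing gene blocks are
filled with `?`, distinct from the alignment gap `-`. The partition
table reports 1-based inclusive column ranges.

Alignment statistics: a column is variable with ≥2 distinct unambiguous
bases (gaps and ambiguity codes ignored) and parsimony-informative with
≥2 bases each in ≥2 sequences. The PI percentage is rounded to the
nearest integer, matching the usual tabular reporting.

## Phylogenetics

Jukes-Cantor distances use d = −¾ ln(1 − 4p/3) with p the mismatch
fraction over sites where both sequences carry a single unambiguous
base; p ≥ 0.75 has no finite distance and raises an error naming the
pair. Neighbor-joining is the canonical Q-criterion agglomeration with
the Studier–Keppler update; Q ties break on the smallest (row, column)
index pair in the current ordering, and negative branch lengths are
clamped to zero with a log note.

Parsimony uses Fitch scoring with equal weights. IUPAC ambiguity codes
are uncertainty state-sets; gaps and `?` are missing data (the full
set), so they never add steps. Scoring is root-invariant on binary
trees; polytomies are folded child-by-child (an upper bound there —
only binary search trees are scored internally). Per-site bounds are
m = distinct unambiguous states − 1 and M = unambiguous occurrences −
count of the commonest state; CI = m/L, RI = (M−L)/(M−m) (undefined
when M = m), reported to 3 decimals. Both the variant including all
sites and the variant restricted to parsimony-informative sites are
available, because published CI values do not always state which
convention was used.

The heuristic MP search runs random-addition-sequence replicates:
randomized stepwise addition, then TBR branch swapping (every edge
bisected; reconnection across all pairs of edges of the two reduced
subtrees, which contains SPR as the single-leaf case) to a local
optimum, keeping up to a configurable number of equally-parsimonious
trees per replicate, deduplicated by topology; the global best set is
capped (default 1000) so strict consensus stays well-defined. Optional
parsimony ratchet rounds reweight a random 25% of characters ×2 —
the common default of ratchet implementations — swap under the
perturbed weights, then swap again under the original weights and keep
the better result. All randomness flows from one seed; identical seeds
give identical output.

Strict consensus keeps exactly the splits common to all input trees and
is built directly from the split intersection. The bootstrap resamples
columns with replacement; each replicate runs a simple-addition (input
taxon order) search with TBR; tied best trees give fractional credit to
their splits (capped at 1 per replicate). Supports are percentages of
replicates and are written as internal-node labels on the full-data MP
tree.

## Synthetic data

The generators produce the statistical structure the analysis assumes,
with planted truth sufficient to score every downstream stage:

- **Planted-family graphs** — within-family edge weights N(60, 5),
  between-family N(5, 2) truncated at zero, emulating the strong
  bimodality of within- versus between-family protein similarity. A
  ≥5× weight separation is the regime the clustering substitute
  benchmark uses: 10 families across 6 genomes, 100 seeded replicates,
  exact-partition recovery.
- **Gene-family evolution** — duplication and loss as independent
  Poisson processes along each species-tree branch (the simplest
  generative model consistent with observed duplicate patterns).
  Observable planted events are labeled: a duplication on a terminal
  branch (or surviving in one taxon) is species-specific; one whose
  both lineages survive in ≥2 common taxa is shared; duplications whose
  surviving copies no longer overlap in any taxon are unobservable and
  omitted from the truth.
- **JC sequence simulation** — uniform root, per-branch substitution
  probability ¾(1 − e^(−4t/3)), i.i.d. columns. JC-only (no rate
  heterogeneity or indels): it matches the distance model used
  downstream and keeps oracles closed-form.
- **EST degradation** — per record: end truncation (probability 0.1–0.2
  per record in the bundled settings, uniform 50–120 aligned bp),
  per-base N substitution, identical redundant variants labeled as EST
  singletons, and hybrid-taxon flags. The defect log predicts the first
  criterion each record falls to, applying the same thresholds in
  criterion order, so curation can be checked for exact agreement.
- **Toy study** — an end-to-end bundle: 12 planted families over four
  genomes (9 single-copy), six 400-bp genes over eight taxa (one gene
  evolved with an elevated duplication rate), mild degradation
  (truncation 0.1, ambiguity 0.005/bp, redundancy 0.1, one hybrid
  taxon), and annotations planting a chloroplast over-representation
  and an exon-count excess in the single-copy set. Everything is a pure
  function of the seed.

What passing these closed loops does *not* show: real EST data have
chimeras, frameshifts, alignment errors and rate heterogeneity that the
generators do not model; recovery rates measured here are upper bounds
on real-data behavior, chosen to verify the machinery, not to estimate
field performance.

## Problem sizes and runtime choices

The validation suites use sizes at which exact oracles exist or planted
truth is unambiguous: exhaustive MP enumeration up to 6 taxa (105
topologies), NJ additivity on 8-taxon trees, duplication screening on a
6-taxon species tree with 1000-bp genes, curation agreement on ~500
records, calibration with 1000 null simulations, and a 100-replicate
clustering benchmark. These sizes keep the full test suite and the
acceptance script each well under a minute on one CPU while leaving no
stochastic assertion near its threshold.

## Known limitations

- MCL is dense-matrix; fine for thousands of genes, not for full
  multi-proteome runs (sparse expansion would be the next step).
- The MP search is exact only in reach, not guarantee: TBR hill
  climbing with random additions and ratchet is a heuristic, and
  plateau exploration of equally-parsimonious trees is bounded.
- Duplication screening interprets one gene tree at a time; it does not
  reconcile against a dated species tree, so a duplication followed by
  heavy loss can be misread as species-specific (by design, matching
  what the tree alone can witness).
- Maximum-likelihood analyses, model selection and alignment inference
  are out of scope; alignments are consumed, not produced.
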