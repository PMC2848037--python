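"""Curate an EST-style alignment with the six elimination criteria.

Simulates a clean gene alignment, degrades it the way EST data degrade
(end truncation, ambiguous base runs, redundant identical variants),
then filters: (1) non-seed plants, (2) >= 5 Ns, (3) low consensus
similarity, (4) >= 50 aligned bp missing from an end, (5) duplicates
(transcript assemblies preferred), (6) hybrids.  Columns gapped in
exactly one sequence are excised afterwards.
"""

import dendropy
import sscphylo as s

tips = ",".join(f"X{i}:0.03" for i in range(20))
tree = dendropy.Tree.get(data=f"({tips}):0.0;", schema="newick")
clean = s.simulate_jc_alignment(tree, 300, seed=3)

spec = s.DegradationSpec(p_truncate=0.2, ambiguity_rate=0.01,
                         p_redundant=0.15, hybrid_taxa=frozenset({"X4"}),
                         seed=9)
degraded, predicted = s.degrade_to_ests(list(clean), spec)
print(f"{len(degraded)} records after degradation "
      f"({len(degraded) - len(clean)} redundant variants added)")

meta = {r.taxon: s.TaxonMetadata(r.taxon, is_hybrid=(r.taxon == "X4"))
        for r in degraded}
filtered, log = s.filter_sequences(s.Alignment(degraded), meta)
print(f"kept {len(filtered)}, removed {len(log.entries)}:")
for e in log.entries:
    print(f"  {e.seq_id}: criterion {e.criterion} ({e.detail})")

agree = {e.seq_id: e.criterion for e in log.entries} == predicted
print(f"removals match the planted defect log exactly: {agree}")

stripped = s.strip_private_gap_columns(filtered)
print(f"private-gap columns excised: {filtered.length - stripped.length} "
      f"({filtered.length} -> {stripped.length} columns)")
stats = s.alignment_stats(stripped)
print(f"curated alignment: {stats.n_seq} seqs x {stats.n_columns} nt, "
      f"{stats.n_variable} variable, {stats.n_parsimony_informative} "
      f"parsimony-informative ({stats.pct_parsimony_informative}%)")
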