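"""Codon threading, the six elimination criteria, duplication screening,
supermatrix assembly and alignment statistics."""

import dendropy
import numpy as np
import pytest

from sscphylo import (
    Alignment,
    CurationCriteria,
    SequenceRecord,
    SupermatrixSpec,
    TaxonMetadata,
    ValidationError,
    alignment_stats,
    backtranslate_alignment,
    detect_duplications,
    filter_sequences,
    select_supermatrix,
    strip_private_gap_columns,
)


def nuc(seq_id, residues, taxon=None, source="transcript_assembly"):
    return SequenceRecord(id=seq_id, residues=residues, taxon=taxon or seq_id,
                          source_type=source)


def prot(seq_id, residues):
    return SequenceRecord(id=seq_id, residues=residues, molecule="protein")


class TestBacktranslate:
    def test_gap_becomes_triple_gap(self):
        aln = backtranslate_alignment(
            Alignment([prot("x", "M-K")]), {"x": "ATGAAA"}
        )
        assert aln["x"].residues == "ATG---AAA"

    def test_all_gap_row(self):
        aln = backtranslate_alignment(
            Alignment([prot("x", "MK"), prot("y", "--")]),
            {"x": "ATGAAA", "y": ""},
        )
        assert aln["y"].residues == "------"

    def test_trailing_stop_stripped(self):
        aln = backtranslate_alignment(
            Alignment([prot("x", "MK")]), {"x": "ATGAAATAA"}
        )
        assert aln["x"].residues == "ATGAAA"

    def test_length_mismatch_names_sequence(self):
        with pytest.raises(ValidationError, match="x"):
            backtranslate_alignment(Alignment([prot("x", "MKW")]),
                                    {"x": "ATGAAA"})

    def test_bad_codon_character(self):
        with pytest.raises(ValidationError, match="x"):
            backtranslate_alignment(Alignment([prot("x", "MK")]),
                                    {"x": "ATG@AA"})


class TestFilterSequences:
    BASE = "ACGT" * 30  # 120 bp

    def _meta(self, recs, non_seed=(), hybrids=()):
        return {
            r.taxon: TaxonMetadata(
                r.taxon,
                lineage_group="Mosses" if r.taxon in non_seed else "Eurosids",
                is_hybrid=r.taxon in hybrids,
            )
            for r in recs
        }

    def test_non_seed_removed_first(self):
        recs = [nuc("ok", self.BASE), nuc("moss", self.BASE, taxon="moss")]
        meta = self._meta(recs, non_seed=("moss",))
        filtered, log = filter_sequences(Alignment(recs), meta)
        assert filtered.ids() == ["ok"]
        assert [(e.seq_id, e.criterion) for e in log.entries] == [("moss", 1)]

    def test_five_ambiguous_bases_boundary(self):
        recs = [
            nuc("ok", self.BASE),
            nuc("ok2", "T" + self.BASE[1:]),
            nuc("n5", "NNNNN" + self.BASE[5:]),
            nuc("n4", "NNNN" + self.BASE[4:]),
        ]
        filtered, log = filter_sequences(Alignment(recs), self._meta(recs))
        assert "n5" not in filtered.ids() and "n4" in filtered.ids()
        assert log.by_criterion(2)[0].seq_id == "n5"

    def test_truncation_boundary_50_vs_49(self):
        recs = [
            nuc("ok", self.BASE),
            nuc("ok2", "T" + self.BASE[1:]),
            nuc("t50", "-" * 50 + self.BASE[50:]),
            nuc("t49", "-" * 49 + self.BASE[49:]),
            nuc("t50r", self.BASE[:-50] + "-" * 50),
        ]
        filtered, log = filter_sequences(Alignment(recs), self._meta(recs))
        assert set(filtered.ids()) == {"ok", "ok2", "t49"}
        assert {e.seq_id for e in log.by_criterion(4)} == {"t50", "t50r"}

    def test_low_similarity_removed(self):
        scrambled = "TGCA" * 30  # 0% identity to the ACGT-consensus
        recs = [
            nuc("a", self.BASE), nuc("b", self.BASE),
            nuc("c", "T" + self.BASE[1:]), nuc("junk", scrambled),
        ]
        filtered, log = filter_sequences(Alignment(recs), self._meta(recs))
        assert "junk" not in filtered.ids()
        assert log.by_criterion(3)[0].seq_id == "junk"

    def test_dedup_prefers_transcript_assembly(self):
        recs = [
            nuc("ta", self.BASE, source="transcript_assembly"),
            nuc("est", self.BASE, source="est_singleton"),
            nuc("other", "T" + self.BASE[1:]),
        ]
        filtered, log = filter_sequences(Alignment(recs), self._meta(recs))
        assert "ta" in filtered.ids() and "est" not in filtered.ids()
        (entry,) = log.by_criterion(5)
        assert entry.seq_id == "est" and "ta" in entry.detail

    def test_hybrid_removed_last(self):
        recs = [
            nuc("ok", self.BASE),
            nuc("ok2", "T" + self.BASE[1:]),
            nuc("hyb", "G" + self.BASE[1:], taxon="hyb"),
        ]
        meta = self._meta(recs, hybrids=("hyb",))
        filtered, log = filter_sequences(Alignment(recs), meta)
        assert "hyb" not in filtered.ids()
        assert log.by_criterion(6)[0].seq_id == "hyb"

    def test_partition_invariant_and_idempotence(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), size=200))
        recs = []
        for i in range(30):
            res = list(base)
            for j in rng.choice(200, size=10, replace=False):
                res[j] = "ACGT"[rng.integers(4)]
            if i % 7 == 0:
                res[:55] = "-" * 55
            if i % 11 == 0:
                res[60:66] = "N" * 6
            recs.append(nuc(f"s{i:02d}", "".join(res), taxon=f"x{i:02d}"))
        meta = self._meta(recs, non_seed=("x03",), hybrids=("x05",))
        aln = Alignment(recs)
        filtered, log = filter_sequences(aln, meta)
        # removed and retained partition the input
        assert log.removed_ids() | set(filtered.ids()) == set(aln.ids())
        assert log.removed_ids() & set(filtered.ids()) == set()
        # a second pass removes nothing
        refiltered, log2 = filter_sequences(filtered, meta)
        assert log2.entries == []
        assert refiltered.ids() == filtered.ids()

    def test_all_removed_returns_empty(self):
        recs = [nuc("m1", self.BASE, taxon="m1"), nuc("m2", self.BASE, taxon="m2")]
        meta = self._meta(recs, non_seed=("m1", "m2"))
        filtered, log = filter_sequences(Alignment(recs), meta)
        assert len(filtered) == 0
        assert log.removed_ids() == {"m1", "m2"}


class TestPrivateGaps:
    def test_single_gap_column_removed(self):
        aln = Alignment([nuc("a", "A-GT"), nuc("b", "ACGT"),
                         nuc("c", "ACGT"), nuc("d", "ACGT")])
        out = strip_private_gap_columns(aln)
        assert out.length == 3
        assert out["a"].residues == "AGT" and out["b"].residues == "AGT"

    def test_shared_gap_column_retained(self):
        aln = Alignment([nuc("a", "A-GT"), nuc("b", "A-GT"), nuc("c", "ACGT")])
        out = strip_private_gap_columns(aln)
        assert out.length == 4

    def test_gap_free_unchanged(self):
        aln = Alignment([nuc("a", "ACGT"), nuc("b", "AGGT")])
        out = strip_private_gap_columns(aln)
        assert [r.residues for r in out] == ["ACGT", "AGGT"]

    def test_never_leaves_private_gap_columns(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, L = int(rng.integers(3, 8)), int(rng.integers(5, 30))
            rows = [
                "".join(rng.choice(list("ACGT-"), size=L)) for _ in range(n)
            ]
            rows = [r if r.strip("-") else "A" * L for r in rows]
            aln = Alignment([nuc(f"s{i}", r) for i, r in enumerate(rows)])
            out = strip_private_gap_columns(aln)
            assert out.length <= aln.length
            arr = np.array([list(r.residues) for r in out])
            if arr.size:
                assert not ((arr == "-").sum(axis=0) == 1).any()


class TestDetectDuplications:
    def test_species_specific_cherry(self):
        tree = dendropy.Tree.get(data="((X1,X2),(Y1,Z1));", schema="newick")
        events = detect_duplications(
            tree, {"X1": "X", "X2": "X", "Y1": "Y", "Z1": "Z"}
        )
        assert [(e.classification, set(e.taxa)) for e in events] == [
            ("species_specific", {"X"})
        ]

    def test_shared_parallel_clades(self):
        tree = dendropy.Tree.get(data="((X1,Y1),(X2,Y2));", schema="newick")
        events = detect_duplications(
            tree, {"X1": "X", "X2": "X", "Y1": "Y", "Y2": "Y"}
        )
        assert [(e.classification, set(e.taxa)) for e in events] == [
            ("shared", {"X", "Y"})
        ]

    def test_no_multicopy_taxon_no_events(self):
        tree = dendropy.Tree.get(data="((A1,B1),(C1,D1));", schema="newick")
        assert detect_duplications(
            tree, {"A1": "A", "B1": "B", "C1": "C", "D1": "D"}
        ) == []

    def test_unmapped_tip_rejected(self):
        tree = dendropy.Tree.get(data="((X1,X2),(Y1,Z1));", schema="newick")
        with pytest.raises(ValidationError, match="Z1"):
            detect_duplications(tree, {"X1": "X", "X2": "X", "Y1": "Y"})

    def test_nested_duplication_both_events(self):
        tree = dendropy.Tree.get(
            data="(((A1,B1),(C1,D1)),((A2,B2),((C2,D2),(C3,D3))));",
            schema="newick",
        )
        mapping = {x: x[0] for x in
                   "A1 B1 C1 D1 A2 B2 C2 D2 C3 D3".split()}
        events = {(e.classification, frozenset(e.taxa))
                  for e in detect_duplications(tree, mapping)}
        assert events == {
            ("shared", frozenset("ABCD")),
            ("shared", frozenset("CD")),
        }

    def test_planted_truth_recovery_rate(self):
        """Classification from NJ trees of 1000-bp JC alignments matches
        the planted truth in >= 90% of simulated families."""
        import sscphylo as s

        sp = ("(((A:0.06,B:0.06):0.05,(C:0.06,D:0.06):0.05):0.04,"
              "(E:0.08,F:0.08):0.07):0.0;")
        rng = np.random.default_rng(11)
        n_match = n_tot = 0
        attempts = 0
        while n_tot < 200 and attempts < 1200:
            attempts += 1
            spec = s.EvolutionSpec(
                species_tree=sp, duplication_rate=0.6, loss_rate=0.1,
                sequence_length=1000, seed=int(rng.integers(2**31)),
            )
            gtree, counts, truth = s.evolve_gene_family(spec)
            seed2 = int(rng.integers(2**31))
            if not truth or sum(counts.values()) < 3:
                continue
            aln = s.simulate_jc_alignment(gtree, 1000, seed2)
            est = s.neighbor_joining(s.jc_distance(aln))
            events = detect_duplications(est, {r.id: r.taxon for r in aln})
            planted = {(e.classification, e.taxa) for e in truth}
            got = {(e.classification, e.taxa) for e in events}
            n_tot += 1
            n_match += planted == got
        assert n_tot == 200
        assert n_match / n_tot >= 0.90


class TestSupermatrix:
    def _gene(self, gene, taxa, length=12, rng=None, sources=None):
        rng = rng or np.random.default_rng(0)
        recs = []
        for t in taxa:
            res = "".join(rng.choice(list("ACGT"), size=length))
            recs.append(
                SequenceRecord(
                    id=f"{gene}_{t}", residues=res, taxon=t,
                    source_type=(sources or {}).get(t, "transcript_assembly"),
                )
            )
        return Alignment(recs)

    def test_taxon_below_min_genes_dropped(self):
        rng = np.random.default_rng(2)
        taxa_full = [f"T{i}" for i in range(8)]
        genes = {}
        for k in range(13):
            # T7 present in only 5 genes
            taxa = taxa_full if k < 5 else taxa_full[:-1]
            genes[f"g{k:02d}"] = self._gene(f"g{k:02d}", taxa, rng=rng)
        matrix, spec = select_supermatrix(genes, {}, SupermatrixSpec())
        assert "T7" not in matrix.ids()
        assert set(matrix.ids()) == set(taxa_full[:-1])

    def test_flagged_gene_excluded_and_width(self):
        rng = np.random.default_rng(3)
        taxa = [f"T{i}" for i in range(6)]
        genes = {f"g{k}": self._gene(f"g{k}", taxa, length=10 + k, rng=rng)
                 for k in range(8)}
        matrix, spec = select_supermatrix(
            genes, {"g3": True}, SupermatrixSpec(min_genes_per_taxon=6)
        )
        assert ("g3", "shared duplication") in spec.excluded_genes
        included = [g for g, _, _ in spec.partitions]
        assert "g3" not in included
        assert matrix.length == sum(
            genes[g].length for g in included
        ) == spec.width

    def test_coverage_preference(self):
        taxa = ["T1"]
        rec_hi = SequenceRecord(id="g_a", residues="ACGTACGTAC", taxon="T1")
        rec_lo = SequenceRecord(id="g_b", residues="ACG---GTAC", taxon="T1")
        genes = {
            "g": Alignment([rec_hi, rec_lo]),
        }
        matrix, _ = select_supermatrix(
            genes, {}, SupermatrixSpec(min_genes_per_taxon=1)
        )
        assert matrix["T1"].residues == "ACGTACGTAC"

    def test_source_preference_beats_coverage(self):
        rec_ta = SequenceRecord(id="g_a", residues="ACG---GTAC", taxon="T1",
                                source_type="transcript_assembly")
        rec_est = SequenceRecord(id="g_b", residues="ACGTACGTAC", taxon="T1",
                                 source_type="est_singleton")
        matrix, _ = select_supermatrix(
            {"g": Alignment([rec_ta, rec_est])}, {},
            SupermatrixSpec(min_genes_per_taxon=1),
        )
        assert matrix["T1"].residues == "ACG---GTAC"

    def test_branch_length_breaks_ties(self):
        rec_a = SequenceRecord(id="g_a", residues="ACGTACGTAC", taxon="T1")
        rec_b = SequenceRecord(id="g_b", residues="TCGTACGTAC", taxon="T1")
        matrix, _ = select_supermatrix(
            {"g": Alignment([rec_a, rec_b])}, {},
            SupermatrixSpec(min_genes_per_taxon=1),
            branch_lengths={"g": {"g_a": 0.5, "g_b": 0.1}},
        )
        assert matrix["T1"].residues == "TCGTACGTAC"

    def test_missing_blocks_filled_with_question_marks(self):
        rng = np.random.default_rng(4)
        g1 = self._gene("g1", ["T1", "T2"], rng=rng)
        g2 = self._gene("g2", ["T1"], rng=rng)
        matrix, spec = select_supermatrix(
            {"g1": g1, "g2": g2}, {}, SupermatrixSpec(min_genes_per_taxon=1)
        )
        t2 = matrix["T2"].residues
        (_, start, end) = [p for p in spec.partitions if p[0] == "g2"][0]
        assert t2[start - 1 : end] == "?" * (end - start + 1)

    def test_matches_brute_force_rule_application(self):
        """Retained taxa and genes equal an independent application of the
        three inclusion criteria on a planted 10-gene x 20-taxon set."""
        rng = np.random.default_rng(5)
        taxa = [f"T{i:02d}" for i in range(20)]
        genes = {}
        presence = {}
        flags = {}
        for k in range(10):
            keep = [t for t in taxa if rng.random() < 0.6]
            if len(keep) < 2:
                keep = taxa[:2]
            gene = f"g{k:02d}"
            genes[gene] = self._gene(gene, keep, rng=rng)
            presence[gene] = set(keep)
            flags[gene] = bool(rng.random() < 0.2)
        spec_in = SupermatrixSpec(min_genes_per_taxon=4)
        matrix, spec_out = select_supermatrix(genes, flags, spec_in)

        # brute force: criterion 1 then iterate criterion 2
        inc_genes = sorted(g for g in genes if not flags[g])
        keep_taxa = set(taxa)
        while True:
            counts = {
                t: sum(t in presence[g] for g in inc_genes) for t in keep_taxa
            }
            drop = {t for t in keep_taxa if counts[t] < 4}
            if not drop:
                break
            keep_taxa -= drop
        assert set(matrix.ids()) == keep_taxa
        assert [g for g, _, _ in spec_out.partitions] == inc_genes

    def test_no_surviving_taxon_raises(self):
        g = self._gene("g1", ["T1"])
        with pytest.raises(ValidationError):
            select_supermatrix({"g1": g}, {}, SupermatrixSpec(min_genes_per_taxon=6))


class TestAlignmentStats:
    def test_hand_enumerated_counts(self, small_nuc_alignment):
        stats = alignment_stats(small_nuc_alignment)
        assert stats.n_seq == 4 and stats.n_columns == 4
        assert stats.n_variable == 2
        assert stats.n_parsimony_informative == 2
        assert stats.pct_parsimony_informative == 50

    def test_identical_sequences_zero_counts(self):
        aln = Alignment([nuc("a", "ACGT"), nuc("b", "ACGT")])
        stats = alignment_stats(aln)
        assert stats.n_variable == 0 and stats.n_parsimony_informative == 0

    def test_gaps_and_ambiguity_ignored(self):
        aln = Alignment([nuc("a", "A-NT"), nuc("b", "AC-T"),
                         nuc("c", "ACGT"), nuc("d", "GCGA")])
        stats = alignment_stats(aln)
        # col1 A/A/A/G var not PI; col2 C/C/C; col3 G/G; col4 T/T/T/A var not PI
        assert stats.n_variable == 2
        assert stats.n_parsimony_informative == 0

    def test_pi_subset_of_variable_property(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n, L = int(rng.integers(2, 10)), int(rng.integers(4, 60))
            rows = ["".join(rng.choice(list("ACGTN-"), size=L)) for _ in range(n)]
            rows = [r if set(r) - set("N-") else "ACGT" * (L // 4 + 1) for r in rows]
            rows = [r[:L] for r in rows]
            aln = Alignment([nuc(f"s{i}", r) for i, r in enumerate(rows)])
            stats = alignment_stats(aln)
            assert stats.n_parsimony_informative <= stats.n_variable

    def test_empty_alignment_raises(self):
        with pytest.raises(ValidationError):
            alignment_stats(Alignment([]))
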