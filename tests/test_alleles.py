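import numpy as np
import pandas as pd
import pytest

from crisprtile.alleles import (
    AlleleTableFormatError,
    Category,
    FilterDecision,
    MutationEvent,
    ObservedAllele,
    background_filter,
    classify_allele,
    collapse_by_translation,
    extract_events,
    merge_technical_replicates,
    proximity_filter,
    read_allele_table,
)


def _allele(read, ref, reads=1):
    return ObservedAllele(aligned_read=read, aligned_ref=ref, reads=reads)


class TestReadAlleleTable:
    def _write(self, tmp_path, df):
        p = tmp_path / "alleles.tsv"
        df.to_csv(p, sep="\t", index=False)
        return p

    def test_counts_preserved(self, tmp_path):
        df = pd.DataFrame(
            {
                "Aligned_Sequence": ["ACGT", "AC-T", "ACGGT"],
                "Reference_Sequence": ["ACGT", "ACGT", "ACG-T"],
                "#Reads": [100, 30, 7],
                "%Reads": [73.0, 21.9, 5.1],
            }
        )
        alleles = read_allele_table(self._write(tmp_path, df), "s1")
        assert len(alleles) == 3
        assert sum(a.reads for a in alleles) == 137
        assert all(a.sample_id == "s1" for a in alleles)

    def test_missing_column_named_in_error(self, tmp_path):
        df = pd.DataFrame({"Aligned_Sequence": ["ACGT"], "#Reads": [1]})
        with pytest.raises(AlleleTableFormatError, match="Reference_Sequence"):
            read_allele_table(self._write(tmp_path, df), "s1")

    def test_mismatched_gapped_lengths_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"Aligned_Sequence": ["ACG"], "Reference_Sequence": ["ACGT"], "#Reads": [1]}
        )
        with pytest.raises(AlleleTableFormatError):
            read_allele_table(self._write(tmp_path, df), "s1")

    def test_non_integer_count_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"Aligned_Sequence": ["ACGT"], "Reference_Sequence": ["ACGT"], "#Reads": [1.5]}
        )
        with pytest.raises(AlleleTableFormatError, match="row 0"):
            read_allele_table(self._write(tmp_path, df), "s1")

    def test_empty_table_gives_empty_list(self, tmp_path):
        df = pd.DataFrame(
            {"Aligned_Sequence": [], "Reference_Sequence": [], "#Reads": []}
        )
        assert read_allele_table(self._write(tmp_path, df), "s1") == []


class TestExtractEvents:
    @pytest.mark.parametrize(
        "read,ref,expected",
        [
            # one 2-column deletion
            ("AC--GT", "ACTAGT", [("deletion", (2, 4), "")]),
            # deletion, 4 matches, deletion: two distinct events
            ("A-CGTA-T", "ATCGTACT", [("deletion", (1, 2), ""), ("deletion", (6, 7), "")]),
            # two adjacent mismatches merge into one substitution run
            ("ATTA", "ACGA", [("substitution", (1, 3), "TT")]),
            # insertion carries its point and sequence
            ("ACGGGT", "AC--GT", [("insertion", (2, 2), "GG")]),
            # unedited
            ("ACGT", "ACGT", []),
        ],
    )
    def test_run_decomposition(self, read, ref, expected):
        events = extract_events(_allele(read, ref))
        assert [(e.kind, e.ref_interval, e.alt_seq) for e in events] == expected

    def test_sizes(self):
        ev = extract_events(_allele("AC--GT", "ACTAGT"))[0]
        assert ev.size == -2
        ev = extract_events(_allele("ACGGGT", "AC--GT"))[0]
        assert ev.size == 2
        ev = extract_events(_allele("ATTA", "ACGA"))[0]
        assert ev.size == 0


class TestProximityFilter:
    def test_deletion_boundary_2bp_from_cut_kept(self):
        # deletion over bases 10-14; cut at 16 is 2 bp from the last base
        ev = [MutationEvent("deletion", (10, 14), "")]
        assert proximity_filter(ev, [16], radius=2) == FilterDecision.KEEP

    def test_distal_substitution_dropped(self):
        ev = [MutationEvent("substitution", (10, 11), "A")]
        assert proximity_filter(ev, [30], radius=2) == FilterDecision.DROP_DISTAL

    def test_two_events_near_cuts_dropped_complex(self):
        ev = [
            MutationEvent("deletion", (10, 12), ""),
            MutationEvent("deletion", (30, 33), ""),
        ]
        assert proximity_filter(ev, [11, 31], radius=2) == FilterDecision.DROP_COMPLEX

    def test_zero_events_kept_as_unedited(self):
        assert proximity_filter([], [10]) == FilterDecision.KEEP

    def test_insertion_uses_insertion_point(self):
        ev = [MutationEvent("insertion", (12, 12), "AA")]
        assert proximity_filter(ev, [10], radius=2) == FilterDecision.KEEP
        assert proximity_filter(ev, [9], radius=2) == FilterDecision.DROP_DISTAL

    def test_monotone_in_radius(self, rng):
        """keep(r) implies keep(r') for r' >= r, single-event alleles."""
        for _ in range(200):
            s = int(rng.integers(0, 50))
            e = s + int(rng.integers(1, 10))
            cut = int(rng.integers(0, 60))
            ev = [MutationEvent("deletion", (s, e), "")]
            kept = [proximity_filter(ev, [cut], radius=r) == FilterDecision.KEEP for r in range(6)]
            assert kept == sorted(kept)  # False..False True..True


class TestMergeTechnicalReplicates:
    def test_counts_summed(self):
        t1 = [_allele("AC-T", "ACGT", 10)]
        t2 = [_allele("AC-T", "ACGT", 15), _allele("ACGT", "ACGT", 5)]
        merged = merge_technical_replicates([t1, t2])
        by_key = {a.key: a.reads for a in merged}
        assert by_key[("AC-T", "ACGT")] == 25
        assert by_key[("ACGT", "ACGT")] == 5

    def test_single_table_identity(self):
        t1 = [_allele("ACGT", "ACGT", 3)]
        assert merge_technical_replicates([t1]) == t1

    def test_mixed_amplicons_rejected(self):
        t1 = [_allele("ACGT", "ACGT", 1)]
        t2 = [_allele("TTTT", "TTTT", 1)]
        with pytest.raises(ValueError):
            merge_technical_replicates([t1, t2])


class TestClassifyAllele:
    """Category precedence on the toy single-exon model (start codon at 0-3,
    donor window 57-62)."""

    def _del(self, model, pos, length):
        ref = model.amplicon_seq
        return _allele(ref[:pos] + "-" * length + ref[pos + length :], ref)

    def test_start_codon_deletion_wins(self, toy_model):
        # deletion covering one base of ATG: start-codon rule beats frame rule
        ca = classify_allele(self._del(toy_model, 2, 3), toy_model)
        assert ca.category == Category.START_CODON_DELETION

    def test_start_codon_substitution_counts_as_mutagenized(self, toy_model):
        ref = toy_model.amplicon_seq
        read = ref[:1] + "C" + ref[2:]  # T of ATG -> C
        ca = classify_allele(_allele(read, ref), toy_model)
        assert ca.category == Category.START_CODON_DELETION

    def test_splice_window_deletion(self, toy_model):
        # 3-nt deletion touching donor position -1 (nt 57-59)
        ca = classify_allele(self._del(toy_model, 57, 3), toy_model)
        assert ca.category == Category.SPLICING_VARIANT

    def test_frame_shift(self, toy_model):
        ca = classify_allele(self._del(toy_model, 20, 4), toy_model)
        assert ca.category == Category.FRAME_SHIFT
        assert ca.net_indel == -4

    def test_in_frame(self, toy_model):
        ca = classify_allele(self._del(toy_model, 12, 3), toy_model)
        assert ca.category == Category.IN_FRAME

    def test_de_novo_stop_from_insertion(self, toy_model):
        ref = toy_model.amplicon_seq
        # in-frame +3 insertion of TAA at a codon boundary (nt 12)
        read = ref[:12] + "TAA" + ref[12:]
        aref = ref[:12] + "---" + ref[12:]
        ca = classify_allele(_allele(read, aref), toy_model)
        assert ca.category == Category.DE_NOVO_STOP
        assert ca.protein_alignment.premature_stop

    def test_unedited(self, toy_model):
        ref = toy_model.amplicon_seq
        ca = classify_allele(_allele(ref, ref), toy_model)
        assert ca.category == Category.UNEDITED
        assert ca.protein_alignment.is_identity

    def test_substitution_only_allele_in_frame(self, toy_model):
        # synonymous-style single-nt substitution mid-exon: net 0, no stop
        ref = toy_model.amplicon_seq
        read = ref[:31] + ("A" if ref[31] != "A" else "G") + ref[32:]
        ca = classify_allele(_allele(read, ref), toy_model)
        assert ca.category in (Category.IN_FRAME, Category.DE_NOVO_STOP)
        assert ca.net_indel == 0


class TestCollapse:
    def test_identical_translations_merge_with_summed_counts(self, toy_model):
        ref = toy_model.amplicon_seq
        # two nucleotide-distinct 3-nt deletions with the same single-residue
        # deletion (offsets 13 and 14 both collapse codons 5/6 to E)
        a1 = _allele(ref[:13] + "---" + ref[16:], ref)
        a2 = _allele(ref[:14] + "---" + ref[17:], ref)
        c1 = classify_allele(a1, toy_model)
        c2 = classify_allele(a2, toy_model)
        assert c1.protein_alignment.key() == c2.protein_alignment.key()
        counts = pd.DataFrame({"s1": [100, 50]}, index=[a1.uid, a2.uid])
        out = collapse_by_translation([c1, c2], counts, enabled=True)
        assert len(out) == 1
        assert out["s1"].iloc[0] == 150

    def test_disabled_keeps_nucleotide_identity(self, toy_model):
        ref = toy_model.amplicon_seq
        a1 = _allele(ref[:13] + "---" + ref[16:], ref)
        a2 = _allele(ref[:14] + "---" + ref[17:], ref)
        c1, c2 = (classify_allele(a, toy_model) for a in (a1, a2))
        counts = pd.DataFrame({"s1": [100, 50]}, index=[a1.uid, a2.uid])
        out = collapse_by_translation([c1, c2], counts, enabled=False)
        assert len(out) == 2
        assert out["s1"].sum() == 150

    def test_total_reads_conserved(self, toy_model, rng):
        ref = toy_model.amplicon_seq
        alleles, cas = [], []
        for pos in range(5, 50, 3):
            a = _allele(ref[:pos] + "---" + ref[pos + 3 :], ref)
            alleles.append(a)
            cas.append(classify_allele(a, toy_model))
        counts = pd.DataFrame(
            {f"s{j}": rng.integers(0, 1000, len(alleles)) for j in range(3)},
            index=[a.uid for a in alleles],
        )
        out = collapse_by_translation(cas, counts, enabled=True)
        for j in range(3):
            assert out[f"s{j}"].sum() == counts[f"s{j}"].sum()


class TestBackgroundFilter:
    def test_allele_at_or_below_control_flagged(self):
        table = pd.DataFrame({"s1": [2, 98]}, index=["mut", "wt"])
        control = pd.Series({"mut": 0.03, "wt": 0.97})
        flags = background_filter(table, ["s1"], control)
        assert bool(flags.loc["mut", "s1"])  # 2% <= 3% in control

    def test_allele_absent_from_control_not_flagged(self):
        table = pd.DataFrame({"s1": [2, 98]}, index=["mut", "wt"])
        control = pd.Series({"wt": 1.0})
        flags = background_filter(table, ["s1"], control)
        assert not bool(flags.loc["mut", "s1"])
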