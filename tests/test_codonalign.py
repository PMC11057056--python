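"""Back-translation (pal2nal semantics), gap stripping, substitution
classification against the genetic-code oracle, and shared-change tallies."""

import numpy as np
import pytest
from Bio.Seq import Seq

from sawselect.codonalign import (
    CodonAlignment,
    amino_property_change,
    backtranslate,
    classify_substitution,
    shared_substitution_tally,
    strip_gap_columns,
    DEFAULT_PROPERTY_CLASSES,
)
from sawselect.genetics import SENSE_CODONS, STANDARD_AA


class TestBacktranslate:
    def test_worked_toy_case(self):
        aln = backtranslate(
            {"s1": "M-K", "s2": "MAK"},
            {"s1": "ATGAAA", "s2": "ATGGCTAAA"},
        )
        assert aln.rows == ["ATG---AAA", "ATGGCTAAA"]

    def test_roundtrip_translation_identity(self, rng):
        # random protein MSAs with gaps; translate(strip_gaps(backtranslate)) == proteins
        aas = list(STANDARD_AA)
        codons_of = {}
        for codon in SENSE_CODONS:
            codons_of.setdefault(str(Seq(codon).translate()), []).append(codon)
        for _ in range(50):
            n_cols = int(rng.integers(5, 30))
            msa, cds = {}, {}
            for s in range(3):
                cols = [
                    "-" if rng.random() < 0.15 else aas[rng.integers(len(aas))]
                    for _ in range(n_cols)
                ]
                protein = "".join(cols)
                ungapped = protein.replace("-", "")
                cds[f"s{s}"] = "".join(
                    codons_of[aa][rng.integers(len(codons_of[aa]))] for aa in ungapped
                )
                msa[f"s{s}"] = protein
            aln = strip_gap_columns(backtranslate(msa, cds))
            kept_cols = [
                c for c in range(n_cols) if all(msa[f"s{s}"][c] != "-" for s in range(3))
            ]
            for s in range(3):
                back = str(Seq(aln.rows[s]).translate())
                assert back == "".join(msa[f"s{s}"][c] for c in kept_cols)

    def test_terminal_stop_trimmed(self):
        aln = backtranslate({"s1": "MK"}, {"s1": "ATGAAATAA"})
        assert aln.rows == ["ATGAAA"]

    def test_translation_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            backtranslate({"s1": "MK"}, {"s1": "ATGGGG"})

    def test_internal_stop_raises(self):
        with pytest.raises(ValueError, match="stop"):
            backtranslate({"s1": "M*K"}, {"s1": "ATGTAAAAA"})

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            backtranslate({"s1": "MKK"}, {"s1": "ATGAAA"})


class TestStripGapColumns:
    def test_toy_case_keeps_two_columns(self):
        aln = CodonAlignment(ids=["a", "b"], rows=["ATG---AAA", "ATGGCTAAA"])
        out = strip_gap_columns(aln)
        assert out.rows == ["ATGAAA", "ATGAAA"]

    def test_gap_free_unchanged(self):
        aln = CodonAlignment(ids=["a"], rows=["ATGAAA"])
        assert strip_gap_columns(aln).rows == aln.rows

    def test_all_columns_gapped_gives_empty(self):
        aln = CodonAlignment(ids=["a", "b"], rows=["---GCT", "ATG---"])
        assert strip_gap_columns(aln).rows == ["", ""]


class TestClassifySubstitution:
    def test_synonymous_pair(self):
        assert classify_substitution("GCT", "GCC") == "synonymous"

    def test_nonsynonymous_pair(self):
        assert classify_substitution("GCT", "GAT") == "non-synonymous"

    def test_identical_codons_no_call(self):
        assert classify_substitution("GCT", "GCT") is None

    def test_stop_codon_is_ambiguous(self):
        assert classify_substitution("TAA", "GCT") == "ambiguous"

    def test_all_sense_pairs_match_translation_oracle(self):
        for a in SENSE_CODONS:
            aa_a = str(Seq(a).translate())
            for b in SENSE_CODONS:
                got = classify_substitution(a, b)
                if a == b:
                    assert got is None
                elif aa_a == str(Seq(b).translate()):
                    assert got == "synonymous"
                else:
                    assert got == "non-synonymous"

    def test_symmetry(self, rng):
        for _ in range(200):
            a, b = rng.choice(SENSE_CODONS, size=2)
            assert classify_substitution(a, b) == classify_substitution(b, a)


class TestAminoPropertyChange:
    def test_both_acidic_is_no_change(self):
        assert amino_property_change("D", "E") is False

    def test_basic_vs_hydrophobic_is_change(self):
        assert amino_property_change("K", "L") is True

    def test_all_unordered_pairs_match_class_lookup_oracle(self):
        class_of = {
            aa: name for name, members in DEFAULT_PROPERTY_CLASSES.items() for aa in members
        }
        aas = sorted(STANDARD_AA)
        for i, a in enumerate(aas):
            for b in aas[i + 1:]:
                assert amino_property_change(a, b) == (class_of[a] != class_of[b])

    def test_nonstandard_residue_raises(self):
        with pytest.raises(ValueError):
            amino_property_change("X", "A")


class TestSharedSubstitutionTally:
    def _build(self, columns):
        """columns: list of (focal1, focal2, ref) codons."""
        rows = ["".join(c[i] for c in columns) for i in range(3)]
        return CodonAlignment(ids=["P1", "P2", "REF"], rows=rows,
                              taxa=["P1", "P2", "REF"])

    def test_no_changes_when_all_identical(self):
        aln = self._build([("ATG", "ATG", "ATG")] * 5)
        t = shared_substitution_tally(aln, ["P1", "P2"], "REF")
        assert t.total_shared == 0 and t.within_focal_variable == 0

    def test_constructed_21_changes_18_nonsynonymous(self):
        # 18 non-synonymous shared differences (Ala GCT -> Asp GAT),
        # 3 synonymous (GCT -> GCC), plus identical filler columns
        cols = [("GCT", "GCT", "GAT")] * 18 + [("GCT", "GCT", "GCC")] * 3
        cols += [("ATG", "ATG", "ATG")] * 4
        t = shared_substitution_tally(self._build(cols), ["P1", "P2"], "REF")
        assert (t.total_shared, t.nonsynonymous_shared) == (21, 18)

    def test_focal_disagreement_counts_as_within_focal(self):
        aln = self._build([("GCT", "GAT", "GGG")])
        t = shared_substitution_tally(aln, ["P1", "P2"], "REF")
        assert t.total_shared == 0 and t.within_focal_variable == 1

    def test_focal_order_invariance(self):
        cols = [("GCT", "GCT", "GAT"), ("AAA", "AAA", "AAA"), ("TTT", "TTG", "CCC")]
        aln = self._build(cols)
        t1 = shared_substitution_tally(aln, ["P1", "P2"], "REF")
        t2 = shared_substitution_tally(aln, ["P2", "P1"], "REF")
        assert (t1.total_shared, t1.nonsynonymous_shared, t1.within_focal_variable) == (
            t2.total_shared, t2.nonsynonymous_shared, t2.within_focal_variable
        )

    def test_property_changes_counted(self):
        # Lys AAA -> Leu CTA is basic -> hydrophobic: a property change
        aln = self._build([("AAA", "AAA", "CTA")])
        t = shared_substitution_tally(aln, ["P1", "P2"], "REF")
        assert t.property_change_shared == 1
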