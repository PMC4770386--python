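"""Tests for N-terminus classification, iMet rules and origin assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteoturn import (
    ImetConfig,
    OriginEvidence,
    ValidationError,
    assign_origin,
    classify_peptide_start,
    imet_processing_expected,
    pair_proteoforms,
    select_mature_nterminus,
)
from proteoturn.annotation import classify_table

# database sequence with Met at positions 1 and 40 (1-based)
PROT = "M" + "QWERTYIPNDFHKLQWERTYIPNDFHKLQWERTYIPND" + "M" + "SDFGHKLQWERTY"
PROT_ML = PROT[:40] + "L" + PROT[41:]  # residue 41 = Leu after the Met


class TestImetRule:
    @pytest.mark.parametrize("res", list("AVSTCGP"))
    def test_cleavable_residues(self, res):
        assert imet_processing_expected(res)

    @pytest.mark.parametrize("res", list("LMKDEFWQRYNIH"))
    def test_retaining_residues(self, res):
        assert not imet_processing_expected(res)

    @pytest.mark.parametrize("res", ["X", "U", "B", "", "AA", "1"])
    def test_invalid_codes_rejected(self, res):
        with pytest.raises(ValidationError):
            imet_processing_expected(res)

    def test_narrow_residue_set_config(self):
        cfg = ImetConfig(frozenset("AVTCGP"))  # without Ser
        assert not imet_processing_expected("S", cfg)
        assert imet_processing_expected("A", cfg)


class TestClassifyPeptideStart:
    def test_dbtis_position_1_retained(self):
        rec = classify_peptide_start("MQWER", 1, PROT)
        assert (rec.category, rec.imet_status) == ("dbTIS", "retained")
        assert rec.length == len(PROT)

    def test_dbtis_position_2_processed(self):
        seq = "MA" + PROT[2:]
        rec = classify_peptide_start("A" + PROT[2:6], 2, seq)
        assert (rec.category, rec.imet_status) == ("dbTIS", "processed")
        assert rec.length == len(seq) - 1

    def test_position_2_noncleavable_noncompliant(self):
        rec = classify_peptide_start(PROT[1:6], 2, PROT)  # residue 2 = Q
        assert rec.category == "non-compliant"

    def test_atis_retained_met_start(self):
        rec = classify_peptide_start("MSDFG", 40, PROT)
        assert (rec.category, rec.imet_status) == ("aTIS", "retained")

    def test_atis_processed_after_met(self):
        rec = classify_peptide_start("SDFGH", 41, PROT)
        assert (rec.category, rec.imet_status) == ("aTIS", "processed")

    def test_atis_noncleavable_after_met_noncompliant(self):
        rec = classify_peptide_start(PROT_ML[40:45], 41, PROT_ML)
        assert rec.category == "non-compliant"

    def test_internal_start_noncompliant(self):
        rec = classify_peptide_start(PROT[9:14], 10, PROT)  # preceded by N
        assert rec.category == "non-compliant"

    def test_peptide_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            classify_peptide_start("AAAAA", 10, PROT)

    def test_start_beyond_sequence_rejected(self):
        with pytest.raises(ValidationError):
            classify_peptide_start("M", len(PROT) + 5, PROT)

    def test_categories_partition_the_input(self):
        """Every peptide gets exactly one of the three categories."""
        for start in range(1, len(PROT) - 4):
            rec = classify_peptide_start(
                PROT[start - 1 : start + 4], start, PROT
            )
            assert rec.category in ("dbTIS", "aTIS", "non-compliant")


class TestPairing:
    def _rec(self, gene, start, peptide, seq):
        return classify_peptide_start(
            peptide, start, seq, gene=gene, accession=gene
        )

    def test_one_dbtis_one_atis(self):
        recs = [
            self._rec("G1", 1, "MQWER", PROT),
            self._rec("G1", 40, "MSDFG", PROT),
        ]
        pairs = pair_proteoforms(recs)
        assert len(pairs.tis_pairs) == 1
        assert pairs.multi_atis_flags == [False]

    def test_dbtis_only_no_pairs(self):
        pairs = pair_proteoforms([self._rec("G1", 1, "MQWER", PROT)])
        assert pairs.tis_pairs == []

    def test_empty_input(self):
        pairs = pair_proteoforms([])
        assert pairs.tis_pairs == [] and pairs.imet_pairs == []

    def test_imet_pair_shares_start_codon(self):
        seq = "MV" + PROT[2:]
        recs = [
            self._rec("G1", 1, "MV", seq),  # retained at codon 1
            self._rec("G1", 2, "V" + PROT[2:5], seq),  # processed, codon 1
        ]
        pairs = pair_proteoforms(recs)
        assert len(pairs.imet_pairs) == 1
        retained, processed = pairs.imet_pairs[0]
        assert retained.imet_status == "retained"
        assert processed.imet_status == "processed"

    def test_multi_atis_flagged(self):
        seq = PROT[:20] + "M" + PROT[21:]
        recs = [
            self._rec("G1", 1, "MQWER", PROT),
            self._rec("G1", 40, "MSDFG", PROT),
            self._rec("G1", 21, seq[20:25], seq),
        ]
        recs[2].gene = "G1"
        pairs = pair_proteoforms(recs)
        assert len(pairs.tis_pairs) == 2
        assert all(pairs.multi_atis_flags)


class TestSelectMature:
    def test_cleavable_pair_selects_processed(self):
        seq = "MV" + PROT[2:]
        retained = classify_peptide_start("MV", 1, seq)
        processed = classify_peptide_start("V" + PROT[2:5], 2, seq)
        assert (
            select_mature_nterminus((retained, processed)).imet_status
            == "processed"
        )

    def test_gly_pair_selects_processed(self):
        seq = "MG" + PROT[2:]
        retained = classify_peptide_start("MG", 1, seq)
        processed = classify_peptide_start("G" + PROT[2:5], 2, seq)
        assert (
            select_mature_nterminus((retained, processed)).imet_status
            == "processed"
        )

    def test_singleton_passes_through(self):
        rec = classify_peptide_start("MQWER", 1, PROT)
        assert select_mature_nterminus((rec,)) is rec

    def test_malformed_pair_rejected(self):
        a = classify_peptide_start("MQWER", 1, PROT)
        with pytest.raises(ValidationError):
            select_mature_nterminus((a, a))


class TestAssignOrigin:
    def _atis(self):
        return classify_peptide_start("MSDFG", 40, PROT)

    def test_dbtis_passes_through(self):
        rec = classify_peptide_start("MQWER", 1, PROT)
        assert assign_origin(rec, OriginEvidence()) == ("annotated", True)

    def test_riboseq_only_alternative_initiation(self):
        origin, confident = assign_origin(
            self._atis(), OriginEvidence(riboseq_tis=True)
        )
        assert origin == "alternative-initiation" and confident

    def test_ensembl_with_support_splicing_likely(self):
        origin, confident = assign_origin(
            self._atis(),
            OriginEvidence(ensembl=True, transcript_support_level=2),
        )
        assert origin == "splicing-likely" and confident

    def test_isoform_without_support_splicing_poor(self):
        origin, _ = assign_origin(
            self._atis(), OriginEvidence(swissprot_isoform=True)
        )
        assert origin == "splicing-poor"

    def test_topfind_only_proteolysis_candidate(self):
        origin, confident = assign_origin(
            self._atis(), OriginEvidence(topfind_protease=True)
        )
        assert origin == "proteolysis-candidate" and not confident

    def test_acetylation_disregards_protease_match(self):
        origin, confident = assign_origin(
            self._atis(),
            OriginEvidence(topfind_protease=True, acetylated=True),
        )
        assert origin == "alternative-initiation" and confident

    @given(st.lists(st.booleans(), min_size=6, max_size=6))
    @settings(max_examples=64, derandomize=True)
    def test_adding_evidence_never_demotes_confidence(self, flags):
        """Monotonicity: extra evidence can only add confidence."""
        base = OriginEvidence(
            riboseq_tis=flags[0],
            swissprot_isoform=flags[1],
            trembl=flags[2],
            ensembl=flags[3],
            topfind_protease=flags[4],
            acetylated=flags[5],
        )
        _, confident = assign_origin(self._atis(), base)
        more = OriginEvidence(
            riboseq_tis=True,
            swissprot_isoform=flags[1],
            trembl=flags[2],
            ensembl=flags[3],
            topfind_protease=flags[4],
            acetylated=flags[5],
        )
        _, confident_more = assign_origin(self._atis(), more)
        assert confident_more >= confident


class TestSyntheticRecovery:
    def test_rules_recover_generator_truth_exactly(self, small_truth):
        """Deterministic rules give 100% category and iMet accuracy."""
        sequences, truth = small_truth
        rows = [
            {
                "peptide": sequences[p.accession][p.start - 1 : p.start + 9],
                "accession": p.accession,
                "gene": p.gene,
                "start": p.start,
            }
            for p in truth.proteoforms.itertuples()
        ]
        records = classify_table(rows, sequences)
        for rec, truth_row in zip(records, truth.proteoforms.itertuples()):
            assert rec.category == truth_row.category
            assert rec.imet_status == truth_row.imet_status
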