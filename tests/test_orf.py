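"""Lesion detection, NMD prediction and pseudogene classification."""

import pytest

import dollotrace as dt
from dollotrace.orf import (
    FRAMESHIFT_INDEL,
    PREMATURE_STOP,
    START_LOSS,
    TERMINAL_STOP_LOSS,
)


@pytest.fixture(scope="module")
def intact_300():
    return dt.random_intact_cds(300, seed=11, n_exons=8)


class TestSpliceCds:
    def test_single_exon_plus_is_identity(self):
        assert dt.splice_cds([(1, 6)], "ATGTAA", "+") == "ATGTAA"

    def test_single_exon_minus_is_reverse_complement(self):
        assert dt.splice_cds([(1, 6)], "TTACAT", "-") == "ATGTAA"

    def test_multi_exon_equals_single_exon_concatenation(self):
        genome = "ATGAAACCCGGGTTTTAA"
        whole = dt.splice_cds([(1, 18)], genome, "+")
        parts = dt.splice_cds([(1, 6), (7, 12), (13, 18)], genome, "+")
        assert whole == parts

    def test_out_of_range_exon_is_hard_error(self):
        with pytest.raises(ValueError):
            dt.splice_cds([(1, 10)], "ATG", "+")


class TestScanOrf:
    def test_intact_cds_reports_intact(self, intact_300):
        rep = dt.scan_orf(intact_300)
        assert rep.status == "INTACT" and rep.lesions == []
        assert rep.nmd_predicted is False

    def test_planted_stop_found_at_its_codon(self, intact_300):
        mut, _ = dt.mutate_cds(intact_300, [("PREMATURE_STOP", 150)], seed=1)
        rep = dt.scan_orf(mut)
        assert [(l.kind, l.codon_position) for l in rep.lesions] == [
            (PREMATURE_STOP, 150)
        ]

    def test_terminal_stop_is_not_premature(self):
        m = dt.CodingModel("g", "sp", [(1, 6)], "+", "ATGTAA")
        assert dt.scan_orf(m).status == "INTACT"

    def test_missing_start_and_terminal_stop(self):
        m = dt.CodingModel("g", "sp", [(1, 9)], "+", "CTGAAACCC")
        kinds = {l.kind for l in dt.scan_orf(m).lesions}
        assert kinds == {START_LOSS, TERMINAL_STOP_LOSS}

    def test_ambiguous_codons_are_not_lesions(self, intact_300):
        cds = intact_300.spliced_cds
        cds = cds[:300] + "NNN" + cds[303:]
        m = dt.CodingModel("g", "sp", [(1, len(cds))], "+", cds)
        rep = dt.scan_orf(m)
        assert rep.status == "INTACT"
        assert 101 in rep.ambiguous_codons

    def test_length_not_multiple_of_three_is_hard_error(self):
        m = dt.CodingModel("g", "sp", [(1, 7)], "+", "ATGAAAT")
        with pytest.raises(ValueError, match="compare_to_reference"):
            dt.scan_orf(m)

    def test_fuzz_intact_orfs_stay_intact(self):
        for seed in range(30):
            m = dt.random_intact_cds(60, seed=seed)
            assert dt.scan_orf(m).status == "INTACT"


class TestCompareToReference:
    def test_identity_has_no_lesions(self, intact_300):
        assert dt.compare_to_reference(
            intact_300.spliced_cds, intact_300.spliced_cds
        ) == []

    def test_one_nt_deletion_gives_frameshift_then_stop(self, intact_300):
        ref = intact_300.spliced_cds
        query = ref[:99] + ref[100:]  # 1-nt deletion at base 100 (codon 34)
        lesions = dt.compare_to_reference(query, ref)
        fs = [l for l in lesions if l.kind == FRAMESHIFT_INDEL]
        assert len(fs) == 1
        # alignment may slide the gap by one codon within a repeat
        assert abs(fs[0].codon_position - 34) <= 1
        stops = [l for l in lesions if l.kind == PREMATURE_STOP]
        assert stops and all(s.codon_position >= fs[0].codon_position for s in stops)

    def test_in_frame_deletion_is_not_a_frameshift(self, intact_300):
        ref = intact_300.spliced_cds
        query = ref[:99] + ref[102:]
        lesions = dt.compare_to_reference(query, ref)
        assert all(l.kind != FRAMESHIFT_INDEL for l in lesions)

    def test_empty_sequence_is_hard_error(self):
        with pytest.raises(ValueError):
            dt.compare_to_reference("", "ATG")


class TestPredictNmd:
    def make_model(self, n_exons, n_codons=120):
        return dt.random_intact_cds(n_codons, seed=3, n_exons=n_exons)

    def test_stop_in_early_exon_predicts_nmd(self):
        m = self.make_model(8)
        mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", 30)], seed=1)  # exon 3 of 8
        assert dt.scan_orf(mut).nmd_predicted is True

    def test_stop_in_last_exon_does_not(self):
        m = self.make_model(8)
        mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", 110)], seed=1)
        assert dt.scan_orf(mut).nmd_predicted is False

    def test_single_exon_never_predicts_nmd(self):
        m = self.make_model(1)
        mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", 10)], seed=1)
        assert dt.scan_orf(mut).nmd_predicted is False

    def test_margin_threshold_boundary(self):
        # 2 exons of 60 codons each: junction at nt 180
        m = dt.random_intact_cds(120, seed=5, n_exons=2)
        junction = m.last_junction_nt()
        assert junction == 180
        # stop end at nt 3*codon; distance junction - 3*codon
        for codon, expected in [(44, False), (43, True)]:
            # distances 180-132=48 < 50 -> False; 180-129=51 >= 50 -> True
            mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", codon)], seed=1)
            rep = dt.scan_orf(mut)
            assert dt.predict_nmd(rep, mut, margin=50) is expected
        # exact threshold: distance 50 -> codon position 130/3 not integral,
        # so construct junction-aligned case with margin equal to distance
        mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", 40)], seed=1)
        rep = dt.scan_orf(mut)
        assert dt.predict_nmd(rep, mut, margin=60) is True
        assert dt.predict_nmd(rep, mut, margin=61) is False

    def test_monotone_in_stop_position(self):
        m = dt.random_intact_cds(120, seed=7, n_exons=5)
        nmd_at = []
        for codon in range(2, 119):
            mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", codon)], seed=1)
            nmd_at.append(dt.scan_orf(mut).nmd_predicted)
        # once NMD stops being predicted it never resumes downstream
        assert nmd_at == sorted(nmd_at, reverse=True)


class TestAssessFunctionality:
    def test_stop_inside_rod_domain_is_nonfunctional(self):
        m = dt.random_intact_cds(300, seed=9)
        mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", 100)], seed=1)
        mut.rod_domain = (50, 200)
        rep = dt.scan_orf(mut)
        assert dt.assess_functionality(rep, mut) == "nonfunctional"
        assert rep.truncates_rod is True

    def test_intact_report_is_functional(self):
        m = dt.random_intact_cds(300, seed=9)
        rep = dt.scan_orf(m)
        assert dt.assess_functionality(rep, m) == "functional"

    def test_near_terminal_stop_after_rod_is_tolerated(self):
        # single exon (no NMD), stop 3 codons before the end, rod ends earlier
        m = dt.random_intact_cds(300, seed=9, n_exons=1)
        mut, _ = dt.mutate_cds(m, [("PREMATURE_STOP", 297)], seed=1)
        mut.rod_domain = (50, 250)
        rep = dt.scan_orf(mut)
        assert rep.nmd_predicted is False
        assert dt.assess_functionality(rep, mut) == "functional"
        assert rep.truncates_rod is False

    def test_frameshift_is_always_nonfunctional(self):
        m = dt.random_intact_cds(300, seed=9)
        mut, _ = dt.mutate_cds(m, [("FRAMESHIFT_INDEL", 290, -1)], seed=1)
        lesions = dt.compare_to_reference(mut.spliced_cds, m.spliced_cds)
        rep = dt.IntegrityReport(
            gene_id="g", species="sp", status="PSEUDOGENE", lesions=lesions
        )
        assert dt.assess_functionality(rep, mut) == "nonfunctional"


class TestSharedLesion:
    def test_stop_at_shared_aligned_column_groups_species(self):
        base = dt.random_intact_cds(100, seed=13)
        reports, aln = {}, {}
        for sp in ("walrus", "sea_lion"):
            mut, _ = dt.mutate_cds(base, [("PREMATURE_STOP", 40)], seed=17)
            reports[sp] = dt.scan_orf(mut)
            aln[sp] = mut.spliced_cds  # ungapped: same column
        groups = dt.shared_lesion(reports, aln)
        assert groups == [{"sea_lion", "walrus"}]

    def test_single_report_is_singleton(self):
        base = dt.random_intact_cds(100, seed=13)
        mut, _ = dt.mutate_cds(base, [("PREMATURE_STOP", 40)], seed=17)
        groups = dt.shared_lesion({"walrus": dt.scan_orf(mut)}, {"walrus": mut.spliced_cds})
        assert groups == [{"walrus"}]

    def test_different_columns_stay_separate(self):
        base = dt.random_intact_cds(100, seed=13)
        reports, aln = {}, {}
        for sp, codon in [("a", 30), ("b", 60)]:
            mut, _ = dt.mutate_cds(base, [("PREMATURE_STOP", codon)], seed=17)
            reports[sp] = dt.scan_orf(mut)
            aln[sp] = mut.spliced_cds
        assert dt.shared_lesion(reports, aln) == [{"a"}, {"b"}]

    def test_gapped_alignment_shifts_columns(self):
        # same reference codon, but one sequence has a 3-nt insertion before
        # it: gapped alignment still maps both stops to one column
        base = dt.random_intact_cds(100, seed=13)
        m1, _ = dt.mutate_cds(base, [("PREMATURE_STOP", 40)], seed=17)
        m2, _ = dt.mutate_cds(base, [("PREMATURE_STOP", 40)], seed=17)
        s1 = m1.spliced_cds
        s2 = "AAA" + m2.spliced_cds  # pretend N-terminal insertion
        aln = {"x": "---" + s1, "y": s2}
        reports = {
            "x": dt.scan_orf(m1),
            "y": dt.IntegrityReport(
                gene_id="g", species="y", status="PSEUDOGENE",
                lesions=[dt.Lesion("PREMATURE_STOP", 41)],
            ),
        }
        assert dt.shared_lesion(reports, aln) == [{"x", "y"}]

    def test_species_missing_from_alignment_is_hard_error(self):
        base = dt.random_intact_cds(100, seed=13)
        rep = dt.scan_orf(base)
        with pytest.raises(KeyError):
            dt.shared_lesion({"a": rep}, {})
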