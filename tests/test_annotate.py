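"""Annotation reconciliation and boundary-editing rules."""

import pytest

from mitorder.annotate import (
    curate,
    detect_arms,
    extend_rrna,
    reconcile_trnas,
    refine_pcg,
)
from mitorder.model import AnnotatedGenome, Feature, revcomp
from mitorder.synthetic import cloverleaf


def trna(label, start, end, source, strand="+", structure=None):
    return Feature(label, "tRNA", strand, start, end, source, structure)


class TestDetectArms:
    def test_four_stem_cloverleaf(self):
        s = cloverleaf(68)
        assert detect_arms(s) == {
            "acceptor": True, "D": True, "anticodon": True, "T": True,
        }

    def test_d_armless_structure(self):
        s = cloverleaf(60, d_arm=False)
        arms = detect_arms(s)
        assert arms["D"] is False
        assert arms["acceptor"] and arms["anticodon"] and arms["T"]

    def test_empty_structure_all_absent(self):
        assert detect_arms("." * 60) == {
            "acceptor": False, "D": False, "anticodon": False, "T": False,
        }

    @pytest.mark.parametrize("bad", ["(((..", "..)))", "((x))"])
    def test_unbalanced_or_bad_characters(self, bad):
        with pytest.raises(ValueError):
            detect_arms(bad)

    def test_structure_sequence_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            detect_arms("(((...)))", seq="ACGT")


class TestReconcileTrnas:
    def test_dual_source_overlap_accepted(self):
        calls = [trna("D", 100, 165, "mitos"), trna("D", 102, 168, "arwen")]
        res = reconcile_trnas(calls)
        (acc,) = res.accepted
        assert "evidence:dual" in acc.flags and not res.rejected

    def test_single_source_with_cloverleaf_accepted(self):
        s = cloverleaf(65)
        res = reconcile_trnas([trna("A", 10, 75, "arwen", structure=s)])
        (acc,) = res.accepted
        assert "evidence:single+cloverleaf" in acc.flags

    def test_single_source_without_structure_rejected(self):
        res = reconcile_trnas([trna("A", 10, 75, "arwen")])
        assert not res.accepted
        ((_, reason),) = res.rejected
        assert reason == "single-evidence, no structure"

    def test_same_strand_required_for_dual_evidence(self):
        calls = [trna("D", 100, 165, "mitos", strand="+"),
                 trna("D", 102, 168, "arwen", strand="-")]
        res = reconcile_trnas(calls)
        assert not res.accepted and len(res.rejected) == 2

    def test_disjoint_same_label_loci_flagged_putative_duplication(self):
        s = cloverleaf(65)
        calls = [
            trna("C", 10, 75, "mitos"), trna("C", 12, 77, "arwen"),
            trna("C", 500, 565, "arwen", structure=s),
        ]
        res = reconcile_trnas(calls)
        assert len(res.accepted) == 2
        assert all("putative duplication" in f.flags for f in res.accepted)

    def test_span_follows_source_priority(self):
        calls = [trna("D", 100, 165, "mitos"), trna("D", 102, 168, "arwen")]
        res = reconcile_trnas(calls, priority=["arwen", "mitos"])
        assert (res.accepted[0].start, res.accepted[0].end) == (102, 168)

    def test_every_accepted_trna_has_exactly_one_evidence_code(self):
        s = cloverleaf(65)
        calls = [
            trna("D", 100, 165, "mitos"), trna("D", 102, 168, "arwen"),
            trna("A", 300, 365, "arwen", structure=s),
        ]
        res = reconcile_trnas(calls)
        for f in res.accepted:
            codes = [x for x in f.flags if x.startswith("evidence:")]
            assert len(codes) == 1


def pcg_genome(seq, strand="+"):
    """A genome whose single PCG call covers the whole sequence."""
    plus = seq if strand == "+" else revcomp(seq)
    g = AnnotatedGenome("g", plus + "G" * 30, circular=False)
    call = Feature("cox1", "PCG", strand, 0, len(seq), "mitos")
    return g, call


class TestRefinePcg:
    def test_start_moved_to_first_start_codon_and_stop_found(self):
        body = "AAA" * 35
        seq = "GG" + "ATG" + body + "TAA" + "CCC"
        g, call = pcg_genome(seq)
        refined, rec = refine_pcg(g, call)
        assert (refined.start, refined.end) == (2, 2 + 3 + len(body) + 3)
        assert (rec.start_codon, rec.stop_codon, rec.truncated) == ("ATG", "TAA", False)
        assert "pseudo?" not in refined.flags

    def test_short_orf_flagged_pseudo(self):
        g, call = pcg_genome("GGATGAAATTTTAA")
        refined, rec = refine_pcg(g, call)
        assert refined.end - refined.start == 12  # ATG AAA TTT TAA
        assert "pseudo?" in refined.flags

    def test_no_start_codon_leaves_feature_unedited(self):
        g, call = pcg_genome("CCCCCCCCCCCC")
        refined, rec = refine_pcg(g, call)
        assert rec is None and "no-start" in refined.flags
        assert (refined.start, refined.end) == (call.start, call.end)

    def test_truncated_stop_T_before_validated_trna(self):
        seq = "ATG" + "AAA" * 35 + "T"
        g = AnnotatedGenome("g", seq + "C" * 65, circular=False)
        call = Feature("cox1", "PCG", "+", 0, len(seq), "mitos")
        t = Feature("K", "tRNA", "+", len(seq), len(seq) + 65, "mitos")
        refined, rec = refine_pcg(g, call, validated_trnas=[t])
        assert rec.stop_codon == "T(AA)" and rec.truncated
        assert refined.end == len(seq)

    def test_truncated_stop_requires_nearby_trna(self):
        seq = "ATG" + "AAA" * 35 + "T"
        g = AnnotatedGenome("g", seq + "C" * 65, circular=False)
        call = Feature("cox1", "PCG", "+", 0, len(seq), "mitos")
        far = Feature("K", "tRNA", "+", len(seq) + 10, len(seq) + 65, "mitos")
        refined, rec = refine_pcg(g, call, validated_trnas=[far])
        assert rec.stop_codon is None and "no-stop" in refined.flags

    def test_minus_strand_coordinates(self):
        coding = "ATG" + "AAA" * 35 + "TAA"
        g, call = pcg_genome("GG" + coding + "CC", strand="-")
        refined, rec = refine_pcg(g, call)
        # on the minus strand the 5' offset trims from the feature *end*
        assert refined.strand == "-"
        assert g.feature_seq(refined) == coding
        assert rec.stop_codon == "TAA"

    def test_same_frame_overlap_rejected_in_curation(self):
        # body codons are ATT (also a start codon), so the second call
        # refines to the same frame and the same stop as the first
        a = "ATG" + "ATT" * 35 + "TAA"
        seq = a + "G" * 40
        g = AnnotatedGenome("g", seq, circular=False)
        first = Feature("cox1", "PCG", "+", 0, len(a), "mitos")
        second = Feature("cox2", "PCG", "+", 3, len(a) + 30, "mitos")
        res = curate(g, [first, second])
        assert any("same-frame overlap" in why for _, why in res.rejected)


class TestExtendRrna:
    def test_extends_to_abut_flanking_features(self):
        feats = [
            Feature("V", "tRNA", "-", 30, 95, "x"),
            Feature("rrnS", "rRNA", "-", 100, 900, "x"),
            Feature("M", "tRNA", "-", 910, 975, "x"),
        ]
        out = extend_rrna(feats, genome_length=2000)
        rrn = next(f for f in out if f.label == "rrnS")
        assert (rrn.start, rrn.end) == (95, 910)

    def test_already_abutting_is_unchanged(self):
        feats = [
            Feature("V", "tRNA", "-", 30, 100, "x"),
            Feature("rrnS", "rRNA", "-", 100, 900, "x"),
            Feature("M", "tRNA", "-", 900, 975, "x"),
        ]
        out = extend_rrna(feats, genome_length=2000)
        rrn = next(f for f in out if f.label == "rrnS")
        assert (rrn.start, rrn.end) == (100, 900)
        assert extend_rrna(out, 2000) == out  # idempotent

    def test_linear_genome_edge_flagged_and_interior_extended(self):
        feats = [
            Feature("rrnL", "rRNA", "-", 5, 900, "x"),
            Feature("V", "tRNA", "-", 920, 985, "x"),
        ]
        out = extend_rrna(feats, genome_length=1000, circular=False)
        rrn = next(f for f in out if f.label == "rrnL")
        assert rrn.end == 920 and rrn.start == 5
        assert "no-flank:5'" in rrn.flags

    def test_wraps_across_origin_on_circles(self):
        feats = [
            Feature("rrnL", "rRNA", "-", 10, 900, "x"),
            Feature("V", "tRNA", "-", 950, 995, "x"),  # ends 5 bp before origin
        ]
        out = extend_rrna(feats, genome_length=1000)
        rrn = next(f for f in out if f.label == "rrnL")
        assert (rrn.start, rrn.end) == (995, 1950)  # wraps: 995..(origin)..950


class TestCurationIdempotence:
    def test_full_curation_is_idempotent(self, clean_study):
        tip = sorted(clean_study.genomes)[0]
        g = clean_study.genomes[tip]
        calls = [c for src in clean_study.views[tip].values() for c in src]
        once = curate(g, calls)
        again = curate(g, [f for f in once.accepted])
        def key(fs):
            return sorted((f.label, f.start, f.end, f.strand) for f in fs)
        # accepted tRNAs re-enter as single-source calls but keep their
        # structures, so the accepted set must be reproduced exactly
        assert key(again.accepted) == key(once.accepted)
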