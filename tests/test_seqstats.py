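"""Composition, codon usage, NCR/overlap inventories, tandem motifs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorder.model import AnnotatedGenome, Feature, revcomp
from mitorder.seqstats import (
    at_richest_ncr,
    codon_usage,
    composition,
    find_ncrs,
    find_overlaps,
    find_tandem_motifs,
    summarize_ncrs,
    synonymous_families,
)


class TestComposition:
    @pytest.mark.parametrize("seq,at_skew,gc_skew", [
        ("GGATCC", 0.0, 0.0),
        ("AAT", (2 - 1) / 3, 0.0),
    ])
    def test_hand_counts(self, seq, at_skew, gc_skew):
        c = composition(seq)
        assert c.at_skew == pytest.approx(at_skew)
        assert c.gc_skew == pytest.approx(gc_skew)

    def test_n_excluded_from_percentages(self):
        c = composition("AANNT")
        assert c.counts["N"] == 2
        assert c.at_percent == pytest.approx(100.0)  # over the 3 real bases

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            composition("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_reverse_complement_negates_both_skews(self, seq):
        a, b = composition(seq), composition(revcomp(seq))
        assert a.at_skew == pytest.approx(-b.at_skew)
        assert a.gc_skew == pytest.approx(-b.gc_skew)
        assert -1.0 <= a.at_skew <= 1.0 and -1.0 <= a.gc_skew <= 1.0


def one_gene_genome(codon_blocks: str):
    seq = codon_blocks + "G" * 10
    g = AnnotatedGenome("g", seq, circular=False)
    pcg = Feature("cox1", "PCG", "+", 0, len(codon_blocks), "t")
    return g, [pcg]


class TestCodonUsage:
    def test_rscu_six_codon_family_hand_value(self):
        # Leu counts TTA=3, TTG=1 in a 6-codon family: RSCU(TTA)=3*6/4=4.5
        g, pcgs = one_gene_genome("ATG" + "TTA" * 3 + "TTG" + "TAA")
        usage = codon_usage(g, pcgs)
        assert usage.rscu["TTA"] == pytest.approx(4.5)
        assert usage.rscu["TTG"] == pytest.approx(1.5)
        fam = synonymous_families()["L"]
        assert sum(usage.rscu[c] for c in fam) == pytest.approx(len(fam))

    def test_uniform_family_rscu_one(self):
        g, pcgs = one_gene_genome("ATG" + "GTT" + "GTC" + "GTA" + "GTG" + "TAA")
        usage = codon_usage(g, pcgs)
        for c in synonymous_families()["V"]:
            assert usage.rscu[c] == pytest.approx(1.0)

    def test_zero_family_gets_zero_rscu(self):
        g, pcgs = one_gene_genome("ATG" + "TAA")
        usage = codon_usage(g, pcgs)
        assert all(usage.rscu[c] == 0.0 for c in synonymous_families()["V"])

    def test_start_and_stop_tallies(self):
        g, pcgs = one_gene_genome("ATG" + "AAA" * 3 + "TAG")
        usage = codon_usage(g, pcgs)
        assert usage.start_tally == {"ATG": 1}
        assert usage.stop_tally == {"TAG": 1}

    def test_non_codon_multiple_excluded(self):
        g = AnnotatedGenome("g", "ATGAAAT" + "G" * 10, circular=False)
        pcg = Feature("cox1", "PCG", "+", 0, 7, "t")
        usage = codon_usage(g, [pcg])
        assert usage.excluded == ["cox1"]

    def test_position_at_percent(self):
        # codons TAT, TAT: position 1 = T,T (100% AT); 2 = A,A; 3 = T,T
        g, pcgs = one_gene_genome("TAT" * 2)
        usage = codon_usage(g, pcgs)
        # no start codon semantics needed: counts are positional only
        assert usage.position_at == (100.0, 100.0, 100.0)


def circle(length, spans):
    feats = [
        Feature(lab, "tRNA", "+", s, e, "t") for lab, s, e in spans
    ]
    return AnnotatedGenome("g", "ACGT" * (length // 4), circular=True,
                           features=feats)


class TestNcrs:
    def test_hand_layout_two_gaps(self):
        g = circle(100, [("A", 0, 40), ("C", 50, 90)])
        ncrs = find_ncrs(g)
        assert [(r.start, r.end, r.length) for r in ncrs] == [
            (40, 50, 10), (90, 100, 10),
        ]
        assert ncrs[0].flank_upstream == "A"
        assert ncrs[0].flank_downstream == "C"

    def test_tiling_features_no_ncrs(self):
        g = circle(100, [("A", 0, 60), ("C", 60, 100)])
        assert find_ncrs(g) == []

    def test_origin_spanning_gap_reported_once(self):
        g = circle(100, [("A", 10, 90)])
        (r,) = find_ncrs(g)
        assert (r.start, r.end, r.length) == (90, 110, 20)

    def test_conservation_on_synthetic_genomes(self, clean_study):
        for tip, genome in clean_study.genomes.items():
            feats = [f for f in clean_study.features[tip] if f.ftype != "NCR"]
            ncrs = find_ncrs(genome, feats)
            covered = sum(f.length for f in feats)
            assert covered + sum(r.length for r in ncrs) == genome.length
            summary = summarize_ncrs(ncrs, genome.length)
            assert summary["n_gt10"] <= summary["n_ncrs"]

    def test_at_richest_tie_rules(self):
        from mitorder.seqstats import NCRRecord
        r1 = NCRRecord("x", "y", 0, 40, 40, 85.0)
        r2 = NCRRecord("x", "y", 100, 160, 60, 85.0)
        r3 = NCRRecord("x", "y", 300, 340, 40, 80.0)
        assert at_richest_ncr([r1, r2, r3]) is r2  # tie broken by length
        with pytest.raises(ValueError):
            at_richest_ncr([])


class TestOverlaps:
    def test_interval_arithmetic(self):
        g = circle(100, [("A", 0, 50), ("C", 45, 80)])
        records, total = find_overlaps(g)
        assert [(r.gene_a, r.gene_b, r.length) for r in records] == [("A", "C", 5)]
        assert total == 5

    def test_disjoint_features_empty(self):
        g = circle(100, [("A", 0, 40), ("C", 50, 90)])
        assert find_overlaps(g) == ([], 0)

    def test_strands_do_not_matter(self):
        feats = [
            Feature("A", "tRNA", "+", 0, 50, "t"),
            Feature("R", "tRNA", "-", 23, 80, "t"),
        ]
        g = AnnotatedGenome("g", "ACGT" * 25, circular=True, features=feats)
        records, total = find_overlaps(g)
        assert total == 27

    def test_origin_spanning_overlap(self):
        feats = [
            Feature("A", "tRNA", "+", 90, 110, "t"),  # wraps: covers 90-100 + 0-10
            Feature("C", "tRNA", "+", 0, 8, "t"),
        ]
        g = AnnotatedGenome("g", "ACGT" * 25, circular=True, features=feats)
        records, total = find_overlaps(g)
        assert total == 8


class TestTandemMotifs:
    def test_simple_dinucleotide_array(self):
        (m,) = find_tandem_motifs("ATATATATAT", min_unit=2, max_unit=4)
        assert (m.unit, m.copies, m.partial_tail, m.start) == ("AT", 5, 0, 0)

    def test_aperiodic_sequence_empty(self):
        assert find_tandem_motifs("ACGTTGCAACGGATCGTTAAGCTGATCGATCCGATTACGGCAAGTCCAGT") == []

    def test_planted_19bp_motif_recovered(self):
        unit = "CTATTATATATATATATTA"
        seq = "GGC" + unit * 8 + "GCC"
        hits = find_tandem_motifs(seq)
        best = max(hits, key=lambda m: m.total_length)
        assert (best.unit_length, best.copies, best.start) == (19, 8, 3)
        assert best.unit == unit

    def test_partial_tail_counted(self):
        unit = "ACGTAG"
        seq = unit * 3 + unit[:4] + "CCCCCC"
        (m,) = find_tandem_motifs(seq, min_unit=6, max_unit=10)
        assert (m.copies, m.partial_tail) == (3, 4)

    def test_overlap_resolution_prefers_longer_then_smaller_unit(self):
        # a 2x12 array whose halves are themselves 2x6 arrays: same span,
        # the 6-mer reading wins on the smaller-unit tie rule
        seq = "AAATTC" * 4
        (m,) = find_tandem_motifs(seq, min_unit=6, max_unit=12)
        assert m.unit_length == 6 and m.copies == 4

    def test_canonical_unit_is_least_rotation(self):
        (m,) = find_tandem_motifs("TTAATTAATTAA", min_unit=4, max_unit=4)
        assert m.canonical_unit == "AATT"

    def test_planted_motifs_in_synthetic_study(self, clean_study):
        for tip, motif in clean_study.motifs.items():
            genome = clean_study.genomes[tip]
            feats = [f for f in clean_study.features[tip] if f.ftype != "NCR"]
            found = []
            for r in find_ncrs(genome, feats):
                for m in find_tandem_motifs(genome.span_seq(r.start, r.end)):
                    found.append((r.start + m.start, m.unit, m.copies))
            assert (motif.start, motif.unit, motif.copies) in found
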