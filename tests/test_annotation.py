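"""ORF scanning, UR extraction, codon census and poly-A classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_orf
from conftest import random_dna
from mitoscan.annotation import (
    INVERTEBRATE_MITO,
    AnnotationConflictError,
    codon_census,
    detect_incomplete_stop,
    detect_polya_tail,
    extract_unassigned_regions,
    find_lur,
    scan_orf_downstream,
)
from mitoscan.genome_io import AnnotationSet, CircularGenome, FeatureAnnotation


def _genome(seq: str, circular: bool = False) -> CircularGenome:
    return CircularGenome("t", seq, circular=circular)


class TestGeneticCode:
    def test_invertebrate_peculiarities(self):
        code = INVERTEBRATE_MITO
        assert code.translate("AGA") == "S" and code.translate("AGG") == "S"
        assert code.translate("ATA") == "M"
        assert code.translate("TGA") == "W"
        assert code.start_codons == {"ATG", "ATA", "ATC"}
        assert code.stop_codons == {"TAA", "TAG"}


class TestOrfScan:
    def test_first_start_codon_any_frame(self):
        call = scan_orf_downstream(_genome("CCATCGGGTAA"), anchor=0)
        assert (call.start, call.stop) == (3, 11)
        assert call.start_codon == "ATC" and call.stop_codon == "TAA"
        assert call.complete

    def test_start_at_first_base(self):
        call = scan_orf_downstream(_genome("ATAAAATTTTAG"), anchor=0)
        assert (call.start, call.stop) == (1, 12)
        assert call.start_codon == "ATA" and call.stop_codon == "TAG"

    def test_no_start_codon_gives_no_orf(self):
        assert scan_orf_downstream(_genome("CCCCCCGGG"), anchor=0) is None

    def test_tiny_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_orf_downstream(_genome("AC"), anchor=0)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(20, 300))
    def test_matches_exhaustive_oracle(self, seed, n):
        """The scanner equals exhaustive enumeration on random sequences."""
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, n)
        anchor = int(rng.integers(0, n // 2))
        got = scan_orf_downstream(_genome(seq, circular=True), anchor)
        want = brute_force_orf(seq, anchor, circular=True)
        if want is None:
            assert got is None
        else:
            ws, wstop, wstart_c, wstop_c, wcomplete = want
            assert got.start == (ws - 1) % n + 1
            assert got.stop == (wstop - 1) % n + 1
            assert (got.start_codon, got.stop_codon, got.complete) == (
                wstart_c, wstop_c, wcomplete)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_scan_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 200)
        anchor = int(rng.integers(0, 50))
        boundary = int(rng.integers(anchor + 10, 200))
        want = brute_force_orf(seq, anchor, boundary=boundary, circular=True)
        if want == "conflict":
            with pytest.raises(AnnotationConflictError):
                scan_orf_downstream(_genome(seq, circular=True), anchor,
                                    boundary=boundary)
            return
        got = scan_orf_downstream(_genome(seq, circular=True), anchor,
                                  boundary=boundary)
        if want is None:
            assert got is None
        else:
            assert (got.start, got.stop, got.start_codon, got.stop_codon,
                    got.complete) == want


class TestIncompleteStop:
    def test_ta_residual(self):
        # 8 nt ORF abutting the next feature: residual "TA" completes by
        # polyadenylation, mirroring a 1,340 bp gene (1340 mod 3 == 2)
        call = detect_incomplete_stop(_genome("ATAAAGTA"), 1, 9)
        assert call.stop_codon == "TA-"
        assert (call.start, call.stop) == (1, 8)
        assert not call.complete

    def test_t_residual(self):
        call = detect_incomplete_stop(_genome("ATGAAAT"), 1, 8)
        assert call.stop_codon == "T--"

    def test_empty_residual_is_conflict(self):
        with pytest.raises(AnnotationConflictError):
            detect_incomplete_stop(_genome("ATGAAA"), 1, 7)

    def test_non_ta_residual_has_no_end(self):
        call = detect_incomplete_stop(_genome("ATGAAACC"), 1, 9)
        assert call.stop_codon is None and not call.has_end


class TestUnassignedRegions:
    def test_reference_annotation_yields_24_urs(self, ref_annotation):
        urs = extract_unassigned_regions(ref_annotation)
        assert len(urs) == 24
        assert (urs[0].name, urs[0].start, urs[0].stop, urs[0].length) == (
            "UR1", 1717, 1753, 37)

    def test_lur_is_ur11(self, ref_annotation):
        urs = extract_unassigned_regions(ref_annotation)
        lur = find_lur(urs)
        assert (lur.name, lur.start, lur.stop, lur.length) == (
            "UR11", 11269, 13378, 2110)

    def test_full_coverage_yields_no_urs(self):
        aset = AnnotationSet("g", 100, [FeatureAnnotation("a", "rRNA", 1, 100)])
        assert extract_unassigned_regions(aset) == []

    def test_hand_enumerated_circular_gaps(self):
        aset = AnnotationSet("g", 100, [
            FeatureAnnotation("a", "coding", 1, 48),
            FeatureAnnotation("b", "tRNA", 61, 90, anticodon="AAA"),
        ])
        urs = extract_unassigned_regions(aset)
        assert [(u.start, u.stop, u.length) for u in urs] == [
            (49, 60, 12), (91, 100, 10)]

    def test_circular_junction_gap_wraps(self):
        aset = AnnotationSet("g", 100, [FeatureAnnotation("a", "rRNA", 11, 90)])
        urs = extract_unassigned_regions(aset)
        assert len(urs) == 1
        u = urs[0]
        assert (u.start, u.stop, u.length) == (91, 10, 20)

    def test_conservation_and_order_independence(self, ref_annotation):
        urs = extract_unassigned_regions(ref_annotation)
        total = sum(u.length for u in urs) + ref_annotation.genic_length()
        assert total == ref_annotation.genome_length
        shuffled = AnnotationSet(
            ref_annotation.genome_id, ref_annotation.genome_length,
            list(reversed(ref_annotation.genic_features)))
        assert extract_unassigned_regions(shuffled) == urs

    def test_lur_tie_breaks_to_smaller_start(self):
        from mitoscan.annotation import UnassignedRegion

        a = UnassignedRegion("UR1", 10, 19, 10)
        b = UnassignedRegion("UR2", 50, 59, 10)
        assert find_lur([b, a]) is a
        assert find_lur([a]) is a
        with pytest.raises(ValueError):
            find_lur([])


class TestCodonCensus:
    def test_synthetic_truth_recovered(self, sim_genome):
        """Census of the venerid-like genome equals the planted codons:
        7 ATA + 6 ATG starts and exactly one incomplete stop."""
        genome, truth = sim_genome
        census = codon_census(truth.annotations, genome)
        assert dict(census.start_counts) == {"ATA": 7, "ATG": 6}
        assert census.n_incomplete == 1
        assert dict(census.incomplete_stop_counts) == {"TA-": 1}
        assert sum(census.stop_counts.values()) == 12
        assert census.non_canonical_starts == []
        for f in truth.annotations.of_type("coding"):
            assert census.per_gene[f.name] == (f.start_codon, f.stop_codon)

    def test_non_canonical_start_warns(self):
        g = CircularGenome("g", "CCCAAATAA" + "A" * 21, circular=True)
        aset = AnnotationSet("g", 30, [FeatureAnnotation("x", "coding", 1, 9)])
        with pytest.warns(UserWarning, match="non-canonical"):
            census = codon_census(aset, g)
        assert census.non_canonical_starts == ["x"]


class TestPolyA:
    @pytest.mark.parametrize("tail,run,status", [
        ("A" * 56, 56, "present"),
        ("A" * 8, 8, "ambiguous"),
        ("G", 0, "absent"),
    ])
    def test_classification(self, tail, run, status):
        res = detect_polya_tail("CCGT" + tail, min_run=10)
        assert (res.status, res.run) == (status, run)

    def test_empty_contig_rejected(self):
        with pytest.raises(ValueError):
            detect_polya_tail("", 10)
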