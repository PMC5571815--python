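"""Variant localization, frameshift logic, private alleles and ORF re-scan."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import translate_table5
from conftest import random_dna
from mitoscan.genome_io import (
    AnnotationSet,
    CircularGenome,
    FeatureAnnotation,
    SampleGenotypeMatrix,
    VariantRecord,
)
from mitoscan.simulate import sample_codons
from mitoscan.variants import (
    apply_variants_rescan_orf,
    classify_indel_frameshift,
    classify_variant_region,
    homopolymer_adjacent,
    private_allele_summary,
    sp_frequency,
)


def _var(pos, ref, alt, freqs=None):
    return VariantRecord(pos, ref, alt, freqs or {})


class TestRegionClassification:
    @pytest.mark.parametrize("pos,cls,name", [
        (1698, "coding", "cox1"),
        (12000, "UR", "UR11"),
        (14900, "tRNA", "tRNA-His"),
        (7000, "rRNA", "rrnL"),
    ])
    def test_reference_positions(self, ref_annotation, pos, cls, name):
        got = classify_variant_region(_var(pos, "A", "C"), ref_annotation)
        assert got == (cls, name)

    def test_out_of_range_position_rejected(self, ref_annotation):
        with pytest.raises(ValueError):
            classify_variant_region(_var(20000, "A", "C"), ref_annotation)

    def test_classes_partition_all_positions(self, ref_annotation):
        rng = np.random.default_rng(2)
        positions = rng.integers(1, ref_annotation.genome_length + 1, size=300)
        counts = {"coding": 0, "tRNA": 0, "rRNA": 0, "UR": 0}
        for p in positions:
            cls, _ = classify_variant_region(_var(int(p), "A", "C"),
                                             ref_annotation)
            counts[cls] += 1
        assert sum(counts.values()) == 300


class TestFrameshift:
    @pytest.mark.parametrize("ref,alt,fs", [
        ("C", "CAAA", False),   # +3: inserts one residue
        ("CT", "C", True),      # -1
        ("C", "CAT", True),     # +2
        ("AGCG", "A", False),   # -3: deletes one residue
        ("C", "CT", True),      # +1
    ])
    def test_mod3_rule(self, ref, alt, fs):
        cons = classify_indel_frameshift(_var(10, ref, alt))
        assert cons.frameshift is fs
        assert cons.delta == len(alt) - len(ref)

    def test_snv_rejected(self):
        with pytest.raises(ValueError, match="not an indel"):
            classify_indel_frameshift(_var(10, "A", "C"))

    def test_published_cds_indels_give_four_frameshifts(self, cds_indels):
        flags = [classify_indel_frameshift(v).frameshift for v in cds_indels]
        assert sum(flags) == 4

    def test_agrees_with_retranslation_oracle(self):
        """The mod-3 rule agrees with full retranslation of the mutated CDS
        on 1,000 random CDS/indel pairs: an in-frame indel leaves the
        protein tail untouched, a frameshift scrambles it."""
        rng = np.random.default_rng(31)
        for _ in range(1000):
            n_codons = int(rng.integers(30, 60))
            cds = "ATG" + "".join(sample_codons(rng, n_codons)) + "TAA"
            pos = int(rng.integers(4, len(cds) - 3 * 15))
            delta = int(rng.choice([-3, -2, -1, 1, 2, 3]))
            if delta > 0:
                ref = cds[pos - 1]
                alt = ref + random_dna(rng, delta)
            else:
                ref = cds[pos - 1 : pos - delta]  # anchor + |delta| deleted
                alt = cds[pos - 1]
            v = _var(pos, ref, alt)
            mutated = cds[: pos - 1] + alt + cds[pos - 1 + len(ref):]
            tail_same = (
                translate_table5(mutated)[-10:] == translate_table5(cds)[-10:]
            )
            assert classify_indel_frameshift(v).frameshift == (not tail_same)


class TestHomopolymerFlag:
    def test_indel_inside_long_run_is_flagged(self):
        g = CircularGenome("g", "GGGGCTTTTTTTGGGG", circular=False)
        assert homopolymer_adjacent(_var(5, "CT", "C"), g)

    def test_indel_far_from_runs_is_not(self):
        g = CircularGenome("g", "GACGTACGTAGCATGCACGT", circular=False)
        assert not homopolymer_adjacent(_var(5, "TA", "T"), g)


class TestPrivateAlleles:
    def _matrix(self, rows, samples):
        recs = [
            VariantRecord(10 + i, "A", "C",
                          dict(zip(samples, row)))
            for i, row in enumerate(rows)
        ]
        return SampleGenotypeMatrix(recs, samples)

    def test_single_carrier_is_private(self):
        m = self._matrix([[0.9, 0.0, 0.0]], ["a", "b", "c"])
        s = private_allele_summary(m)
        assert s.n_private_by_sample == {"a": 1, "b": 0, "c": 0}

    def test_two_carriers_private_to_none(self):
        m = self._matrix([[0.9, 0.8, 0.0]], ["a", "b", "c"])
        s = private_allele_summary(m)
        assert sum(s.n_private_by_sample.values()) == 0

    def test_threshold_defines_presence(self):
        # 0.089 and 0.11 straddle the default 0.1 carrier threshold
        m = self._matrix([[0.11, 0.089, 0.0]], ["a", "b", "c"])
        s = private_allele_summary(m)
        assert s.n_private_by_sample["a"] == 1

    def test_unknown_group_member_rejected(self):
        m = self._matrix([[0.9, 0.0]], ["a", "b"])
        with pytest.raises(ValueError, match="unknown"):
            private_allele_summary(m, groups={"males": ["nope"]})

    def test_generated_matrix_recovers_planted_split(self, sim_genome):
        """A 12-sample matrix planted with 151 of 257 variants private to
        one sample is summarized back to exactly that split."""
        from mitoscan.simulate import generate_variant_table

        genome, truth = sim_genome
        vt = generate_variant_table(
            truth, n_samples=12, n_variants=257,
            private_fraction_by_sample={"S01": 151 / 257}, seed=17)
        s = private_allele_summary(vt.matrix, annotations=truth.annotations,
                                   groups={"first": ["S01"]})
        assert s.n_total == 257
        assert s.n_private_by_sample["S01"] == 151
        assert s.n_cds == vt.n_cds
        assert sum(s.region_counts.values()) == 257
        assert s.group_summaries["first"]["n_private"] == 151
        assert sum(s.n_private_by_sample.values()) <= s.n_total

    def test_all_private_matrix_reaches_equality(self):
        samples = ["a", "b", "c"]
        rows = [[0.9, 0, 0], [0, 0.9, 0], [0, 0, 0.9]]
        s = private_allele_summary(self._matrix(rows, samples))
        assert sum(s.n_private_by_sample.values()) == s.n_total == 3


class TestSpFrequency:
    def test_cds_rate_all_samples(self):
        f = sp_frequency(145, 14920)
        assert f.rate_4dp == 0.0097
        assert f.one_every == 103

    def test_cds_rate_excluding_outlier(self):
        f = sp_frequency(42, 14920)
        assert f.rate_4dp == 0.0028
        assert f.one_every == 355

    def test_zero_variants(self):
        f = sp_frequency(0, 1000)
        assert f.rate == 0.0 and f.one_every is None


class TestRescan:
    def test_no_variants_is_identity(self):
        cds = "ATGAAATAGAAA"
        res = apply_variants_rescan_orf(cds, [])
        assert res.nt_length == 9  # up to and including TAG
        assert res.aa_length == 2
        assert res.stop_codon == "TAG"

    def test_single_deletion_matches_retranslation_oracle(self):
        # deleting one base brings a TAA into frame at codon 3
        cds = "ATGGAAATAAGC"
        v = _var(4, "GA", "G")
        res = apply_variants_rescan_orf(cds, [v])
        mutated = cds[:3] + "G" + cds[5:]
        full = translate_table5(mutated)
        assert res.protein == full.split("*")[0] == "ME"
        assert res.complete and res.stop_codon == "TAA"
        assert res.nt_length == 9 and res.aa_length == 2

    def test_no_new_stop_reports_incomplete(self):
        cds = "ATGAAATAGAAA"
        res = apply_variants_rescan_orf(cds, [_var(5, "AA", "A")])
        mutated = "ATGA" + "A" + cds[6:]
        assert res.sequence == mutated
        assert "*" not in translate_table5(mutated)
        assert not res.complete and res.stop_codon is None
        assert res.protein == translate_table5(mutated)

    def test_minus_one_plus_two_pair_matches_oracle(self):
        """A -1 deletion combined with a +2 insertion downstream (the classic
        compensating pair seen in mitogenome RNA variants) is applied
        right-to-left and re-translated identically to a full-string oracle;
        the protein is unchanged before the first edited codon."""
        rng = np.random.default_rng(47)
        cds = "ATG" + "".join(sample_codons(rng, 40)) + "TAA"
        v1 = _var(10, cds[9], cds[9] + "GC")      # +2
        v0 = _var(7, cds[6:8], cds[6])            # -1
        res = apply_variants_rescan_orf(cds, [v0, v1])
        # oracle: full retranslation of the independently mutated string
        mutated_oracle = cds[:6] + v0.alt_allele + cds[8:9] + v1.alt_allele + cds[10:]
        assert res.sequence == mutated_oracle
        oracle_protein = translate_table5(mutated_oracle).split("*")[0]
        assert res.protein == oracle_protein
        # first edit is inside codon 3, so the first two residues survive
        ref_protein = translate_table5(cds).split("*")[0]
        assert res.protein[:2] == ref_protein[:2]

    def test_overlapping_variants_rejected(self):
        cds = "ATGAAATAG"
        with pytest.raises(ValueError, match="overlap"):
            apply_variants_rescan_orf(cds, [_var(4, "AA", "A"), _var(5, "AA", "A")])

    def test_variant_beyond_cds_rejected(self):
        with pytest.raises(ValueError):
            apply_variants_rescan_orf("ATGTAA", [_var(10, "A", "C")])

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            apply_variants_rescan_orf("ATGTAA", [_var(1, "C", "A")])
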