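"""Nucleotide composition, codon usage and codon/anticodon wobble matching.

Composition is reported per region (genes, rRNAs, tRNAs, URs, aggregates)
as base percentages plus, for coding regions, the same percentages restricted
to third codon positions — the positions where synonymous codon choice and
A+T pressure show most clearly.  Codon usage is pooled over coding sequences
and summarised both within each synonymous family and against all counted
codons.  The wobble analysis asks, family by family, whether the most used
(modal) codon is the exact Watson-Crick partner of an encoded tRNA anticodon;
in mitogenomes it frequently is not, wobble pairing covering the rest.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .annotation import (
    INVERTEBRATE_MITO,
    GeneticCode,
    extract_unassigned_regions,
    reverse_complement,
)
from .genome_io import AnnotationSet, CircularGenome, FeatureAnnotation

logger = logging.getLogger(__name__)

AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr", "*": "STOP",
}


@dataclass
class CompositionReport:
    """Base percentages for one region; raw (unrounded) values are stored."""

    region_name: str
    length: int
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float
    third: dict[str, float] | None = None  # T3/C3/A3/G3 percentages

    @property
    def pct_AT(self) -> float:
        return self.pct_A + self.pct_T

    @property
    def pct_A3T3(self) -> float | None:
        if self.third is None:
            return None
        return self.third["A3"] + self.third["T3"]

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "name": self.region_name,
            "length": self.length,
            "T%": round(self.pct_T, 1),
            "C%": round(self.pct_C, 1),
            "A%": round(self.pct_A, 1),
            "G%": round(self.pct_G, 1),
            "A+T%": round(self.pct_AT, 1),
        }
        if self.third is not None:
            row.update({
                "T3%": round(self.third["T3"], 1),
                "C3%": round(self.third["C3"], 1),
                "A3%": round(self.third["A3"], 1),
                "G3%": round(self.third["G3"], 1),
                "A3+T3%": round(self.pct_A3T3, 1),
            })
        return row


def nucleotide_composition(seq: str, name: str = "") -> CompositionReport:
    """Percentage of each base in ``seq``; N bases leave the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = Counter(seq)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError(f"region {name!r}: no unambiguous bases")
    return CompositionReport(
        region_name=name,
        length=len(seq),
        pct_T=100.0 * counts["T"] / denom,
        pct_C=100.0 * counts["C"] / denom,
        pct_A=100.0 * counts["A"] / denom,
        pct_G=100.0 * counts["G"] / denom,
    )


def third_position_composition(cds: str) -> dict[str, float]:
    """Base percentages at third codon positions of an in-frame CDS.

    A trailing incomplete codon (1-2 nt) is ignored.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    thirds = cds[2 : 3 * (len(cds) // 3) : 3]
    counts = Counter(thirds)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("no unambiguous third-position bases")
    return {f"{b}3": 100.0 * counts[b] / denom for b in "TCAG"}


def composition_report(seq: str, name: str = "", coding: bool = False) -> CompositionReport:
    """Full composition row; third-position columns only for coding regions."""
    rep = nucleotide_composition(seq, name)
    if coding:
        rep.third = third_position_composition(seq)
    return rep


def feature_sequence(genome: CircularGenome, f: FeatureAnnotation) -> str:
    seq = genome.fetch(f.start, f.stop)
    return reverse_complement(seq) if f.strand == "-" else seq


def genome_composition_table(
    genome: CircularGenome, annotations: AnnotationSet
) -> pd.DataFrame:
    """Per-gene composition rows plus the standard aggregate rows.

    Aggregates: all coding genes, all rRNAs, all tRNAs, all URs (derived from
    the annotation gaps), all genic DNA and the whole genome.  Third-position
    columns are filled for coding rows and the pooled-coding aggregate.
    """
    rows = []
    for f in annotations.genic_features:
        seq = feature_sequence(genome, f)
        rows.append(composition_report(seq, f.name, coding=f.ftype == "coding").to_row())
    pooled = {
        "All coding": ("".join(feature_sequence(genome, f)
                               for f in annotations.of_type("coding")), True),
        "All rRNAs": ("".join(feature_sequence(genome, f)
                              for f in annotations.of_type("rRNA")), False),
        "All tRNAs": ("".join(feature_sequence(genome, f)
                              for f in annotations.of_type("tRNA")), False),
        "All URs": ("".join(genome.fetch(u.start, u.stop)
                            for u in extract_unassigned_regions(annotations)),
                    False),
        "All genic DNA": ("".join(feature_sequence(genome, f)
                                  for f in annotations.genic_features), False),
        "All DNA": (genome.sequence, False),
    }
    for name, (seq, coding) in pooled.items():
        if seq:
            rows.append(composition_report(seq, name, coding=coding).to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Codon usage


@dataclass
class CodonUsageTable:
    """Pooled codon counts with per-family frequencies and global percentages."""

    counts: dict[str, int]
    family_freq: dict[str, float]
    pct_total: dict[str, float]
    amino_acid: dict[str, str]
    include_stops: bool = False

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        code: GeneticCode = INVERTEBRATE_MITO,
        include_stops: bool = False,
    ) -> "CodonUsageTable":
        counts = {c.upper(): int(n) for c, n in counts.items() if n > 0}
        amino_acid = {c: code.translate(c) for c in counts}
        families: dict[str, int] = defaultdict(int)
        for c, n in counts.items():
            families[amino_acid[c]] += n
        total = sum(
            n for c, n in counts.items()
            if include_stops or amino_acid[c] != "*"
        )
        family_freq = {
            c: counts[c] / families[amino_acid[c]] for c in counts
        }
        pct_total = {
            c: (100.0 * counts[c] / total
                if (include_stops or amino_acid[c] != "*") and total
                else 0.0)
            for c in counts
        }
        return cls(counts, family_freq, pct_total, amino_acid, include_stops)

    def families(self) -> dict[str, dict[str, int]]:
        """Counts grouped by amino acid (single-letter key)."""
        out: dict[str, dict[str, int]] = defaultdict(dict)
        for c, n in self.counts.items():
            out[self.amino_acid[c]][c] = n
        return dict(out)

    def modal_codons(self, aa: str) -> list[str]:
        """The most used codon(s) of one family (several when tied)."""
        fam = self.families()[aa]
        best = max(fam.values())
        return sorted(c for c, n in fam.items() if n == best)

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for c in sorted(self.counts, key=lambda c: (AA3[self.amino_acid[c]], c)):
            rows.append({
                "amino_acid": AA3[self.amino_acid[c]],
                "codon": c,
                "count": self.counts[c],
                "family_frequency": round(self.family_freq[c], 2),
                "pct_total": round(self.pct_total[c], 2),
            })
        return rows


def codon_usage(
    cds_collection: list[str],
    code: GeneticCode = INVERTEBRATE_MITO,
    include_stops: bool = False,
) -> CodonUsageTable:
    """Pool codon counts over coding sequences (stride 3, in frame).

    Trailing incomplete codons are skipped; codons containing N are excluded
    with a logged notice.
    """
    counts: Counter = Counter()
    for cds in cds_collection:
        cds = cds.upper()
        if len(cds) < 3:
            raise ValueError("CDS shorter than one codon")
        for i in range(0, 3 * (len(cds) // 3), 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                logger.info("excluding ambiguous codon %s at offset %d", codon, i)
                continue
            counts[codon] += 1
    return CodonUsageTable.from_counts(dict(counts), code, include_stops)


# ---------------------------------------------------------------------------
# Wobble matching


@dataclass
class WobbleFamilyResult:
    modal_codon: str
    matching_trna: str | None
    matched: bool
    tied: bool


@dataclass
class WobbleMatchReport:
    per_aa: dict[str, WobbleFamilyResult]
    n_matched: int
    n_families: int


def modal_codon_wobble_match(
    usage: CodonUsageTable,
    trnas: list[FeatureAnnotation],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> WobbleMatchReport:
    """Does each family's modal codon Watson-Crick-match an encoded tRNA?

    A codon matches a tRNA when it equals the reverse complement of the
    anticodon (anticodons given 5'->3').  The amino acid served by a tRNA is
    inferred from its anticodon under the genetic code.  Families with codon
    usage but no tRNA are excluded (and logged).  When the modal codon is
    tied, the family counts as matched only if every tied codon matches.
    """
    trna_by_aa: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for t in trnas:
        if t.ftype != "tRNA" or not t.anticodon:
            continue
        codon = reverse_complement(t.anticodon)
        aa = code.translate(codon)
        trna_by_aa[aa].append((t.name, codon))

    per_aa: dict[str, WobbleFamilyResult] = {}
    n_matched = 0
    for aa, fam in sorted(usage.families().items()):
        if aa == "*":
            continue
        if aa not in trna_by_aa:
            logger.info("family %s has codon usage but no tRNA; excluded", AA3[aa])
            continue
        modal = usage.modal_codons(aa)
        tied = len(modal) > 1
        matched_all = True
        matching_trna = None
        for codon in modal:
            hit = next(
                (name for name, c in trna_by_aa[aa] if c == codon), None
            )
            if hit is None:
                matched_all = False
            elif matching_trna is None:
                matching_trna = hit
        matched = matched_all
        if matched:
            n_matched += 1
        per_aa[AA3[aa]] = WobbleFamilyResult(
            modal_codon="/".join(modal), matching_trna=matching_trna,
            matched=matched, tied=tied,
        )
    return WobbleMatchReport(per_aa=per_aa, n_matched=n_matched,
                             n_families=len(per_aa))
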