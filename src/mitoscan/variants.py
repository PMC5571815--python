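"""Polymorphism summaries against an annotated reference mitogenome.

Variants (SNVs and small indels) are localized to annotation features,
indels are classified for frameshift effect, private alleles are counted per
sample and per sample group, and SP density is reported both as a per-bp
rate and in the conventional "1 every N bp" form.  Indel alleles can also be
applied to a coding sequence and the ORF re-scanned, which is how a
single-base deletion plus a nearby two-base insertion can restore frame and
yield a protein differing only downstream of the edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import (
    INVERTEBRATE_MITO,
    GeneticCode,
    extract_unassigned_regions,
)
from .genome_io import (
    AnnotationSet,
    CircularGenome,
    SampleGenotypeMatrix,
    VariantRecord,
)

REGION_CLASSES = ("coding", "tRNA", "rRNA", "UR")


# ---------------------------------------------------------------------------
# Region localization


def classify_variant_region(
    variant: VariantRecord, annotations: AnnotationSet
) -> tuple[str, str]:
    """Region class and feature name containing the variant position.

    Positions inside no annotated gene fall in an unassigned region and
    report the UR name (URs are derived on the fly if the annotation set
    does not carry them).
    """
    pos = variant.position
    if not 1 <= pos <= annotations.genome_length:
        raise ValueError(
            f"position {pos} beyond genome length {annotations.genome_length}"
        )
    feat = annotations.feature_at(pos)
    if feat is not None:
        return feat.ftype, feat.name
    for ur in extract_unassigned_regions(annotations):
        if ur.start <= ur.stop:
            if ur.start <= pos <= ur.stop:
                return "UR", ur.name
        elif pos >= ur.start or pos <= ur.stop:  # wrap-around UR
            return "UR", ur.name
    raise ValueError(f"position {pos} not covered by any feature or UR")


# ---------------------------------------------------------------------------
# Indels


@dataclass
class IndelConsequence:
    variant: VariantRecord
    delta: int
    frameshift: bool
    note: str = ""


def classify_indel_frameshift(variant: VariantRecord) -> IndelConsequence:
    """Frameshift iff the length change is not a multiple of three."""
    if not variant.is_indel:
        raise ValueError(
            f"variant {variant.ref_allele}>{variant.alt_allele} is not an indel"
        )
    delta = variant.delta
    frameshift = delta % 3 != 0
    note = (
        f"{'insertion' if delta > 0 else 'deletion'} of {abs(delta)} nt"
    )
    return IndelConsequence(variant, delta, frameshift, note)


def homopolymer_adjacent(
    variant: VariantRecord,
    genome: CircularGenome,
    min_len: int = 6,
) -> bool:
    """Whether an indel sits in or against a homopolymer run of ``min_len``.

    Indels inside long single-base runs are plausible sequencing artifacts;
    they are flagged, never filtered.
    """
    if not variant.is_indel:
        return False
    lo = max(1, variant.position - min_len)
    hi = min(len(genome), variant.position + len(variant.ref_allele) + min_len)
    window = genome.fetch(lo, hi)
    run_base, run_len = None, 0
    for i, b in enumerate(window):
        if b == run_base:
            run_len += 1
        else:
            run_base, run_len = b, 1
        if run_len >= min_len:
            run_start = lo + i - run_len + 1
            run_end = lo + i
            # indel footprint plus one flanking base on either side
            if run_start <= variant.position + len(variant.ref_allele) and \
                    run_end >= variant.position - 1:
                return True
    return False


# ---------------------------------------------------------------------------
# Private alleles and group summaries


@dataclass
class SpSummary:
    n_total: int
    n_cds: int
    n_private_by_sample: dict[str, int]
    n_indels: int
    n_frameshift: int
    region_counts: dict[str, int] = field(default_factory=dict)
    group_summaries: dict[str, dict[str, int]] = field(default_factory=dict)


def private_allele_summary(
    matrix: SampleGenotypeMatrix,
    presence_threshold: float = 0.1,
    annotations: AnnotationSet | None = None,
    groups: dict[str, list[str]] | None = None,
) -> SpSummary:
    """Count variants, private alleles per sample, and per-group summaries.

    An allele is present in a sample when its frequency is at or above
    ``presence_threshold``; it is private to a sample (or group) when present
    there and nowhere else.  With an annotation set, variants are localized
    and CDS/indel/frameshift tallies filled in; group summaries report, per
    user-defined group, total and private counts genome-wide and in CDS.
    """
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if groups:
        for g, members in groups.items():
            unknown = set(members) - set(samples)
            if unknown:
                raise ValueError(f"group {g!r}: unknown samples {sorted(unknown)}")

    n_total = len(matrix.variants)
    presence = matrix.frequencies.ge(presence_threshold)
    n_private = {s: 0 for s in samples}
    for i in range(n_total):
        row = presence.iloc[i]
        carriers = [s for s in samples if row[s]]
        if len(carriers) == 1:
            n_private[carriers[0]] += 1

    region_counts: dict[str, int] = {}
    in_cds = [False] * n_total
    if annotations is not None:
        region_counts = {c: 0 for c in REGION_CLASSES}
        for i, v in enumerate(matrix.variants):
            cls, _ = classify_variant_region(v, annotations)
            region_counts[cls] += 1
            in_cds[i] = cls == "coding"
        n_cds = region_counts["coding"]
    else:
        n_cds = 0

    n_indels = sum(1 for v in matrix.variants if v.is_indel)
    n_frameshift = sum(
        1 for v in matrix.variants if v.is_indel and v.delta % 3 != 0
    )

    group_summaries: dict[str, dict[str, int]] = {}
    for g, members in (groups or {}).items():
        member_set = set(members)
        tot = tot_cds = priv = priv_cds = 0
        for i in range(n_total):
            row = presence.iloc[i]
            carriers = {s for s in samples if row[s]}
            if carriers & member_set:
                tot += 1
                is_private = carriers <= member_set
                if is_private:
                    priv += 1
                if in_cds[i]:
                    tot_cds += 1
                    if is_private:
                        priv_cds += 1
        group_summaries[g] = {
            "n_total": tot, "n_private": priv,
            "n_cds": tot_cds, "n_private_cds": priv_cds,
        }

    return SpSummary(
        n_total=n_total,
        n_cds=n_cds,
        n_private_by_sample=n_private,
        n_indels=n_indels,
        n_frameshift=n_frameshift,
        region_counts=region_counts,
        group_summaries=group_summaries,
    )


# ---------------------------------------------------------------------------
# SP frequency


@dataclass
class SpFrequency:
    rate: float  # raw per-bp rate
    one_every: int | None  # "1 every N bp"; None when no SPs

    @property
    def rate_4dp(self) -> float:
        return round(self.rate, 4)


def sp_frequency(n_sp: int, region_length: int) -> SpFrequency:
    """Polymorphism density: per-bp rate and its "1 every N bp" form."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if n_sp < 0:
        raise ValueError("n_sp must be non-negative")
    if n_sp == 0:
        return SpFrequency(rate=0.0, one_every=None)
    return SpFrequency(
        rate=n_sp / region_length,
        one_every=round(region_length / n_sp),
    )


# ---------------------------------------------------------------------------
# Variant application and ORF re-scan


@dataclass
class RescanResult:
    sequence: str
    nt_length: int
    aa_length: int
    stop_codon: str | None
    complete: bool
    protein: str


def apply_variants_rescan_orf(
    cds: str,
    variants: list[VariantRecord],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> RescanResult:
    """Apply alleles to a CDS and re-scan the ORF from its original start.

    Variant positions are CDS-local (1-based) and must not overlap; alleles
    are applied right-to-left so earlier edits cannot shift later
    coordinates.  The ORF is then read codon by codon from position 1 to the
    first in-frame stop; the reported nucleotide length includes the stop
    codon, and the amino-acid length excludes it.
    """
    cds = cds.upper()
    ordered = sorted(variants, key=lambda v: v.position)
    for v in ordered:
        if not 1 <= v.position <= len(cds):
            raise ValueError(f"variant position {v.position} beyond CDS")
        if v.position + len(v.ref_allele) - 1 > len(cds):
            raise ValueError(f"variant at {v.position}: REF extends beyond CDS")
        ref_here = cds[v.position - 1 : v.position - 1 + len(v.ref_allele)]
        if ref_here != v.ref_allele:
            raise ValueError(
                f"variant at {v.position}: REF {v.ref_allele} does not match "
                f"CDS ({ref_here})"
            )
    for a, b in zip(ordered, ordered[1:]):
        if a.position + len(a.ref_allele) - 1 >= b.position:
            raise ValueError(
                f"overlapping variants at {a.position} and {b.position}"
            )
    seq = cds
    for v in reversed(ordered):
        i = v.position - 1
        seq = seq[:i] + v.alt_allele + seq[i + len(v.ref_allele):]

    protein: list[str] = []
    stop_codon = None
    nt_length = len(seq)
    complete = False
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if code.is_stop(codon):
            stop_codon = codon
            nt_length = i + 3
            complete = True
            break
        protein.append(code.translate(codon))
    return RescanResult(
        sequence=seq,
        nt_length=nt_length,
        aa_length=len(protein),
        stop_codon=stop_codon,
        complete=complete,
        protein="".join(protein),
    )
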