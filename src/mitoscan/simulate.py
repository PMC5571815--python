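"""Synthetic circular mitogenomes with known ground truth.

The generator emulates the architecture of a venerid bivalve mitogenome —
13 protein-coding genes, 22 tRNAs, 2 rRNAs, two dozen short unassigned
regions and one large UR carrying a tandem repeat of configurable period and
fractional copy number — so every pipeline stage can be tested against
planted truth without any external data.

Two generation rules make annotation recovery provable rather than merely
likely: coding sequences are built codon-wise with no internal in-frame
stop, and unassigned regions are sampled with no "AT" dinucleotide (checked
across junctions too).  Since all three accepted start codons (ATG, ATA,
ATC) begin with AT, a UR generated this way cannot contain, or straddle
into, a spurious start codon — the first start codon downstream of any
feature is exactly the planted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import (
    INVERTEBRATE_MITO,
    GeneticCode,
    UnassignedRegion,
)
from .genome_io import (
    AnnotationSet,
    CircularGenome,
    FeatureAnnotation,
    SampleGenotypeMatrix,
    VariantRecord,
)
from .repeats import RepeatCall

BASES = "ACGT"


@dataclass
class ElementSpec:
    """One element of the genome layout: a gene, an RNA, or a UR."""

    name: str
    ftype: str  # coding | tRNA | rRNA | UR
    length: int
    start_codon: str = "ATG"
    stop_codon: str = "TAA"  # "TA-"/"T--" for incomplete stops
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"element {self.name!r}: length must be >= 1")
        if self.ftype == "coding":
            stop_len = 3 - self.stop_codon.count("-")
            if (self.length - 3 - stop_len) % 3 or self.length < 3 + stop_len:
                raise ValueError(
                    f"gene {self.name!r}: length {self.length} incompatible "
                    f"with start + body codons + stop {self.stop_codon!r}"
                )


@dataclass
class RepeatSpec:
    period: int = 54
    copy_number: float = 6.5
    target_ur: str = ""  # name of the UR element carrying the repeat
    mutation_rate: float = 0.0  # substitutions per base, per copy

    @property
    def span(self) -> int:
        return int(round(self.period * self.copy_number))


@dataclass
class GenomeSpec:
    """Ordered layout plus codon bias, repeat placement and the seed."""

    layout: list[ElementSpec]
    repeat_spec: RepeatSpec | None = None
    codon_bias: dict[str, float] | None = None
    seed: int = 42
    genome_id: str = "synthetic-mito"

    @property
    def gene_order(self) -> list[ElementSpec]:
        return [e for e in self.layout if e.ftype != "UR"]

    @property
    def ur_lengths(self) -> list[int]:
        return [e.length for e in self.layout if e.ftype == "UR"]

    def validate(self, code: GeneticCode = INVERTEBRATE_MITO) -> None:
        if self.repeat_spec is not None:
            target = next(
                (e for e in self.layout
                 if e.ftype == "UR" and e.name == self.repeat_spec.target_ur),
                None,
            )
            if target is None:
                raise ValueError(
                    f"repeat target UR {self.repeat_spec.target_ur!r} not in layout"
                )
            if self.repeat_spec.span > target.length:
                raise ValueError(
                    f"UR {target.name!r} ({target.length} bp) too short for "
                    f"repeat span {self.repeat_spec.span} bp"
                )
        if self.codon_bias is not None:
            if any(w < 0 for w in self.codon_bias.values()):
                raise ValueError("codon weights must be non-negative")
            usable = {
                c: w for c, w in self.codon_bias.items()
                if w > 0 and not code.is_stop(c)
            }
            if not usable:
                raise ValueError("codon bias leaves no usable (non-stop) codon")


@dataclass
class TruthSet:
    """Everything the generator planted, for direct comparison in tests."""

    genome: CircularGenome
    annotations: AnnotationSet
    urs: list[UnassignedRegion]
    planted_repeats: list[RepeatCall] = field(default_factory=list)
    planted_variants: list[VariantRecord] = field(default_factory=list)
    carrier_map: dict[str, list[str]] = field(default_factory=dict)
    planted_polya: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence sampling helpers


def sample_codons(
    rng: np.random.Generator,
    n: int,
    bias: dict[str, float] | None = None,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> list[str]:
    """Draw ``n`` non-stop codons from a weight map (uniform by default)."""
    if bias is None:
        pool = sorted(c for c in code.codon_to_aa if not code.is_stop(c))
        weights = np.ones(len(pool))
    else:
        pool = sorted(
            c.upper() for c, w in bias.items()
            if w > 0 and not code.is_stop(c)
        )
        weights = np.array([bias[c] if c in bias else bias[c.upper()]
                            for c in pool], dtype=float)
    weights = weights / weights.sum()
    idx = rng.choice(len(pool), size=n, p=weights)
    return [pool[i] for i in idx]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _no_at_seq(rng: np.random.Generator, length: int, prev_char: str) -> str:
    """Random sequence containing no AT dinucleotide, also across ``prev_char``."""
    out = []
    prev = prev_char
    for _ in range(length):
        choices = "ACG" if prev == "A" else BASES
        b = choices[rng.integers(0, len(choices))]
        out.append(b)
        prev = b
    return "".join(out)


def _no_at_unit(rng: np.random.Generator, period: int, prev_char: str) -> str:
    """A repeat unit free of AT inside, across tandem junctions and entry."""
    while True:
        unit = _no_at_seq(rng, period, prev_char)
        if not (unit[-1] == "A" and unit[0] == "T"):
            return unit


# ---------------------------------------------------------------------------
# Genome generation


def generate_genome(
    spec: GenomeSpec, code: GeneticCode = INVERTEBRATE_MITO
) -> tuple[CircularGenome, TruthSet]:
    """Assemble a circular genome from the layout; deterministic per seed."""
    spec.validate(code)
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    features: list[FeatureAnnotation] = []
    urs: list[UnassignedRegion] = []
    planted_repeats: list[RepeatCall] = []
    pos = 1
    prev_char = ""
    ur_index = 0
    for elem in spec.layout:
        if elem.ftype == "coding":
            seq = _generate_cds(rng, elem, spec.codon_bias, code)
        elif elem.ftype in ("tRNA", "rRNA"):
            seq = _random_seq(rng, elem.length)
        else:
            ur_index += 1
            if (spec.repeat_spec is not None
                    and elem.name == spec.repeat_spec.target_ur):
                seq, rep = _generate_repeat_ur(
                    rng, elem.length, spec.repeat_spec, prev_char
                )
                rep.start += pos - 1
                planted_repeats.append(rep)
            else:
                seq = _no_at_seq(rng, elem.length, prev_char)
        stop = pos + elem.length - 1
        if elem.ftype == "UR":
            urs.append(UnassignedRegion(elem.name, pos, stop, elem.length))
        else:
            features.append(FeatureAnnotation(
                name=elem.name,
                ftype=elem.ftype,
                start=pos,
                stop=stop,
                strand="+",
                anticodon=elem.anticodon,
                start_codon=elem.start_codon if elem.ftype == "coding" else None,
                stop_codon=elem.stop_codon if elem.ftype == "coding" else None,
            ))
        parts.append(seq)
        pos = stop + 1
        prev_char = seq[-1]
    sequence = "".join(parts)
    genome = CircularGenome(spec.genome_id, sequence, circular=True)
    annotations = AnnotationSet(spec.genome_id, len(sequence), features)
    truth = TruthSet(
        genome=genome,
        annotations=annotations,
        urs=urs,
        planted_repeats=planted_repeats,
    )
    return genome, truth


def _generate_cds(
    rng: np.random.Generator,
    elem: ElementSpec,
    bias: dict[str, float] | None,
    code: GeneticCode,
) -> str:
    stop_txt = elem.stop_codon.replace("-", "")
    n_body = (elem.length - 3 - len(stop_txt)) // 3
    body = sample_codons(rng, n_body, bias, code) if n_body else []
    return elem.start_codon + "".join(body) + stop_txt


def _generate_repeat_ur(
    rng: np.random.Generator,
    ur_length: int,
    rep: RepeatSpec,
    prev_char: str,
) -> tuple[str, RepeatCall]:
    """UR with a tandem array at its 3' end (as in the reference LUR)."""
    span = rep.span
    flank = _no_at_seq(rng, ur_length - span, prev_char)
    unit = _no_at_unit(rng, rep.period, flank[-1] if flank else prev_char)
    n_full, partial = divmod(span, rep.period)
    array = unit * n_full + unit[:partial]
    if rep.mutation_rate > 0:
        array = _mutate_no_at(rng, array, rep.mutation_rate)
    seq = flank + array
    call = RepeatCall(
        start=len(flank) + 1,  # UR-local; shifted to genome coords by caller
        span=span,
        period=rep.period,
        copy_number=span / rep.period,
        consensus=unit,
        identity=1.0,
    )
    return seq, call


def _mutate_no_at(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    sites = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for i in sorted(sites.tolist()):
        left = out[i - 1] if i > 0 else ""
        right = out[i + 1] if i + 1 < len(out) else ""
        allowed = [b for b in BASES if b != out[i]
                   and not (left == "A" and b == "T")
                   and not (b == "A" and right == "T")]
        if allowed:
            out[i] = allowed[rng.integers(0, len(allowed))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Transcript contigs with poly-A tails


def generate_transcript_contigs(
    genome: CircularGenome,
    truth: TruthSet,
    polya_runs: list[int],
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Contigs spanning 1-8 consecutive genes, each with an appended A-run.

    Returns ``(contigs, planted)`` where contigs are (id, sequence) pairs and
    planted maps contig id to its appended run length.
    """
    if any(r < 0 for r in polya_runs):
        raise ValueError("poly-A run lengths must be >= 0")
    rng = np.random.default_rng(seed)
    genic = truth.annotations.genic_features
    contigs: list[tuple[str, str]] = []
    planted: dict[str, int] = {}
    for k, run in enumerate(polya_runs, 1):
        # choose a window whose genomic end is not A, so the appended run is
        # exactly the trailing A-run of the contig (truth stays exact)
        for _ in range(200):
            n_genes = int(rng.integers(1, min(8, len(genic)) + 1))
            first = int(rng.integers(0, len(genic) - n_genes + 1))
            block = genic[first : first + n_genes]
            start, stop = block[0].start, block[-1].stop
            if genome.base(stop) != "A":
                break
        else:
            raise ValueError("could not find a window ending on a non-A base")
        if not genome.circular and stop < start:
            raise ValueError("contig window exceeds linear genome")
        seq = genome.fetch(start, stop) + "A" * run
        cid = f"contig{k}"
        contigs.append((cid, seq))
        planted[cid] = run
    truth.planted_polya.update(planted)
    return contigs, planted


# ---------------------------------------------------------------------------
# Variant tables


@dataclass
class VariantTruth:
    records: list[VariantRecord]
    matrix: SampleGenotypeMatrix
    carrier_map: dict[str, list[str]]
    n_private_by_sample: dict[str, int]
    n_cds: int
    n_indels: int
    n_frameshift: int


def generate_variant_table(
    truth: TruthSet,
    n_samples: int,
    n_variants: int,
    private_fraction_by_sample: dict[str, float] | None = None,
    indel_fraction: float = 0.0,
    seed: int = 0,
) -> VariantTruth:
    """Plant variants with known carriers on the synthetic genome.

    ``private_fraction_by_sample`` maps sample name to the fraction of
    variants private to it (single carrier); remaining variants are shared
    by at least two samples and therefore private to none.  Carrier
    frequencies are drawn in [0.6, 1.0]; non-carriers have frequency 0.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if not 0.0 <= indel_fraction <= 1.0:
        raise ValueError("indel_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    private_fraction_by_sample = private_fraction_by_sample or {}
    for s in private_fraction_by_sample:
        if s not in samples:
            raise ValueError(f"unknown sample {s!r} in private fractions")
    private_counts = {
        s: int(round(f * n_variants))
        for s, f in private_fraction_by_sample.items()
    }
    if sum(private_counts.values()) > n_variants:
        raise ValueError("requested private counts exceed n_variants")

    genome = truth.genome
    n = len(genome)
    positions = sorted(
        int(p) + 1 for p in rng.choice(n - 6, size=n_variants, replace=False)
    )
    n_indels_target = int(round(indel_fraction * n_variants))
    is_indel = np.zeros(n_variants, dtype=bool)
    if n_indels_target:
        is_indel[rng.choice(n_variants, size=n_indels_target, replace=False)] = True

    # assign ownership: blocks of private variants per sample, rest shared
    owners: list[str | None] = []
    for s, k in private_counts.items():
        owners.extend([s] * k)
    owners.extend([None] * (n_variants - len(owners)))
    rng.shuffle(owners)  # type: ignore[arg-type]

    records: list[VariantRecord] = []
    carrier_map: dict[str, list[str]] = {}
    n_frameshift = 0
    for pos, owner, indel in zip(positions, owners, is_indel):
        ref_base = genome.base(pos)
        if indel:
            delta = int(rng.choice([-3, -2, -1, 1, 2, 3]))
            if delta > 0:
                ref = ref_base
                alt = ref_base + _random_seq(rng, delta)
            else:
                ref = genome.fetch(pos, pos - delta)
                alt = ref_base
            if delta % 3 != 0:
                n_frameshift += 1
        else:
            ref = ref_base
            alt = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        if owner is not None:
            carriers = [owner]
        else:
            k = int(rng.integers(2, n_samples + 1))
            carriers = sorted(
                str(samples[i]) for i in rng.choice(n_samples, size=k, replace=False)
            )
        freqs = {s: float(rng.uniform(0.6, 1.0)) for s in carriers}
        rec = VariantRecord(
            position=pos, ref_allele=ref, alt_allele=alt,
            per_sample_frequency=freqs, quality=float(rng.uniform(30, 5000)),
        )
        records.append(rec)
        carrier_map[f"{pos}:{ref}>{alt}"] = carriers

    matrix = SampleGenotypeMatrix(records, samples)
    n_private = {s: 0 for s in samples}
    for key, carriers in carrier_map.items():
        if len(carriers) == 1:
            n_private[carriers[0]] += 1
    n_cds = sum(
        1 for r in records
        if (f := truth.annotations.feature_at(r.position)) is not None
        and f.ftype == "coding"
    )
    truth.planted_variants = records
    truth.carrier_map = carrier_map
    return VariantTruth(
        records=records,
        matrix=matrix,
        carrier_map=carrier_map,
        n_private_by_sample=n_private,
        n_cds=n_cds,
        n_indels=int(is_indel.sum()),
        n_frameshift=n_frameshift,
    )


# ---------------------------------------------------------------------------
# The default, venerid-like architecture


def venerid_like(seed: int = 42) -> GenomeSpec:
    """The default study architecture: 13 CDS, 22 tRNA, 2 rRNA, 24 URs,
    and a 54 bp x 6.5 tandem repeat in the large UR between atp8 and nd5.

    Gene and UR lengths, start/stop codons and anticodons mirror the
    published reference annotation that ships with the package.
    """
    from .annotation import extract_unassigned_regions
    from .data import load_reference_annotation

    ref = load_reference_annotation()
    urs = extract_unassigned_regions(ref)
    ur_by_start = {u.start: u for u in urs}
    layout: list[ElementSpec] = []
    lur = max(urs, key=lambda u: u.length)
    events: list[tuple[int, ElementSpec]] = []
    for f in ref.genic_features:
        events.append((f.start, ElementSpec(
            name=f.name, ftype=f.ftype,
            length=f.length(ref.genome_length),
            start_codon=f.start_codon or "ATG",
            stop_codon=f.stop_codon or "TAA",
            anticodon=f.anticodon,
        )))
    for u in urs:
        events.append((u.start, ElementSpec(u.name, "UR", u.length)))
    layout = [e for _, e in sorted(events, key=lambda t: t[0])]
    return GenomeSpec(
        layout=layout,
        repeat_spec=RepeatSpec(period=54, copy_number=6.5, target_ur=lur.name),
        seed=seed,
        genome_id=f"venerid-sim-{seed}",
    )
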