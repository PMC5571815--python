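"""Annotation conventions for invertebrate mitochondrial genomes.

Protein-coding genes are located by ORF scanning under the invertebrate
mitochondrial genetic code (NCBI translation table 5), with the alternative
start codons ATA and ATC accepted alongside ATG, and TAA/TAG as stops.
A gene may end on an incomplete stop codon ("TA-" or "T--") at an annotation
boundary; such stops are presumed completed to TAA by polyadenylation of the
transcript, so they are only accepted where the gene directly abuts the next
annotated feature.  Everything left unannotated between genes is an
unassigned region (UR); the largest one (LUR) is presumed to contain the
control region.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome_io import AnnotationSet, CircularGenome, FeatureAnnotation

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationConflictError(ValueError):
    """A gene boundary that admits neither a complete nor an incomplete stop."""


@dataclass(frozen=True)
class GeneticCode:
    """Invertebrate mitochondrial code with the annotation start/stop sets.

    The 64-codon amino-acid map is NCBI translation table 5 (AGA/AGG = Ser,
    ATA = Met, TGA = Trp).  The start set {ATG, ATA, ATC} is the annotation
    convention used here, wider than NCBI's initiator list; stops are TAA/TAG.
    """

    table_id: int = 5
    codon_to_aa: dict[str, str] = field(default_factory=dict)
    start_codons: frozenset[str] = frozenset({"ATG", "ATA", "ATC"})
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG"})

    def __post_init__(self) -> None:
        if not self.codon_to_aa:
            table = CodonTable.unambiguous_dna_by_id[self.table_id]
            mapping = dict(table.forward_table)
            for stop in table.stop_codons:
                mapping[stop] = "*"
            object.__setattr__(self, "codon_to_aa", mapping)
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map exactly 64 codons")
        if self.start_codons & self.stop_codons:
            raise ValueError("start and stop codon sets must be disjoint")

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper()]

    def is_start(self, codon: str) -> bool:
        return codon.upper() in self.start_codons

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


INVERTEBRATE_MITO = GeneticCode()


@dataclass
class OrfCall:
    """An open reading frame located on the genome.

    ``stop_codon`` is a 3-letter codon when ``complete``; "TA-" or "T--" for
    a boundary-truncated stop; ``None`` when the scan found a start but no
    acceptable end.
    """

    start: int
    stop: int
    frame: int
    start_codon: str
    stop_codon: str | None
    complete: bool

    def length(self, genome_length: int) -> int:
        from .genome_io import span_length

        return span_length(self.start, self.stop, genome_length)

    @property
    def has_end(self) -> bool:
        return self.stop_codon is not None


@dataclass
class UnassignedRegion:
    """A maximal unannotated interval between genes."""

    name: str
    start: int
    stop: int
    length: int

    def to_feature(self) -> FeatureAnnotation:
        return FeatureAnnotation(self.name, "UR", self.start, self.stop)


# ---------------------------------------------------------------------------
# ORF scanning


def scan_orf_downstream(
    genome: CircularGenome,
    anchor: int,
    code: GeneticCode = INVERTEBRATE_MITO,
    boundary: int | None = None,
) -> OrfCall | None:
    """Locate the ORF starting at the first start codon downstream of ``anchor``.

    ``anchor`` is the 1-based position of the last base of the preceding
    feature (0 to scan from the first base).  The first start codon is the
    one with the smallest downstream offset, in any frame; extension then
    proceeds in that frame to the first in-frame TAA/TAG.  If ``boundary``
    (the start of the next feature) is reached before a stop, incomplete-stop
    logic applies.  Returns ``None`` when no start codon exists in range.
    """
    n = len(genome)
    if n < 3:
        raise ValueError("genome shorter than one codon")
    if boundary is not None:
        limit = boundary - anchor - 1  # bases available downstream
    else:
        limit = n  # at most one full revolution
    start_pos = None
    for off in range(1, limit + 1):
        p = anchor + off
        if boundary is not None and anchor + off + 2 >= boundary:
            break
        codon = _codon_at(genome, p)
        if codon is None:
            break
        if code.is_start(codon):
            start_pos = p
            break
    if start_pos is None:
        return None
    frame = (start_pos - anchor - 1) % 3
    start_codon = _codon_at(genome, start_pos)
    # extend in-frame to the first stop
    q = start_pos + 3
    while True:
        if boundary is not None and q + 2 > boundary - 1:
            return _incomplete_call(genome, start_pos, frame, start_codon, q, boundary)
        if boundary is None and q - start_pos >= n:
            # a full revolution without an in-frame stop
            return OrfCall(_wrap(start_pos, n), _wrap(q - 1, n), frame,
                           start_codon, None, complete=False)
        codon = _codon_at(genome, q)
        if codon is None:
            return OrfCall(_wrap(start_pos, n), _wrap(q - 1, n), frame,
                           start_codon, None, complete=False)
        if code.is_stop(codon):
            return OrfCall(_wrap(start_pos, n), _wrap(q + 2, n), frame,
                           start_codon, codon, complete=True)
        q += 3


def detect_incomplete_stop(
    genome: CircularGenome,
    orf_start: int,
    next_feature_start: int,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> OrfCall:
    """Resolve an ORF that reaches the next feature without an in-frame stop.

    The residual bases between the last complete codon and
    ``next_feature_start`` decide the call: "TA" gives stop codon "TA-",
    "T" gives "T--" (both presumed completed to TAA by polyadenylation).
    An empty residual with no stop codon is an annotation conflict.
    """
    q = orf_start
    frame = 0
    start_codon = _codon_at(genome, orf_start)
    while q + 2 <= next_feature_start - 1:
        codon = _codon_at(genome, q)
        if q > orf_start and code.is_stop(codon):
            # precondition said no stop; honour the sequence if one exists
            return OrfCall(orf_start, q + 2, frame, start_codon, codon, True)
        q += 3
    return _incomplete_call(genome, orf_start, frame, start_codon, q,
                            next_feature_start)


def _incomplete_call(
    genome: CircularGenome,
    start_pos: int,
    frame: int,
    start_codon: str,
    q: int,
    boundary: int,
) -> OrfCall:
    """Classify the residual bases in [q, boundary) as an incomplete stop."""
    residual_len = boundary - q
    if residual_len == 0:
        raise AnnotationConflictError(
            f"ORF at {start_pos}: no stop codon and no residual bases before "
            f"position {boundary}"
        )
    residual = genome.fetch(q, boundary - 1)
    if residual == "TA":
        return OrfCall(start_pos, boundary - 1, frame, start_codon, "TA-", False)
    if residual == "T":
        return OrfCall(start_pos, boundary - 1, frame, start_codon, "T--", False)
    return OrfCall(start_pos, boundary - 1, frame, start_codon, None, False)


def _codon_at(genome: CircularGenome, pos: int) -> str | None:
    n = len(genome)
    if genome.circular:
        return "".join(genome.base(pos + k) for k in range(3))
    if pos + 2 > n:
        return None
    return genome.sequence[pos - 1 : pos + 2]


def _wrap(pos: int, n: int) -> int:
    return (pos - 1) % n + 1


# ---------------------------------------------------------------------------
# Unassigned regions


def extract_unassigned_regions(annotations: AnnotationSet) -> list[UnassignedRegion]:
    """Maximal unannotated intervals between non-UR features.

    On a circular genome the junction between the last feature and the first
    is included; a gap spanning the origin is emitted as a single wrap-around
    UR.  Regions are named UR1..URn in order of start coordinate.
    """
    n = annotations.genome_length
    covered: list[tuple[int, int]] = []
    for f in annotations.genic_features:
        covered.extend(f.intervals(n))
    gaps = _complement_intervals(covered, n, circular=True)
    gaps.sort(key=lambda g: g[0])
    urs = []
    for i, (s, e) in enumerate(gaps, 1):
        from .genome_io import span_length

        urs.append(UnassignedRegion(f"UR{i}", s, e, span_length(s, e, n)))
    return urs


def _complement_intervals(
    covered: list[tuple[int, int]], n: int, circular: bool
) -> list[tuple[int, int]]:
    if not covered:
        return [(1, n)]
    merged: list[list[int]] = []
    for s, e in sorted(covered):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps: list[tuple[int, int]] = []
    for (s1, e1), (s2, _) in zip(merged, merged[1:]):
        if s2 > e1 + 1:
            gaps.append((e1 + 1, s2 - 1))
    first_s, last_e = merged[0][0], merged[-1][1]
    left = first_s > 1  # uncovered prefix 1..first_s-1
    right = last_e < n  # uncovered suffix last_e+1..n
    if circular:
        if left and right:
            gaps.append((last_e + 1, first_s - 1))  # wraps the origin
        elif left:
            gaps.append((1, first_s - 1))
        elif right:
            gaps.append((last_e + 1, n))
    else:
        if left:
            gaps.append((1, first_s - 1))
        if right:
            gaps.append((last_e + 1, n))
    return gaps


def find_lur(urs: list[UnassignedRegion]) -> UnassignedRegion:
    """The largest UR; ties resolved toward the smallest start coordinate."""
    if not urs:
        raise ValueError("no unassigned regions supplied")
    return max(urs, key=lambda u: (u.length, -u.start))


# ---------------------------------------------------------------------------
# Start/stop codon census


@dataclass
class CodonCensus:
    per_gene: dict[str, tuple[str, str]]
    start_counts: Counter
    stop_counts: Counter
    incomplete_stop_counts: Counter
    non_canonical_starts: list[str]

    @property
    def n_incomplete(self) -> int:
        return sum(self.incomplete_stop_counts.values())


def codon_census(
    annotations: AnnotationSet,
    genome: CircularGenome,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonCensus:
    """Tally start and stop codons over all coding features.

    Minus-strand genes are reverse-complemented first.  A trailing residual
    of 1-2 nt is reported as an incomplete stop ("T--"/"TA-") and tallied
    separately from complete stops.  A first codon outside the start set is
    recorded as non-canonical with a warning.
    """
    per_gene: dict[str, tuple[str, str]] = {}
    starts: Counter = Counter()
    stops: Counter = Counter()
    incomplete: Counter = Counter()
    non_canonical: list[str] = []
    for feat in annotations.of_type("coding"):
        seq = genome.fetch(feat.start, feat.stop)
        if feat.strand == "-":
            seq = reverse_complement(seq)
        start_codon = seq[:3]
        residual = len(seq) % 3
        if residual == 0:
            stop_codon = seq[-3:]
            stops[stop_codon] += 1
        elif residual == 2:
            stop_codon = seq[-2:] + "-"
            incomplete[stop_codon] += 1
        else:
            stop_codon = seq[-1] + "--"
            incomplete[stop_codon] += 1
        if not code.is_start(start_codon):
            warnings.warn(
                f"gene {feat.name!r}: non-canonical start codon {start_codon}",
                stacklevel=2,
            )
            non_canonical.append(feat.name)
        starts[start_codon] += 1
        per_gene[feat.name] = (start_codon, stop_codon)
    return CodonCensus(per_gene, starts, stops, incomplete, non_canonical)


# ---------------------------------------------------------------------------
# Poly-A tails


@dataclass
class PolyATail:
    status: str  # present | ambiguous | absent
    run: int


def detect_polya_tail(contig: str, min_run: int = 10) -> PolyATail:
    """Classify the 3' adenine run of a transcript contig.

    A trailing run of at least ``min_run`` As is a clear polyadenylation
    signal; a shorter non-zero run is ambiguous; no trailing A means absent.
    """
    if not contig:
        raise ValueError("empty contig")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seq = contig.upper()
    run = len(seq) - len(seq.rstrip("A"))
    if run >= min_run:
        return PolyATail("present", run)
    if run > 0:
        return PolyATail("ambiguous", run)
    return PolyATail("absent", 0)
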