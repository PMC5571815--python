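"""Data model and file I/O for circular mitochondrial genomes.

Coordinates are 1-based and inclusive everywhere in this package, matching
GFF3 and the conventional mitogenome annotation tables.  A feature whose
``start`` exceeds its ``stop`` wraps around the origin of a circular genome.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
FEATURE_TYPES = ("coding", "tRNA", "rRNA", "UR")

#: header of the feature-table dialect (one row per annotated feature)
FEATURE_TSV_COLUMNS = [
    "name", "type", "start", "stop", "strand",
    "anticodon", "start_codon", "stop_codon",
]


class GenomeIOError(ValueError):
    """Raised for malformed genome, feature or variant files."""


@dataclass
class CircularGenome:
    """A nucleotide sequence with explicit (usually circular) topology."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise GenomeIOError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeIOError(
                f"genome {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, stop: int) -> str:
        """Subsequence from ``start`` to ``stop``, 1-based inclusive.

        ``start > stop`` wraps around the origin on a circular genome.
        """
        n = len(self.sequence)
        if not (1 <= start <= n and 1 <= stop <= n):
            raise GenomeIOError(
                f"coordinates {start}..{stop} outside genome of length {n}"
            )
        if start <= stop:
            return self.sequence[start - 1 : stop]
        if not self.circular:
            raise GenomeIOError("wrap-around fetch on a linear genome")
        return self.sequence[start - 1 :] + self.sequence[:stop]

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (modular on circular genomes)."""
        n = len(self.sequence)
        if self.circular:
            return self.sequence[(pos - 1) % n]
        if not 1 <= pos <= n:
            raise GenomeIOError(f"position {pos} outside linear genome")
        return self.sequence[pos - 1]


def span_length(start: int, stop: int, genome_length: int) -> int:
    """Length of a 1-based inclusive span, allowing origin wrap-around."""
    if stop >= start:
        return stop - start + 1
    return (genome_length - start + 1) + stop


@dataclass
class FeatureAnnotation:
    """A typed genomic interval: coding gene, tRNA, rRNA or unassigned region."""

    name: str
    ftype: str
    start: int
    stop: int
    strand: str = "+"
    anticodon: str | None = None  # tRNAs only, written 5'->3'
    start_codon: str | None = None  # coding only
    stop_codon: str | None = None  # coding only; "TA-"/"T--" if incomplete

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise GenomeIOError(
                f"feature {self.name!r}: unknown type {self.ftype!r}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.ftype == "tRNA":
            if not self.anticodon or len(self.anticodon) != 3:
                raise GenomeIOError(
                    f"tRNA {self.name!r} requires a 3-letter anticodon"
                )
            self.anticodon = self.anticodon.upper()
        elif self.anticodon:
            raise GenomeIOError(
                f"feature {self.name!r}: anticodon only valid for tRNAs"
            )

    def length(self, genome_length: int) -> int:
        return span_length(self.start, self.stop, genome_length)

    def wraps(self) -> bool:
        return self.stop < self.start

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """Covered 1-based inclusive intervals; two pieces if wrapping."""
        if not self.wraps():
            return [(self.start, self.stop)]
        return [(self.start, genome_length), (1, self.stop)]


class AnnotationSet:
    """An ordered, non-overlapping annotation of one genome.

    Features are kept sorted by start coordinate.  Overlap among non-UR
    features is rejected; URs may coincide with anything (they are derived).
    """

    def __init__(
        self,
        genome_id: str,
        genome_length: int,
        features: Iterable[FeatureAnnotation] = (),
    ) -> None:
        if genome_length < 1:
            raise GenomeIOError("genome_length must be >= 1")
        self.genome_id = genome_id
        self.genome_length = genome_length
        self.features: list[FeatureAnnotation] = []
        for f in features:
            self.add(f)

    def add(self, feature: FeatureAnnotation) -> None:
        n = self.genome_length
        if not (1 <= feature.start <= n and 1 <= feature.stop <= n):
            raise GenomeIOError(
                f"feature {feature.name!r} ({feature.start}..{feature.stop}) "
                f"outside genome of length {n}"
            )
        if feature.ftype != "UR":
            for other in self.features:
                if other.ftype == "UR":
                    continue
                if self._overlap(feature, other):
                    raise GenomeIOError(
                        f"features {feature.name!r} and {other.name!r} overlap"
                    )
        self.features.append(feature)
        self.features.sort(key=lambda f: (f.start, f.stop))

    def _overlap(self, a: FeatureAnnotation, b: FeatureAnnotation) -> bool:
        n = self.genome_length
        for s1, e1 in a.intervals(n):
            for s2, e2 in b.intervals(n):
                if s1 <= e2 and s2 <= e1:
                    return True
        return False

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[FeatureAnnotation]:
        return iter(self.features)

    def of_type(self, ftype: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.ftype == ftype]

    @property
    def genic_features(self) -> list[FeatureAnnotation]:
        """All non-UR features in genome order."""
        return [f for f in self.features if f.ftype != "UR"]

    def genic_length(self) -> int:
        return sum(f.length(self.genome_length) for f in self.genic_features)

    def feature_at(self, position: int) -> FeatureAnnotation | None:
        """The feature covering a 1-based position (non-UR first, then UR)."""
        if not 1 <= position <= self.genome_length:
            raise GenomeIOError(
                f"position {position} outside genome of length {self.genome_length}"
            )
        hit_ur = None
        for f in self.features:
            for s, e in f.intervals(self.genome_length):
                if s <= position <= e:
                    if f.ftype != "UR":
                        return f
                    hit_ur = f
        return hit_ur


@dataclass
class VariantRecord:
    """One REF/ALT allele pair with per-sample alternate-allele frequencies."""

    position: int
    ref_allele: str
    alt_allele: str
    per_sample_frequency: dict[str, float] = field(default_factory=dict)
    quality: float = 0.0

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise GenomeIOError("ref and alt alleles must be non-empty")
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        for s, f in self.per_sample_frequency.items():
            if not 0.0 <= f <= 1.0:
                raise GenomeIOError(
                    f"variant at {self.position}: frequency {f} for {s} "
                    "outside [0, 1]"
                )
        if self.quality < 0:
            raise GenomeIOError("quality must be non-negative")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def delta(self) -> int:
        """Signed length change, len(alt) - len(ref)."""
        return len(self.alt_allele) - len(self.ref_allele)


class SampleGenotypeMatrix:
    """Alternate-allele frequencies as a variants x samples table."""

    def __init__(self, variants: Sequence[VariantRecord], samples: Sequence[str]):
        self.variants = list(variants)
        self.samples = list(samples)
        rows = []
        for v in self.variants:
            rows.append([v.per_sample_frequency.get(s, 0.0) for s in samples])
        index = [
            f"{v.position}:{v.ref_allele}>{v.alt_allele}" for v in self.variants
        ]
        self.frequencies = pd.DataFrame(rows, index=index, columns=list(samples))

    def carriers(self, variant_idx: int, threshold: float = 0.1) -> list[str]:
        row = self.frequencies.iloc[variant_idx]
        return [s for s in self.samples if row[s] >= threshold]

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | Path, circular: bool = True) -> CircularGenome:
    """Load the first record of a FASTA file as a :class:`CircularGenome`."""
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise GenomeIOError(f"{path}: empty file")
        if not first.startswith(">"):
            raise GenomeIOError(f"{path}: line 1 is not a FASTA header: {first!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} records; loading only the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq), circular=circular)


def write_genome(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    # Biopython wraps at 60; rewrap at the requested width for stable output
    if width != 60:
        lines = [f">{genome.id}"]
        seq = genome.sequence
        lines += [seq[i : i + width] for i in range(0, len(seq), width)]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Feature tables (TSV dialect and GFF3)

_GFF_TYPE_OUT = {"coding": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "UR": "region"}
_GFF_TYPE_IN = {v: k for k, v in _GFF_TYPE_OUT.items()}
_GFF_TYPE_IN.update({"gene": "coding", "CDS": "coding"})


def read_features(
    path: str | Path,
    dialect: str = "table_tsv",
    genome_length: int | None = None,
    genome_id: str | None = None,
) -> AnnotationSet:
    """Read an annotation table (``table_tsv`` or ``gff3`` dialect).

    The TSV dialect may carry ``# genome_length=N`` / ``# genome_id=X``
    comment lines; GFF3 uses the ``##sequence-region`` directive.  An explicit
    ``genome_length`` argument overrides both.
    """
    path = Path(path)
    if dialect in ("table_tsv", "table2_tsv", "tsv"):
        return _read_feature_tsv(path, genome_length, genome_id)
    if dialect == "gff3":
        return _read_gff3(path, genome_length, genome_id)
    raise GenomeIOError(f"unknown feature dialect {dialect!r}")


def _read_feature_tsv(
    path: Path, genome_length: int | None, genome_id: str | None
) -> AnnotationSet:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if genome_length is None:
        if "genome_length" not in meta:
            raise GenomeIOError(
                f"{path}: genome_length neither given nor in a '# genome_length=' line"
            )
        genome_length = int(meta["genome_length"])
    gid = genome_id or meta.get("genome_id", path.stem)

    required = {"name", "type", "start", "stop"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeIOError(f"{path}: missing columns {sorted(missing)}")

    features, bad_lengths = [], []
    for _, row in df.iterrows():
        start, stop = int(row["start"]), int(row["stop"])
        if "length" in df.columns and str(row["length"]).strip():
            expected = span_length(start, stop, genome_length)
            if int(row["length"]) != expected:
                bad_lengths.append(str(row["name"]))
        features.append(
            FeatureAnnotation(
                name=str(row["name"]),
                ftype=_normalize_type(str(row["type"])),
                start=start,
                stop=stop,
                strand=str(row.get("strand", "+")) or "+",
                anticodon=str(row.get("anticodon", "")) or None,
                start_codon=str(row.get("start_codon", "")) or None,
                stop_codon=str(row.get("stop_codon", "")) or None,
            )
        )
    if bad_lengths:
        raise GenomeIOError(
            f"{path}: length column inconsistent with coordinates for "
            f"{bad_lengths}"
        )
    return AnnotationSet(gid, genome_length, features)


def _normalize_type(raw: str) -> str:
    low = raw.strip().lower()
    mapping = {"coding": "coding", "cds": "coding", "trna": "tRNA",
               "rrna": "rRNA", "ur": "UR", "region": "UR"}
    if low not in mapping:
        raise GenomeIOError(f"unknown feature type {raw!r}")
    return mapping[low]


def write_features(aset: AnnotationSet, path: str | Path, dialect: str = "table_tsv") -> None:
    if dialect in ("table_tsv", "table2_tsv", "tsv"):
        rows = []
        for f in aset:
            rows.append({
                "name": f.name,
                "type": f.ftype,
                "start": f.start,
                "stop": f.stop,
                "length": f.length(aset.genome_length),
                "strand": f.strand,
                "anticodon": f.anticodon or "",
                "start_codon": f.start_codon or "",
                "stop_codon": f.stop_codon or "",
            })
        df = pd.DataFrame(rows, columns=["name", "type", "start", "stop",
                                         "length", "strand", "anticodon",
                                         "start_codon", "stop_codon"])
        with open(path, "w") as fh:
            fh.write(f"# genome_id={aset.genome_id}\n")
            fh.write(f"# genome_length={aset.genome_length}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {aset.genome_id} 1 {aset.genome_length}\n")
            for f in aset:
                attrs = [f"ID={f.name}", f"Name={f.name}"]
                if f.anticodon:
                    attrs.append(f"anticodon={f.anticodon}")
                if f.start_codon:
                    attrs.append(f"start_codon={f.start_codon}")
                if f.stop_codon:
                    attrs.append(f"stop_codon={f.stop_codon}")
                fh.write("\t".join([
                    aset.genome_id, "mitoscan", _GFF_TYPE_OUT[f.ftype],
                    str(f.start), str(f.stop), ".", f.strand, ".",
                    ";".join(attrs),
                ]) + "\n")
    else:
        raise GenomeIOError(f"unknown feature dialect {dialect!r}")


def _read_gff3(
    path: Path, genome_length: int | None, genome_id: str | None
) -> AnnotationSet:
    gid = genome_id
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    gid = gid or parts[1]
                    if genome_length is None:
                        genome_length = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 GFF columns")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            ftype = _GFF_TYPE_IN.get(cols[2])
            if ftype is None:
                logger.warning("%s:%d: skipping GFF type %r", path, lineno, cols[2])
                continue
            features.append(FeatureAnnotation(
                name=attrs.get("Name", attrs.get("ID", f"feat{lineno}")),
                ftype=ftype,
                start=int(cols[3]),
                stop=int(cols[4]),
                strand=cols[6] if cols[6] in "+-" else "+",
                anticodon=attrs.get("anticodon"),
                start_codon=attrs.get("start_codon"),
                stop_codon=attrs.get("stop_codon"),
            ))
    if genome_length is None:
        raise GenomeIOError(f"{path}: no ##sequence-region and no genome_length given")
    return AnnotationSet(gid or path.stem, genome_length, features)


# ---------------------------------------------------------------------------
# VCF subset


def read_variants(
    path: str | Path,
) -> tuple[list[VariantRecord], SampleGenotypeMatrix]:
    """Read a VCF; one record per ALT allele (multi-allelic sites split).

    Per-sample alternate-allele frequency comes from a FORMAT ``AF`` field if
    present, otherwise from allele depths (``AD``).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise GenomeIOError(f"{path}: VCF has no sample columns")
    records: list[VariantRecord] = []
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts):
            freqs: dict[str, float] = {}
            ok = True
            for s in samples:
                call = rec.samples[s]
                try:
                    freqs[s] = _sample_alt_frequency(call, ai, len(alts))
                except (KeyError, TypeError, ZeroDivisionError, IndexError):
                    ok = False
                    break
            if not ok:
                logger.warning(
                    "skipping variant at %s: unparsable sample field", rec.pos
                )
                continue
            records.append(VariantRecord(
                position=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alt,
                per_sample_frequency=freqs,
                quality=float(rec.qual) if rec.qual is not None else 0.0,
            ))
    return records, SampleGenotypeMatrix(records, samples)


def _sample_alt_frequency(call, alt_index: int, n_alts: int) -> float:
    if "AF" in call and call["AF"] is not None:
        af = call["AF"]
        if isinstance(af, (tuple, list)):
            val = af[alt_index]
        else:
            val = af
        if val is None:
            raise TypeError("missing AF")
        return float(val)
    ad = call["AD"]
    if ad is None or any(x is None for x in ad):
        raise TypeError("missing AD")
    total = sum(ad)
    return ad[alt_index + 1] / total


def write_variants(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contig: str = "mtDNA",
    contig_length: int = 100000,
) -> None:
    """Write records as an uncompressed VCF with GT and AF sample fields."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=AF,Number=A,Type=Float,'
        'Description="Alternate allele frequency">'
    )
    for s in samples:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for v in sorted(records, key=lambda r: r.position):
        rec = vf.new_record(
            contig=contig,
            start=v.position - 1,
            alleles=(v.ref_allele, v.alt_allele),
            qual=v.quality,
        )
        for s in samples:
            f = v.per_sample_frequency.get(s, 0.0)
            rec.samples[s]["GT"] = (1, 1) if f >= 0.9 else ((0, 1) if f > 0 else (0, 0))
            rec.samples[s]["AF"] = (f,)
        vf.write(rec)
    vf.close()
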