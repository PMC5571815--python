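"""Packaged reference tables for the *Ruditapes decussatus* mitogenome.

These are the published per-feature coordinates/anticodons, pooled codon
counts, LUR amplicon band lengths of the 13 re-sequenced females, and the
six coding-sequence indels of the polymorphism survey.  They let the
desk-scale analyses run with no external downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..genome_io import AnnotationSet, VariantRecord, read_features
from ..repeats import AmpliconLengthSet

#: total length (bp) of the Sanger-sequenced reference mitogenome (female F4)
REFERENCE_GENOME_LENGTH = 18995


def _path(name: str):
    return resources.files(__package__) / name


def load_reference_annotation() -> AnnotationSet:
    """The 37 annotated genes (13 coding, 22 tRNA, 2 rRNA) of the reference."""
    with resources.as_file(_path("rdecussatus_features.tsv")) as p:
        return read_features(p, dialect="table_tsv")


def load_reference_codon_counts() -> dict[str, int]:
    """Pooled codon counts over all 13 protein-coding genes (stops included)."""
    with resources.as_file(_path("rdecussatus_codon_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["codon"], df["count"].astype(int)))


def load_lur_band_lengths() -> list[AmpliconLengthSet]:
    """Gel-estimated LUR amplicon lengths for the 13 female samples."""
    with resources.as_file(_path("rdecussatus_lur_bands.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    out = []
    for _, row in df.iterrows():
        bands = [float(b) for b in str(row["band_lengths"]).split(";")]
        out.append(AmpliconLengthSet(str(row["sample"]), bands, str(row["source"])))
    return out


def load_cds_indels() -> list[VariantRecord]:
    """The six indels called in coding sequences, with per-sample frequencies."""
    with resources.as_file(_path("rdecussatus_cds_indels.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    records = []
    for _, row in df.iterrows():
        samples = str(row["samples"]).split(";")
        freqs = [float(f) for f in str(row["frequencies"]).split(";")]
        records.append(VariantRecord(
            position=int(row["position"]),
            ref_allele=str(row["ref"]),
            alt_allele=str(row["alt"]),
            per_sample_frequency=dict(zip(samples, freqs)),
            quality=float(row["quality"]),
        ))
    return records
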