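# Methods

This note documents the models, conventions and numerical choices behind
`mitoscan`, in the order the pipeline uses them.

## Coordinates and topology

All coordinates are 1-based and inclusive, in I/O and in every operation
contract (matching GFF3 and conventional mitogenome tables); any other
convention is converted at the boundary. A feature with `start > stop` wraps
the origin and is legal only on circular genomes; the shipped reference
annotation contains none, but the data model and the UR extractor support
them. Strand: the reference has every gene on the heavy (+) strand;
minus-strand features are accepted in I/O and are reverse-complemented
before any composition or codon statistic.

## Genetic code and ORF scanning

The amino-acid map is NCBI translation table 5 (invertebrate mitochondrial:
AGA/AGG = Ser, ATA = Met, TGA = Trp), taken from Biopython's codon tables.
The annotation start set {ATG, ATA, ATC} is wider than NCBI's initiator
list because alternative starts are functional in bivalves; stops are
TAA/TAG.

The scanner implements a positional, not frame-restricted, rule: the gene
ORF opens at the start codon with the smallest genomic offset downstream of
the preceding feature, searched in all three frames simultaneously, and
extends in that frame to the first TAA/TAG. When a supplied boundary (the
next feature's start) is reached first, the residual bases decide an
incomplete stop: `TA` → `TA-`, `T` → `T--` (both presumed completed to TAA
by polyadenylation of the transcript), an empty residual is an annotation
conflict, and anything else is a no-end result. Incomplete stops are
therefore only accepted where the gene directly abuts the next annotated
feature; an unbounded scan that makes a full revolution without an in-frame
stop returns a no-end call rather than looping.

## Unassigned regions

URs are the maximal unannotated intervals between non-UR features, computed
by interval complement on the circle; the junction between the last and
first feature is included, and a gap spanning the origin is emitted as a
single wrap-around UR. URs are named UR1..URn by start coordinate. The
extractor is order-independent and satisfies the conservation identity
Σ genic + Σ UR = genome length, which the tests assert on every synthetic
genome. The LUR is the longest UR, ties resolved toward the smaller start.

## Composition and codon usage

Base percentages exclude N from the denominator; third-position statistics
use every third base of complete codons, dropping a 1–2 nt trailing
residual. Reports round percentages to one decimal and family frequencies
to two decimals; raw values are kept on the objects so tests compare
unrounded numbers. The global `%TOT` denominator excludes stop codons by
default (an `include_stops` flag adds a STOP family), because published
codon-usage tables are ambiguous on this point and the exclusive convention
is the reproducible one; note the shipped reference composition aggregates
are computed from the feature coordinates, not copied from any printed
composition table, whose per-gene lengths are not internally consistent
with the coordinate table in two places (rrnL, atp6).

Wobble matching asks, per amino-acid family, whether a modal codon equals
the reverse complement of the 5′→3′ anticodon of any tRNA serving that
family; the amino acid of a tRNA is inferred from its anticodon under the
genetic code rather than parsed from its name. Tied modal codons mark the
family `tied` and count as matched only if every tied codon matches.
Families with usage but no tRNA are excluded from the family count.

## Tandem repeats

The detector is a deliberately simple seed-and-extend scheme rather than a
probabilistic model: the paper-style analysis uses repeat detection as an
instrument, and a simple detector can be verified exactly against a
brute-force oracle. For each candidate period p (default 2–100 bp, the
range of mitogenome control-region units), positions with
`seq[i] == seq[i+p]` are computed; a run of ≥ p consecutive matches (one
exact copy repeated) seeds an array. The array is extended outward while
columns match a rolling consensus (majority vote per column, at most two
consecutive mismatches), trimmed back — never into the seed — until overall
identity meets the threshold (default 0.8), and finally polished by exact
pair extension at both ends. Copy number is span/period, reported to one
decimal (`copy_number × period = span` holds exactly pre-rounding).
Overlapping calls are resolved by score span × identity with ties broken
toward the shorter period, so the primitive unit of a perfect array beats
its doubled-period duplicate while a weaker internal echo of a longer unit
scores lower and is suppressed. With identity 1.0 the detector provably
reports exactly the maximal perfect arrays, which the suite checks against
a brute-force (period, phase, start) enumeration.

Copy number from amplicon length is `(total − nonrepeat)/period` with an
uncertainty of one gel-resolution unit (default ±250 bp) divided by the
period. A sample is length-heteroplasmic when two of its band lengths
differ by more than a tolerance (default 100 bp, i.e. within-gel resolution
at the 2–5 kb scale); published per-sample copy-number columns derived from
gel lengths do not follow a single linear length→copies model, so the
package reports model-based estimates with uncertainty instead of
attempting to reproduce them.

## Variant summaries

A sample carries an allele when its alternate-allele frequency is at or
above 0.1; this default is set low because surveyed indel tables count
samples with frequencies 0.089–0.11 as carriers. A variant is private to a
sample (or group) when carried there and nowhere else. Frameshift is
|len(alt) − len(ref)| mod 3 ≠ 0; the suite checks this against full
retranslation of the mutated CDS. Indels sitting in or against a
single-base run of ≥ 6 nt are flagged homopolymer-adjacent (plausible
sequencing artifacts) but never filtered. SP density is n/length at four
decimals plus the `1 every round(length/n) bp` form. Variant application
edits the CDS right-to-left (descending position) so earlier edits cannot
shift later coordinates, requires non-overlapping REF spans that match the
sequence, and re-reads the ORF from the original start to the first
in-frame stop. When per-sample frequencies are absent from a VCF they are
derived from allele depths (AD).

## Synthetic data

The generator emulates the study architecture: the default `venerid_like`
spec replays the reference layout — 13 coding genes with the reference
start/stop codons (including the one incomplete `TA-` stop), 22 tRNAs with
the reference anticodons, 2 rRNAs, 24 URs with the reference lengths, and a
54 bp × 6.5-copy tandem repeat at the 3′ end of the LUR — giving an
18,995 bp circle. Coding sequences are built codon-wise from a weight map
(uniform over the 62 sense codons by default) with no internal in-frame
stop, so the planted stop is provably the first the scanner meets. URs are
sampled with no `AT` dinucleotide, checked across junctions: all three
accepted start codons begin with AT, so a UR generated this way cannot
contain, or straddle into, a spurious start codon, making
first-start-codon recovery of every planted gene exact rather than merely
likely (a constraint on the 5′ end alone would not suffice for a 2 kb UR).
One integer seed drives a single pseudorandom stream per artifact; equal
seeds give byte-identical FASTA/VCF output.

What the generator does *not* emulate: sequencing reads and their error
models, real UR base composition (the AT-ban skews it), tRNA/rRNA secondary
structure, selection on codon usage along a gene, and linkage between
variants. Passing recovery tests therefore demonstrates the correctness of
the algorithms under the stated conventions, not robustness to real-data
noise such as misassembly or ambiguous boundaries.

Variant planting assigns each variant either one designated carrier
(private) or 2+ random carriers; carrier frequencies are uniform in
[0.6, 1.0]. Poly-A contigs are windows of 1–8 consecutive genes chosen to
end on a non-A base so the appended run is exactly the contig's trailing
A-run; the poly-A thresholds (≥ 10 As present, 1–9 ambiguous, 0 absent)
follow the observation that a 56 A tail is an unambiguous polyadenylation
signal while 8 As are not.

## Problem sizes used in the checks

The oracle-equivalence checks run the ORF scanner against exhaustive
enumeration on 1,000 random sequences of up to 300 nt, the repeat detector
against the brute-force perfect-array oracle on 150 sequences of up to
200 nt over three alphabets, planted-repeat recovery over periods 10–80 at
2–50 copies, the frameshift rule against retranslation on 1,000 random
CDS/indel pairs, and the full pipeline against generator truth on 20 seeded
venerid-like genomes. These sizes make the whole suite run in seconds while
the sequence-level oracles are still exhaustive within each case.

## Known limitations

- The reference mitogenome sequence itself is not distributed; analyses
  needing real sequence (per-gene composition of the actual genome, the
  published variant counts from RNA-Seq reads) run only on synthetic
  genomes or on the packaged printed tables.
- tRNA and rRNA genes are inputs, not predictions; no secondary-structure
  or free-energy computation is attempted.
- The repeat detector prefers primitive periods and a single best call per
  region; deeply nested repeat structures (repeats within repeat units) are
  reported at one level only.
- The scanner assumes the first available start codon opens the gene; genes
  whose real start is an interior codon (e.g. leaky scanning) would be
  called long.
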