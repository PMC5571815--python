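"""Tandem-repeat detection, copy-number estimation and length heteroplasmy.

The control-region neighbourhood of bivalve mitogenomes commonly carries a
tandem repeat whose copy number varies among individuals (CNV), producing
large length polymorphism of the largest unassigned region and sometimes
length heteroplasmy within one animal.  The detector here is a deliberately
simple, fully testable seed-and-extend scheme: exact k-mer recurrence at a
candidate period seeds an array, which is extended while columns keep
agreeing with a rolling consensus; fractional copy numbers (e.g. 6.5 copies
of a 54 bp unit) fall out of span / period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RepeatCall:
    """A detected tandem array. ``start`` is 1-based; span covers the array."""

    start: int
    span: int
    period: int
    copy_number: float  # raw span / period; round to one decimal in reports
    consensus: str
    identity: float

    def __post_init__(self) -> None:
        if self.period < 2:
            raise ValueError("period must be >= 2")

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.span - 1

    @property
    def copy_number_1dp(self) -> float:
        return round(self.copy_number, 1)

    def to_row(self) -> dict[str, object]:
        return {
            "start": self.start,
            "end": self.end,
            "period": self.period,
            "copy_number": self.copy_number_1dp,
            "identity": round(self.identity, 3),
            "consensus": self.consensus,
        }


@dataclass
class AmpliconLengthSet:
    """Amplicon band lengths observed for one sample (gel or sequence)."""

    sample: str
    band_lengths: list[float]
    source: str = "gel"

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.band_lengths):
            raise ValueError(f"sample {self.sample!r}: non-positive band length")


# ---------------------------------------------------------------------------
# Seed-and-extend tandem repeat detection


def find_tandem_repeats(
    seq: str,
    min_period: int = 2,
    max_period: int | None = None,
    min_copies: float = 2.0,
    min_identity: float = 0.8,
) -> list[RepeatCall]:
    """Detect tandem arrays of ``min_copies`` or more approximate copies.

    For every candidate period p, positions where ``seq[i] == seq[i+p]``
    are computed; a run of at least p consecutive matches (one exact copy
    repeated) seeds a candidate array, which is extended outward while
    columns keep matching the consensus unit, then trimmed until overall
    identity reaches ``min_identity``.  Overlapping calls are resolved by
    score (span x identity) with ties broken toward the shorter, primitive
    period.  Sequences shorter than ``2 * min_period`` yield no calls.
    """
    if min_period < 2:
        raise ValueError("min_period must be >= 2")
    seq = seq.upper()
    n = len(seq)
    if max_period is None:
        max_period = min(100, n // 2)
    max_period = min(max_period, n // 2)
    if n < 2 * min_period:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    seen: set[tuple[int, int, int]] = set()
    candidates: list[RepeatCall] = []
    for p in range(min_period, max_period + 1):
        m = arr[:-p] == arr[p:]
        for rs, re in _true_runs(m):
            if re - rs < p:
                continue
            call = _refine(seq, rs, re + p, p, min_identity)
            if call is None:
                continue
            key = (call.start, call.span, call.period)
            if key in seen:
                continue
            seen.add(key)
            if call.copy_number >= min_copies and call.identity >= min_identity:
                candidates.append(call)
    return resolve_overlaps(candidates)


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of consecutive True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _consensus(seq: str, start: int, end: int, p: int) -> str:
    cols = [{} for _ in range(p)]
    for i in range(start, end):
        col = cols[(i - start) % p]
        col[seq[i]] = col.get(seq[i], 0) + 1
    unit = []
    for col in cols:
        unit.append(max("ACGTN", key=lambda b: col.get(b, 0)))
    return "".join(unit)


def _identity(seq: str, start: int, end: int, p: int, cons: str) -> float:
    matches = sum(
        1 for i in range(start, end) if seq[i] == cons[(i - start) % p]
    )
    return matches / (end - start)


def _refine(
    seq: str, start: int, end: int, p: int, min_identity: float,
    max_rounds: int = 4,
) -> RepeatCall | None:
    """Extend a seeded array against its consensus, then trim to identity.

    Trimming never eats into the original seed span, so two nearby arrays
    seeded separately cannot collapse onto the same window.
    """
    seed_start, seed_end = start, end
    for _ in range(max_rounds):
        cons = _consensus(seq, start, end, p)
        # both extensions share the phase anchor of the current start
        new_start = _extend_left(seq, start, p, cons)
        new_end = _extend_right(seq, start, end, p, cons)
        if (new_start, new_end) == (start, end):
            break
        start, end = new_start, new_end
    cons = _consensus(seq, start, end, p)
    # trim outermost mismatching columns until the span meets min_identity
    while end - start >= p:
        mism = [i for i in range(start, end) if seq[i] != cons[(i - start) % p]]
        if not mism:
            break
        boundary_clean = mism[0] != start and mism[-1] != end - 1
        if _identity(seq, start, end, p, cons) >= min_identity and boundary_clean:
            break
        left_mism = [i for i in mism if i < seed_start]
        right_mism = [i for i in mism if i >= seed_end]
        if not left_mism and not right_mism:
            break  # mismatches confined to the seed; identity filter decides
        if left_mism and (not right_mism
                          or left_mism[0] - start <= end - 1 - right_mism[-1]):
            start = left_mism[0] + 1
        else:
            end = right_mism[-1]
        cons = _consensus(seq, start, end, p)
    start, end = _perfect_polish(seq, start, end, p)
    cons = _consensus(seq, start, end, p)
    if end - start < p:
        return None
    if _identity(seq, start, end, p, cons) < min_identity:
        # fall back to the seed, a perfect array by construction
        start, end = _perfect_polish(seq, seed_start, seed_end, p)
        cons = _consensus(seq, start, end, p)
    span = end - start
    if span < p:
        return None
    return RepeatCall(
        start=start + 1,
        span=span,
        period=p,
        copy_number=span / p,
        consensus=cons,
        identity=_identity(seq, start, end, p, cons),
    )


def _perfect_polish(seq: str, start: int, end: int, p: int) -> tuple[int, int]:
    """Greedily add exact-pair columns at both ends (never lowers the span)."""
    while start - 1 >= 0 and seq[start - 1] == seq[start - 1 + p]:
        start -= 1
    while end < len(seq) and seq[end] == seq[end - p]:
        end += 1
    return start, end


def _extend_left(seq: str, anchor: int, p: int, cons: str) -> int:
    x = anchor - 1
    mism_run = 0
    new_start = anchor
    while x >= 0 and mism_run < 2:
        if seq[x] == cons[(x - anchor) % p]:
            new_start = x
            mism_run = 0
        else:
            mism_run += 1
        x -= 1
    return new_start


def _extend_right(seq: str, anchor: int, end: int, p: int, cons: str) -> int:
    x = end
    mism_run = 0
    new_end = end
    while x < len(seq) and mism_run < 2:
        if seq[x] == cons[(x - anchor) % p]:
            new_end = x + 1
            mism_run = 0
        else:
            mism_run += 1
        x += 1
    return new_end


def resolve_overlaps(calls: list[RepeatCall]) -> list[RepeatCall]:
    """Keep the best-scoring call per region.

    Score is span x identity (equivalently copy_number x period x identity);
    ties go to the shorter period, so the primitive unit of a perfect array
    wins over its doubled-period duplicate, while a weaker internal echo of
    a longer true unit scores lower and is suppressed.
    """
    # collapse identical spans first (same array seen at several periods)
    by_span: dict[tuple[int, int], RepeatCall] = {}
    for c in calls:
        key = (c.start, c.span)
        prev = by_span.get(key)
        if prev is None or (c.identity, -c.period) > (prev.identity, -prev.period):
            by_span[key] = c
    ordered = sorted(
        by_span.values(),
        key=lambda c: (-c.span * c.identity, c.period, c.start),
    )
    kept: list[RepeatCall] = []
    for c in ordered:
        if any(not (c.end < k.start or k.end < c.start) for k in kept):
            continue
        kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


# ---------------------------------------------------------------------------
# Copy number from amplicon length


@dataclass
class CopyNumberEstimate:
    estimate: float
    uncertainty: float

    @property
    def estimate_1dp(self) -> float:
        return round(self.estimate, 1)


def estimate_copy_number(
    total_length: float,
    nonrepeat_length: float,
    period: int,
    gel_resolution: float = 250.0,
) -> CopyNumberEstimate:
    """Copies implied by an amplicon length given the non-repeat remainder.

    ``(total - nonrepeat) / period``, with the uncertainty a gel-resolution
    parameter (default +/-250 bp) expressed in copies.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if total_length < nonrepeat_length:
        raise ValueError("negative repeat span: total_length < nonrepeat_length")
    return CopyNumberEstimate(
        estimate=(total_length - nonrepeat_length) / period,
        uncertainty=gel_resolution / period,
    )


# ---------------------------------------------------------------------------
# Length heteroplasmy


@dataclass
class HeteroplasmyReport:
    status: dict[str, str]  # sample -> homoplasmic | heteroplasmic
    n_heteroplasmic: int

    def to_rows(self) -> list[dict[str, str]]:
        return [{"sample": s, "status": st} for s, st in self.status.items()]


def detect_length_heteroplasmy(
    samples: list[AmpliconLengthSet],
    tolerance: float = 100.0,
) -> HeteroplasmyReport:
    """Flag samples whose amplicon bands differ by more than ``tolerance`` bp.

    A sample with two or more band lengths further apart than the tolerance
    carries mtDNA molecules of different lengths (length heteroplasmy).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    status: dict[str, str] = {}
    for s in samples:
        if not s.band_lengths:
            raise ValueError(f"sample {s.sample!r} has no band lengths")
        spread = max(s.band_lengths) - min(s.band_lengths)
        status[s.sample] = (
            "heteroplasmic" if spread > tolerance else "homoplasmic"
        )
    n_het = sum(1 for v in status.values() if v == "heteroplasmic")
    return HeteroplasmyReport(status=status, n_heteroplasmic=n_het)
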