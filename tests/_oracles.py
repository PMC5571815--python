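"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or full
retranslation, staying independent of the library's scanning/seed-and-extend
code paths.
"""

from __future__ import annotations

from Bio.Seq import Seq

START_CODONS = {"ATG", "ATA", "ATC"}
STOP_CODONS = {"TAA", "TAG"}


def brute_force_orf(
    seq: str, anchor: int, boundary: int | None = None, circular: bool = True
):
    """First-start-codon ORF by exhaustive enumeration.

    Enumerates every position after ``anchor`` (unwrapped coordinates on a
    circular sequence), takes the smallest with a start codon, then
    enumerates every in-frame position for the first stop.  Returns
    (start, stop, start_codon, stop_codon, complete) in unwrapped
    coordinates, or None.
    """
    n = len(seq)

    def base(p):  # 1-based, modular
        return seq[(p - 1) % n]

    def codon(p):
        if not circular and p + 2 > n:
            return None
        return base(p) + base(p + 1) + base(p + 2)

    hi = (boundary - 1) if boundary is not None else anchor + n
    starts = []
    for p in range(anchor + 1, hi + 1):
        c = codon(p)
        if c is None:
            break
        if boundary is not None and p + 2 >= boundary:
            break
        if c in START_CODONS:
            starts.append(p)
    if not starts:
        return None
    s = min(starts)
    stops = []
    q = s + 3
    while True:
        if boundary is not None and q + 2 > boundary - 1:
            break
        if boundary is None and q - s >= n:
            break
        c = codon(q)
        if c is None:
            break
        if c in STOP_CODONS:
            stops.append(q)
            break
        q += 3
    if stops:
        return (s, stops[0] + 2, codon(s), codon(stops[0]), True)
    # incomplete: residual before boundary
    if boundary is not None:
        residual = "".join(base(x) for x in range(q, boundary))
        if residual == "":
            return "conflict"  # gene fills the space exactly yet has no stop
        if residual == "TA":
            return (s, boundary - 1, codon(s), "TA-", False)
        if residual == "T":
            return (s, boundary - 1, codon(s), "T--", False)
        return (s, boundary - 1, codon(s), None, False)
    return (s, q - 1, codon(s), None, False)


def brute_force_perfect_arrays(
    seq: str, min_period: int, max_period: int, min_copies: float
):
    """All maximal perfect tandem arrays by scanning every (period, start).

    Returns a list of (start0, span, period) with 0-based starts, keeping
    for each distinct span window only the smallest (primitive) period.
    """
    n = len(seq)
    raw = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        s = 0
        while s < n - 2 * p + 1:
            # left-maximal check
            if s > 0 and seq[s - 1] == seq[s - 1 + p]:
                s += 1
                continue
            end = s + p
            while end < n and seq[end] == seq[end - p]:
                end += 1
            span = end - s
            if span >= 2 * p and span / p >= min_copies:
                raw.append((s, span, p))
            s += 1
    best: dict[tuple[int, int], int] = {}
    for s, span, p in raw:
        key = (s, span)
        if key not in best or p < best[key]:
            best[key] = p
    return sorted((s, span, p) for (s, span), p in best.items())


def translate_table5(seq: str) -> str:
    """Full frame-0 translation under the invertebrate mitochondrial code."""
    trimmed = seq[: 3 * (len(seq) // 3)]
    return str(Seq(trimmed).translate(table=5))


def translate_to_stop_table5(seq: str) -> str:
    trimmed = seq[: 3 * (len(seq) // 3)]
    return str(Seq(trimmed).translate(table=5, to_stop=True))
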