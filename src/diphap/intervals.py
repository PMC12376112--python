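"""Interval-set arithmetic on half-open ``[start, end)`` tuples.

The purge coverage criterion and the window-identity formula both count
bases on interval *unions*, never sums, so overlapping evidence is not
double-counted. These helpers operate on plain ``(start, end)`` integer
tuples; :func:`union_length` also accepts :class:`~diphap.types.Interval`
objects and enforces that they share one sequence.
"""
from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

from .types import Interval

Pair = Tuple[int, int]


def merge(intervals: Iterable[Pair]) -> List[Pair]:
    """Merge overlapping intervals into a sorted disjoint list.

    Abutting intervals ([0,5) and [5,10)) are coalesced; the union length
    is unaffected either way.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Pair] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union_length(intervals: Sequence) -> int:
    """Total length of the set-theoretic union of intervals.

    Accepts ``(start, end)`` tuples or :class:`Interval` objects; mixing
    Intervals from different sequences is a usage error.
    """
    pairs: List[Pair] = []
    seq_ids = set()
    for iv in intervals:
        if isinstance(iv, Interval):
            seq_ids.add(iv.seq_id)
            pairs.append((iv.start, iv.end))
        else:
            s, e = iv
            pairs.append((int(s), int(e)))
    if len(seq_ids) > 1:
        raise ValueError(
            f"union_length over multiple sequences: {sorted(seq_ids)}"
        )
    return sum(e - s for s, e in merge(pairs))


def clip(intervals: Iterable[Pair], start: int, end: int) -> List[Pair]:
    """Intersect a sorted-or-not interval list with window ``[start, end)``."""
    out = []
    for s, e in intervals:
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            out.append((s2, e2))
    return out


def complement(intervals: Iterable[Pair], length: int) -> List[Pair]:
    """Gaps of ``[0, length)`` not covered by the given intervals."""
    out: List[Pair] = []
    cur = 0
    for s, e in merge(intervals):
        if s > cur:
            out.append((cur, min(s, length)))
        cur = max(cur, e)
        if cur >= length:
            break
    if cur < length:
        out.append((cur, length))
    return out
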