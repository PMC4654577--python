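"""Half-open interval set algebra on the session time axis.

All functions operate on lists of ``(start, end)`` pairs interpreted as
half-open intervals ``[start, end)`` in seconds. Interval sets are kept
normalised: sorted by start, non-overlapping, non-empty intervals only.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[float, float]


def normalize(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping/abutting intervals; drop empty ones."""
    ivs = sorted((float(s), float(e)) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    return normalize(list(a) + list(b))


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Set difference a \\ b."""
    a = normalize(a)
    b = normalize(b)
    out: List[Interval] = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    a = normalize(a)
    b = normalize(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> float:
    return sum(e - s for s, e in normalize(intervals))


def contains(intervals: Iterable[Interval], t: float) -> bool:
    """True iff time t lies in [start, end) of some interval."""
    return any(s <= t < e for s, e in normalize(intervals))
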