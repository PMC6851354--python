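"""Half-open interval arithmetic on ``(start, end)`` pairs in seconds.

All intervals in this package are half-open ``[start, end)`` with
``start < end``; these helpers keep that convention in one place.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def validate_interval(start: float, end: float) -> None:
    if not start < end:
        raise ValueError(f"interval must satisfy start < end, got [{start}, {end})")


def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    out: list[tuple[float, float]] = []
    for s, e in ivs:
        validate_interval(s, e)
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    keep: Sequence[tuple[float, float]], remove: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Set difference keep \\ remove of half-open interval unions."""
    keep = merge_intervals(keep)
    remove = merge_intervals(remove)
    out: list[tuple[float, float]] = []
    for s, e in keep:
        cur = s
        for rs, re in remove:
            if re <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, min(rs, e)))
            cur = max(cur, re)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def overlaps(a: tuple[float, float], b: tuple[float, float], pad: float = 0.0) -> bool:
    """True when half-open intervals overlap after symmetric padding of ``a``."""
    return a[0] - pad < b[1] and b[0] < a[1] + pad


def overlap_length(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = overlap_length(a, b)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def total_length(intervals: Iterable[tuple[float, float]]) -> float:
    return sum(e - s for s, e in merge_intervals(intervals))
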