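"""Half-numeric interval arithmetic on flat lists of (start, end) pairs.

All downstream modules treat windows as closed numeric spans; only lengths
and membership matter, so degenerate (zero-length) intervals are tolerated
but contribute nothing.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

Interval = tuple[float, float]


def validate_windows(windows: Sequence[Interval]) -> list[Interval]:
    """Sort windows and check they are well-formed and pairwise disjoint."""
    ws = sorted((float(a), float(b)) for a, b in windows)
    for a, b in ws:
        if b < a:
            raise ValueError(f"window ({a}, {b}) has end before start")
    for (a0, b0), (a1, b1) in zip(ws, ws[1:]):
        if a1 < b0:
            raise ValueError(f"windows ({a0},{b0}) and ({a1},{b1}) overlap")
    return ws


def total_length(windows: Iterable[Interval]) -> float:
    return float(sum(b - a for a, b in windows))


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of possibly-overlapping intervals as a sorted disjoint list."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            prev_a, prev_b = out[-1]
            out[-1] = (prev_a, max(prev_b, b))
        else:
            out.append((a, b))
    return out


def intersect(xs: Iterable[Interval], ys: Iterable[Interval]) -> list[Interval]:
    """Intersection of two disjoint-sorted interval lists."""
    xs, ys = list(xs), list(ys)
    out: list[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if b > a:
            out.append((a, b))
        if xs[i][1] <= ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def clip_point_mask(times: np.ndarray, windows: Sequence[Interval]) -> np.ndarray:
    """Boolean mask of times lying inside any window (closed endpoints)."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for a, b in windows:
        mask |= (times >= a) & (times <= b)
    return mask


def overlap_length(start: float, end: float, windows: Sequence[Interval]) -> float:
    """Length of [start, end] covered by the (disjoint) windows."""
    s = 0.0
    for a, b in windows:
        s += max(0.0, min(end, b) - max(start, a))
    return s


def complement(windows: Sequence[Interval], lo: float, hi: float) -> list[Interval]:
    """[lo, hi] minus the (disjoint, sorted) windows."""
    out: list[Interval] = []
    cursor = lo
    for a, b in sorted(windows):
        if a > cursor:
            out.append((cursor, min(a, hi)))
        cursor = max(cursor, b)
    if cursor < hi:
        out.append((cursor, hi))
    return [(a, b) for a, b in out if b > a]
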