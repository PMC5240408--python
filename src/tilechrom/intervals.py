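"""Small primitives for 0-based half-open genomic intervals.

These back the cher merging/intersection conventions and the window-grid
overlap arithmetic; they intentionally operate on plain ``(start, end)``
pairs or numpy arrays, one chromosome at a time.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


def _sorted(intervals: Iterable[Interval]) -> List[Interval]:
    out = [(int(s), int(e)) for s, e in intervals]
    for s, e in out:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
    return sorted(out)


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals; overlapping or touching intervals are coalesced."""
    ivs = _sorted(intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Pairwise intersection of two interval sets (each merged first)."""
    xs, ys = merge(a), merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        s = max(xs[i][0], ys[j][0])
        e = min(xs[i][1], ys[j][1])
        if e > s:
            out.append((s, e))
        if xs[i][1] <= ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlaps_any(query: Interval, targets: Sequence[Interval]) -> bool:
    """Whether ``query`` overlaps (>=1 bp) any target interval."""
    if not targets:
        return False
    merged = merge(targets)
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    qs, qe = query
    i = int(np.searchsorted(ends, qs, side="right"))
    return i < len(starts) and starts[i] < qe


def overlap_flags(queries: Sequence[Interval], targets: Sequence[Interval]) -> np.ndarray:
    """Boolean flag per query: overlaps any target by >=1 bp."""
    if not queries:
        return np.zeros(0, dtype=bool)
    if not targets:
        return np.zeros(len(queries), dtype=bool)
    merged = merge(targets)
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    qs = np.array([s for s, _ in queries])
    qe = np.array([e for _, e in queries])
    idx = np.searchsorted(ends, qs, side="right")
    ok = idx < len(starts)
    flags = np.zeros(len(queries), dtype=bool)
    flags[ok] = starts[idx[ok]] < qe[ok]
    return flags


def window_mask(intervals: Iterable[Interval], n_windows: int, window_bp: int) -> np.ndarray:
    """Boolean mask over fixed windows: window w is set iff
    ``[w*window_bp, (w+1)*window_bp)`` overlaps any interval by >=1 bp.

    Windows beyond ``n_windows`` (partial trailing windows) are dropped.
    """
    mask = np.zeros(n_windows, dtype=bool)
    for s, e in intervals:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        w0 = max(0, s // window_bp)
        w1 = min(n_windows - 1, (e - 1) // window_bp)
        if w1 >= w0:
            mask[w0 : w1 + 1] = True
    return mask
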