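"""Small numpy interval toolkit (0-based half-open) used across modules."""

from __future__ import annotations

import numpy as np


def merge(intervals) -> np.ndarray:
    """Merge overlapping or touching intervals; returns sorted (n, 2) array."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


def total_length(merged: np.ndarray) -> int:
    if merged.shape[0] == 0:
        return 0
    return int(np.sum(merged[:, 1] - merged[:, 0]))


def intersect_length(merged_a: np.ndarray, merged_b: np.ndarray) -> int:
    """Total bp shared between two merged interval sets."""
    i = j = 0
    total = 0
    while i < merged_a.shape[0] and j < merged_b.shape[0]:
        lo = max(merged_a[i, 0], merged_b[j, 0])
        hi = min(merged_a[i, 1], merged_b[j, 1])
        if hi > lo:
            total += hi - lo
        if merged_a[i, 1] < merged_b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def extend_to(intervals: np.ndarray, merged_hits: np.ndarray) -> np.ndarray:
    """Extend each interval to cover any merged hit it intersects.

    Applied to fixed point, then merged; with hits pre-merged a single pass
    per interval converges, but the loop re-checks until stable anyway.
    """
    if merged_hits.shape[0] == 0:
        return merge(intervals)
    starts = merged_hits[:, 0]
    ends = merged_hits[:, 1]
    cur = np.asarray(intervals, dtype=np.int64).reshape(-1, 2).copy()
    while True:
        changed = False
        for row in cur:
            s, e = row
            lo = int(np.searchsorted(ends, s, side="right"))
            hi = int(np.searchsorted(starts, e, side="left"))
            if hi > lo:
                ns, ne = min(s, int(starts[lo])), max(e, int(ends[hi - 1]))
                if (ns, ne) != (s, e):
                    row[0], row[1] = ns, ne
                    changed = True
        if not changed:
            return merge(cur)
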