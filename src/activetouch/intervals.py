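"""Half-open millisecond intervals and set operations on them.

All epochs in this package are unions of half-open intervals ``[start, end)``
on the 1 ms grid, represented as ``(n, 2)`` float arrays sorted by start.
Events at a boundary belong to the later interval.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "total_duration",
    "union",
    "intersect",
    "subtract",
    "contains",
    "sample_uniform",
]


def as_intervals(iv) -> np.ndarray:
    """Coerce to a (n, 2) float array; empty input gives shape (0, 2)."""
    arr = np.asarray(iv, dtype=float)
    if arr.size == 0:
        return np.empty((0, 2), dtype=float)
    arr = arr.reshape(-1, 2)
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("interval end precedes start")
    return arr


def total_duration(iv) -> float:
    iv = as_intervals(iv)
    return float(np.sum(iv[:, 1] - iv[:, 0]))


def union(*interval_sets) -> np.ndarray:
    """Union of interval sets, merging overlapping/abutting intervals."""
    parts = [as_intervals(s) for s in interval_sets]
    allv = np.vstack(parts) if parts else np.empty((0, 2))
    if len(allv) == 0:
        return np.empty((0, 2), dtype=float)
    allv = allv[np.argsort(allv[:, 0], kind="stable")]
    merged = [list(allv[0])]
    for s, e in allv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=float)


def intersect(a, b) -> np.ndarray:
    """Intersection of two interval sets (each need not be disjoint)."""
    a, b = union(a), union(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return as_intervals(out)


def subtract(a, b) -> np.ndarray:
    """Set difference a \\ b."""
    a, b = union(a), union(b)
    out = []
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
    return as_intervals(out)


def contains(iv, times) -> np.ndarray:
    """Boolean mask: which times fall inside the interval union."""
    iv = union(iv)
    times = np.asarray(times, dtype=float)
    if len(iv) == 0:
        return np.zeros(times.shape, dtype=bool)
    idx = np.searchsorted(iv[:, 0], times, side="right") - 1
    inside = idx >= 0
    inside[inside] &= times[inside] < iv[idx[inside], 1]
    return inside


def sample_uniform(iv, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n times uniformly from the interval union (sorted output).

    Used by the shuffle null of the attribution analysis: redistributes
    spike times uniformly over an epoch set, preserving the count.
    """
    iv = union(iv)
    if len(iv) == 0:
        raise ValueError("cannot sample from an empty interval set")
    lengths = iv[:, 1] - iv[:, 0]
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    u = rng.random(n) * edges[-1]
    k = np.searchsorted(edges, u, side="right") - 1
    k = np.clip(k, 0, len(iv) - 1)
    return np.sort(iv[k, 0] + (u - edges[k]))
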