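"""Half-open interval arithmetic on numpy arrays.

All coordinates in the package are 0-based, half-open (BED convention).
Functions here operate on (n, 2) integer arrays for a single chromosome;
callers group by chromosome.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "union_length",
    "intersect",
    "intersect_length",
    "complement",
    "clip",
    "reciprocal_clusters",
]


def _as_array(iv) -> np.ndarray:
    a = np.asarray(iv, dtype=np.int64)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("expected an (n, 2) interval array")
    if np.any(a[:, 0] > a[:, 1]):
        raise ValueError("interval start > end")
    return a


def merge(iv) -> np.ndarray:
    """Sort and merge overlapping or adjacent-touching intervals."""
    a = _as_array(iv)
    if len(a) == 0:
        return a
    a = a[np.lexsort((a[:, 1], a[:, 0]))]
    out = [list(a[0])]
    for s, e in a[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def union_length(iv) -> int:
    m = merge(iv)
    return int((m[:, 1] - m[:, 0]).sum()) if len(m) else 0


def intersect(a, b) -> np.ndarray:
    """Intervals of the intersection of two interval sets."""
    ma, mb = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i, 0], mb[j, 0])
        e = min(ma[i, 1], mb[j, 1])
        if s < e:
            out.append((s, e))
        if ma[i, 1] < mb[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intersect_length(a, b) -> int:
    x = intersect(a, b)
    return int((x[:, 1] - x[:, 0]).sum()) if len(x) else 0


def complement(iv, length: int) -> np.ndarray:
    """Gaps of an interval set within [0, length)."""
    m = clip(merge(iv), length)
    out = []
    prev = 0
    for s, e in m:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def clip(iv, length: int) -> np.ndarray:
    a = _as_array(iv)
    if len(a) == 0:
        return a
    a = np.clip(a, 0, length)
    return a[a[:, 1] > a[:, 0]]


def reciprocal_clusters(iv, frac: float = 0.5) -> np.ndarray:
    """Single-linkage clusters of intervals overlapping >= ``frac`` of *each*.

    Returns an int label per input interval. Intervals on one chromosome only.
    """
    a = _as_array(iv)
    n = len(a)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = np.argsort(a[:, 0], kind="stable")
    for ii in range(n):
        i = order[ii]
        for jj in range(ii + 1, n):
            j = order[jj]
            if a[j, 0] >= a[i, 1]:
                break
            ov = min(a[i, 1], a[j, 1]) - max(a[i, 0], a[j, 0])
            li = a[i, 1] - a[i, 0]
            lj = a[j, 1] - a[j, 0]
            if li > 0 and lj > 0 and ov >= frac * li and ov >= frac * lj:
                parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels
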