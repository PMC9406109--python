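"""Independent brute-force oracles used to cross-check the scoring layer.

These deliberately avoid the library routines they validate: junction
detection is an O(n^2) scan over every local maximum and its shoulders,
clustering is pairwise union-find, and interval counting is an explicit
position scan.
"""

from __future__ import annotations

import numpy as np


def brute_force_junctions(depth: np.ndarray, min_depth: float) -> list[tuple[int, float]]:
    """All valley peaks (index, prominence) with prominence >= min_depth.

    A peak is a sample strictly greater than its neighbours; plateaus count
    once, at their middle sample. Prominence of a peak of height h: walk out
    on each side until a strictly higher sample (or the boundary); the side's
    base is the minimum over that walk; prominence = h - max(left base,
    right base).
    """
    d = np.asarray(depth, dtype=float)
    n = d.size
    peaks = []
    i = 1
    while i < n - 1:
        if d[i - 1] < d[i]:
            j = i
            while j < n - 1 and d[j + 1] == d[i]:
                j += 1
            if j < n - 1 and d[j + 1] < d[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    out = []
    for m in peaks:
        h = d[m]
        left_min = h
        k = m - 1
        while k >= 0 and d[k] <= h:
            left_min = min(left_min, d[k])
            k -= 1
        right_min = h
        k = m + 1
        while k <= n - 1 and d[k] <= h:
            right_min = min(right_min, d[k])
            k += 1
        prom = h - max(left_min, right_min)
        if prom >= min_depth:
            out.append((m, float(prom)))
    return out


def brute_force_single_linkage(points: np.ndarray, cutoff: float) -> list[frozenset]:
    """Connected components of the pairwise <=cutoff graph via union-find."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def brute_force_interval_counts(
    ganglion_x: np.ndarray, junction_x: np.ndarray
) -> list[int]:
    """Junctions strictly between each pair of adjacent ganglion positions."""
    gx = np.sort(np.asarray(ganglion_x, dtype=float))
    out = []
    for a, b in zip(gx, gx[1:]):
        out.append(int(sum(1 for x in junction_x if a < x < b)))
    return out
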