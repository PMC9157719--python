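"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit Python loops, full
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def _inb(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


def naive_glcm_counts(lv, mask, G):
    """Symmetric pooled co-occurrence counts over all 26 neighbor offsets."""
    counts = np.zeros((G, G), dtype=np.int64)
    shape = lv.shape
    for p in itertools.product(*map(range, shape)):
        if not mask[p]:
            continue
        for d in ALL_26:
            q = tuple(p[a] + d[a] for a in range(3))
            if _inb(q, shape) and mask[q]:
                counts[lv[p] - 1, lv[q] - 1] += 1
    return counts


def naive_glrlm_counts(lv, mask, G, directions=HALF_13):
    """Run-length counts by walking every line start in every direction."""
    shape = lv.shape
    runs = []
    for d in directions:
        for p in itertools.product(*map(range, shape)):
            if not mask[p]:
                continue
            prev = tuple(p[a] - d[a] for a in range(3))
            if _inb(prev, shape) and mask[prev] and lv[prev] == lv[p]:
                continue  # not a run start
            length = 1
            q = tuple(p[a] + d[a] for a in range(3))
            while _inb(q, shape) and mask[q] and lv[q] == lv[p]:
                length += 1
                q = tuple(q[a] + d[a] for a in range(3))
            runs.append((lv[p], length))
    L = max(l for _, l in runs)
    R = np.zeros((G, L), dtype=np.int64)
    for g, l in runs:
        R[g - 1, l - 1] += 1
    return R


def naive_glzlm_counts(lv, mask, G):
    """Zone counts by explicit flood fill (26-connectivity, equal level)."""
    shape = lv.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in itertools.product(*map(range, shape)):
        if not mask[p] or seen[p]:
            continue
        level = lv[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in ALL_26:
                q = tuple(cur[a] + d[a] for a in range(3))
                if _inb(q, shape) and mask[q] and not seen[q] and lv[q] == level:
                    seen[q] = True
                    stack.append(q)
        zones.append((level, size))
    S = max(s for _, s in zones)
    Z = np.zeros((G, S), dtype=np.int64)
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def naive_ngldm_table(lv, mask, G):
    """Per-level (count, accumulated |level - neighborhood mean|)."""
    shape = lv.shape
    n_i = np.zeros(G)
    s_i = np.zeros(G)
    for p in itertools.product(*map(range, shape)):
        if not mask[p]:
            continue
        nbrs = [
            lv[tuple(p[a] + d[a] for a in range(3))]
            for d in ALL_26
            if _inb(tuple(p[a] + d[a] for a in range(3)), shape)
            and mask[tuple(p[a] + d[a] for a in range(3))]
        ]
        if not nbrs:
            continue
        n_i[lv[p] - 1] += 1
        s_i[lv[p] - 1] += abs(lv[p] - sum(nbrs) / len(nbrs))
    return n_i, s_i


def wilcoxon_exact_enum(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Requires tie-free nonzero differences.  p = 2 * min(P(W <= w),
    P(W >= w)) under the null, capped at 1, with W the positive-rank sum.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_lo = np.mean(ws <= w_obs)
    p_hi = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def bh_stepup(p):
    """Benjamini-Hochberg adjusted values by the step-up formula."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


def sphere_mask_offsets(voxel_mm, radius_mm):
    """Brute-force list of voxel offsets inside a sphere of given radius."""
    h = int(math.floor(radius_mm / min(voxel_mm))) + 1
    offs = []
    for d in itertools.product(range(-h, h + 1), repeat=3):
        if sum((d[a] * voxel_mm[a]) ** 2 for a in range(3)) <= radius_mm**2 + 1e-9:
            offs.append(d)
    return offs
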