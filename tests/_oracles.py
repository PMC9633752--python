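"""Independent brute-force oracles for the texture-matrix builders.

Deliberately naive: explicit Python loops over voxels, neighbors, runs and
flood fills.  They share no code with the package's vectorized builders.
"""

from collections import deque
from itertools import product

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx, dy, dz in product((-1, 0, 1), repeat=3)
    if (dx, dy, dz) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def glcm_counts_bruteforce(levels, mask, ng, distance=1):
    """Ordered co-occurrence counts over all 26 offsets (== symmetric 13)."""
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for p in np.argwhere(mask):
        for d in ALL_26:
            q = tuple(p[i] + distance * d[i] for i in range(3))
            if _in_bounds(q, shape) and mask[q]:
                counts[levels[tuple(p)] - 1, levels[q] - 1] += 1
    return counts


def glszm_zones_bruteforce(levels, mask, ng):
    """(level, size) of every maximal 26-connected equal-level zone (BFS)."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if visited[start]:
            continue
        level = levels[start]
        size = 0
        queue = deque([start])
        visited[start] = True
        while queue:
            v = queue.popleft()
            size += 1
            for d in ALL_26:
                w = tuple(v[i] + d[i] for i in range(3))
                if (
                    _in_bounds(w, shape)
                    and mask[w]
                    and not visited[w]
                    and levels[w] == level
                ):
                    visited[w] = True
                    queue.append(w)
        zones.append((int(level), size))
    return zones


def zones_to_matrix(zones, ng):
    smax = max((s for _, s in zones), default=1)
    counts = np.zeros((ng, smax))
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return counts


def glrlm_counts_bruteforce(levels, mask, ng):
    """Merged run-length counts over the 13 directions (linear scans)."""
    shape = levels.shape
    runs = []
    for d in HALF_13:
        for p in np.argwhere(mask):
            p = tuple(p)
            prev = tuple(p[i] - d[i] for i in range(3))
            if (
                _in_bounds(prev, shape)
                and mask[prev]
                and levels[prev] == levels[p]
            ):
                continue  # not a run start
            length = 1
            cur = p
            while True:
                nxt = tuple(cur[i] + d[i] for i in range(3))
                if (
                    _in_bounds(nxt, shape)
                    and mask[nxt]
                    and levels[nxt] == levels[p]
                ):
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((int(levels[p]), length))
    rmax = max((r for _, r in runs), default=1)
    counts = np.zeros((ng, rmax))
    for level, length in runs:
        counts[level - 1, length - 1] += 1
    return counts


def ngtdm_bruteforce(levels, mask, ng):
    """Per-voxel neighborhood means; returns (s, n) arrays of length ng."""
    shape = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=int)
    for p in np.argwhere(mask):
        p = tuple(p)
        nbr = []
        for d in ALL_26:
            q = tuple(p[i] + d[i] for i in range(3))
            if _in_bounds(q, shape) and mask[q]:
                nbr.append(levels[q])
        if not nbr:
            continue
        lev = levels[p]
        s[lev - 1] += abs(lev - sum(nbr) / len(nbr))
        n[lev - 1] += 1
    return s, n


def auc_pairs_bruteforce(scores, labels):
    """AUC as the fraction of (pos, neg) pairs correctly ordered (ties 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))
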