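"""Brute-force reference implementations, independent of the production code.

Everything here is written as plain loops directly from the defining
formulas, so the tests compare two independently derived routes.
"""
from __future__ import annotations

import itertools

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _inside(shape, p):
    return all(0 <= p[a] < shape[a] for a in range(3))


def brute_glcm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Average of per-direction symmetrized, normalized co-occurrence matrices."""
    shape = levels.shape
    mats = []
    for d in DIRS_13:
        m = np.zeros((n_bins, n_bins))
        for p in np.ndindex(shape):
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if not _inside(shape, q):
                continue
            a, b = levels[p], levels[q]
            if a > 0 and b > 0:
                m[a - 1, b - 1] += 1
                m[b - 1, a - 1] += 1
        if m.sum() > 0:
            mats.append(m / m.sum())
    return np.mean(mats, axis=0)


def brute_glrlm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Run-length counts summed over the 13 directions (runs = masked voxels)."""
    shape = levels.shape
    max_run = max(shape)
    R = np.zeros((n_bins, max_run))
    for d in DIRS_13:
        for p in np.ndindex(shape):
            g = levels[p]
            if g == 0:
                continue
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if _inside(shape, prev) and levels[prev] == g:
                continue  # not a run start
            length = 0
            q = p
            while _inside(shape, q) and levels[q] == g:
                length += 1
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            R[g - 1, length - 1] += 1
    return R


def brute_glszm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Zone-size counts from 26-connected flood fill."""
    shape = levels.shape
    n_voxels = int((levels > 0).sum())
    Z = np.zeros((n_bins, max(n_voxels, 1)))
    seen = np.zeros(shape, dtype=bool)
    neighbors = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for p in np.ndindex(shape):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for d in neighbors:
                r = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                if _inside(shape, r) and not seen[r] and levels[r] == g:
                    seen[r] = True
                    stack.append(r)
        Z[g - 1, size - 1] += 1
    return Z


def brute_ngtdm(levels: np.ndarray, n_bins: int):
    """Per-level (n_i, s_i) with 26-neighborhood means over masked neighbors."""
    shape = levels.shape
    n = np.zeros(n_bins)
    s = np.zeros(n_bins)
    neighbors = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for p in np.ndindex(shape):
        g = levels[p]
        if g == 0:
            continue
        vals = []
        for d in neighbors:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _inside(shape, q) and levels[q] > 0:
                vals.append(levels[q])
        if not vals:
            continue
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(vals) / len(vals))
    return n, s


def exhaustive_l0_objective(F: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Global minimum of ||y - Fw||^2 + gamma ||w||_0 by support enumeration."""
    p = F.shape[1]
    best = float(y @ y)
    for k in range(1, p + 1):
        for S in itertools.combinations(range(p), k):
            cols = F[:, list(S)]
            coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
            r = y - cols @ coef
            obj = float(r @ r) + gamma * k
            if obj < best:
                best = obj
    return best


def haar_lll_oracle(volume: np.ndarray) -> np.ndarray:
    """Single-level Haar approximation band: 2x2x2 block means x 2^(3/2)."""
    a, b, c = (s // 2 for s in volume.shape)
    out = np.zeros((a, b, c))
    for i in range(a):
        for j in range(b):
            for k in range(c):
                block = volume[2 * i:2 * i + 2, 2 * j:2 * j + 2, 2 * k:2 * k + 2]
                out[i, j, k] = block.mean() * (2 ** 1.5)
    return out


def auc_pair_count(labels: np.ndarray, scores: np.ndarray, positive) -> float:
    """AUC as the normalized count of concordant pairs, ties as 1/2."""
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
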