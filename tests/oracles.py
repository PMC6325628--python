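"""Brute-force reference implementations used to cross-check the fast paths.

Everything here is deliberately naive (explicit loops, BFS, direct kernel
sums) and independent of the package's implementation choices.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

import numpy as np


def brute_gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Direct construction of the truncated, normalised 2D Gaussian kernel."""
    c = (size - 1) / 2.0
    k = np.empty((size, size))
    for i in range(size):
        for j in range(size):
            k[i, j] = np.exp(-((i - c) ** 2 + (j - c) ** 2) / (2 * sigma**2))
    return k / k.sum()


def brute_max_project(vol: np.ndarray) -> np.ndarray:
    nz, ny, nx = vol.shape
    out = np.full((ny, nx), -np.inf)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                out[y, x] = max(out[y, x], vol[z, y, x])
    return out


def _neighbors(idx, shape, connectivity):
    """Neighbour offsets: 'full' = all 3^d - 1, 'minimal' = faces only."""
    d = len(shape)
    offs = []
    for delta in np.ndindex(*(3,) * d):
        delta = tuple(v - 1 for v in delta)
        if all(v == 0 for v in delta):
            continue
        if connectivity == "minimal" and sum(abs(v) for v in delta) != 1:
            continue
        offs.append(delta)
    for off in offs:
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= v < s for v, s in zip(nb, shape)):
            yield nb


def bfs_label(mask: np.ndarray, connectivity: str = "full") -> tuple[np.ndarray, int]:
    """Flood-fill connected-component labelling."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if labels[idx]:
            continue
        n += 1
        queue = deque([idx])
        labels[idx] = n
        while queue:
            cur = queue.popleft()
            for nb in _neighbors(cur, mask.shape, connectivity):
                if mask[nb] and not labels[nb]:
                    labels[nb] = n
                    queue.append(nb)
    return labels, n


def brute_filter_size(mask, min_px, max_px, connectivity="full"):
    labels, n = bfs_label(mask, connectivity)
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for i in range(1, n + 1):
        comp = labels == i
        if min_px <= comp.sum() <= max_px:
            out |= comp
    return out


def brute_erode6(mask: np.ndarray) -> np.ndarray:
    """6-connected erosion, out-of-volume neighbours = background."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        ok = True
        for nb in _neighbors(idx, mask.shape, "minimal"):
            if not mask[nb]:
                ok = False
                break
        # any face neighbour outside the volume also fails the erosion
        if ok:
            for i, (v, s) in enumerate(zip(idx, mask.shape)):
                if v == 0 or v == s - 1:
                    ok = False
                    break
        if ok:
            out[idx] = True
    return out


def brute_reconstruct(seed, limit, connectivity="full"):
    seed = np.asarray(seed, dtype=bool)
    limit = np.asarray(limit, dtype=bool)
    labels, n = bfs_label(limit, connectivity)
    out = np.zeros_like(limit)
    for i in range(1, n + 1):
        comp = labels == i
        if (comp & seed).any():
            out |= comp
    return out


def brute_ncc_offset(ref_strip, mov_strip_fn, window):
    """Exhaustive NCC argmax over integer shifts (used for stitching checks)."""
    best, best_shift = -np.inf, (0, 0)
    for dy in range(-window, window + 1):
        for dx in range(-window, window + 1):
            pair = mov_strip_fn(dy, dx)
            if pair is None:
                continue
            a, b = pair
            a = a.ravel() - a.mean()
            b = b.ravel() - b.mean()
            den = np.sqrt((a @ a) * (b @ b))
            if den == 0:
                continue
            r = (a @ b) / den
            if r > best:
                best, best_shift = r, (dy, dx)
    return best_shift


def exact_mannwhitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties, n small)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == nx + ny, "enumeration oracle assumes no ties"
    u_obs = sum((xi > yj) for xi in x for yj in y)
    ranks = np.argsort(np.argsort(pooled)) + 1
    count = 0
    total = comb(nx + ny, nx)
    idx_all = set(range(nx + ny))
    for xs in combinations(range(nx + ny), nx):
        rx = sum(ranks[list(xs)])
        u = rx - nx * (nx + 1) / 2
        if min(u, nx * ny - u) <= min(u_obs, nx * ny - u_obs):
            count += 1
    return count / total
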