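"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the NLM oracle is a plain
quadruple loop over pixels and search offsets, the DBSCAN oracle closes
density-reachability by boolean matrix powers, and the Hausdorff oracle is
the all-pairs max-min.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def naive_nlm(img: np.ndarray, patch_radius: int, search_radius: int, h: float) -> np.ndarray:
    """Windowed Nonlocal Means by direct quadruple-loop evaluation, with
    mirror-padded patch extraction and per-pixel weight normalization."""
    m, n = img.shape
    pr, sr = patch_radius, search_radius
    pad = sr + pr
    p = np.pad(np.asarray(img, dtype=np.float64), pad, mode="reflect")
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            ci, cj = pad + i, pad + j
            patch_i = p[ci - pr:ci + pr + 1, cj - pr:cj + pr + 1]
            acc = 0.0
            wsum = 0.0
            for di in range(-sr, sr + 1):
                for dj in range(-sr, sr + 1):
                    ni, nj = ci + di, cj + dj
                    patch_j = p[ni - pr:ni + pr + 1, nj - pr:nj + pr + 1]
                    w = np.exp(-np.sum((patch_i - patch_j) ** 2) / h**2)
                    acc += w * p[ni, nj]
                    wsum += w
            out[i, j] = acc / wsum
    return out


def naive_nlm_full(img: np.ndarray, patch_radius: int, h: float) -> np.ndarray:
    """Full-image Nonlocal Means: the literal sum over every pixel j."""
    m, n = img.shape
    pr = patch_radius
    p = np.pad(np.asarray(img, dtype=np.float64), pr, mode="reflect")
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            patch_i = p[i:i + 2 * pr + 1, j:j + 2 * pr + 1]
            acc = 0.0
            wsum = 0.0
            for i2 in range(m):
                for j2 in range(n):
                    patch_j = p[i2:i2 + 2 * pr + 1, j2:j2 + 2 * pr + 1]
                    w = np.exp(-np.sum((patch_i - patch_j) ** 2) / h**2)
                    acc += w * img[i2, j2]
                    wsum += w
            out[i, j] = acc / wsum
    return out


def brute_dbscan(features: np.ndarray, delta: float, min_neighbors: int):
    """Density-connectivity closure by O(n^3) boolean matrix powers.

    Returns ``(core_partition, core, noise)`` where ``core_partition`` is a
    frozenset of frozensets of core indices (one per cluster), ``core`` the
    boolean core indicator, and ``noise`` the set of noise indices.
    """
    f = np.asarray(features, dtype=np.float64)
    n = f.shape[0]
    within = cdist(f, f) <= delta
    core = within.sum(axis=1) >= min_neighbors
    reach = within & core[:, None] & core[None, :]
    np.fill_diagonal(reach, core)
    closure = reach.copy()
    for _ in range(n):
        nxt = closure | (closure @ reach)
        if (nxt == closure).all():
            break
        closure = nxt
    clusters = []
    seen = set()
    for i in range(n):
        if core[i] and i not in seen:
            members = frozenset(np.flatnonzero(closure[i] | closure[:, i]) .tolist()) | {i}
            members = frozenset(m for m in members if core[m])
            seen |= members
            clusters.append(members)
    border = set()
    for i in range(n):
        if not core[i] and (within[i] & core).any():
            border.add(i)
    noise = set(range(n)) - seen - border
    return frozenset(clusters), core, noise


def brute_hausdorff(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Hausdorff distance by all-pairs max-min."""
    px = np.argwhere(np.asarray(x, dtype=bool)).astype(float)
    py = np.argwhere(np.asarray(y, dtype=bool)).astype(float)
    d = cdist(px, py)
    return max(d.min(axis=1).max(), d.min(axis=0).max())
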