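"""Grid-seeded local intuitionistic fuzzy c-means (IFCM) superpixels.

The image, transformed to (mu, nu, pi) triples, is over-segmented into K
edge-adherent superpixels by minimizing the fuzzy c-means functional in the
intuitionistic fuzzy domain,

    J = sum_l sum_k  u_lk^gamma * d(x_l, v_k),

where d is the squared Euclidean IFS distance, u_lk the membership of pixel l
in superpixel k (rows of U sum to 1), v_k the superpixel prototype, and
gamma >= 2 the fuzzifier.  Clustering is *local* in the SLIC sense: seeds are
placed on a regular grid with step S = round(sqrt(M*N/K)), and each pixel
competes only among the centroids whose seed lies within a 2S x 2S window
around it.  Alternating the exact minimizers,

    u_lk = 1 / sum_r (d_lk / d_lr)^(1/(gamma-1))
    v_k  = sum_l u_lk^gamma x_l / sum_l u_lk^gamma,

makes J non-increasing across iterations.  Hard labels are the per-pixel
membership argmax; a connectivity pass then absorbs fragments smaller than
S^2/4 pixels into the adjacent superpixel with the most similar prototype so
every label forms a single connected region.

The distance carries no spatial term: locality comes solely from the
candidate windows, so superpixel boundaries lock onto intensity edges rather
than compromising between color and position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .errors import ContractError, ParameterError
from .ifs import IFSImage

__all__ = [
    "SuperpixelParams",
    "SuperpixelMap",
    "init_grid",
    "update_memberships",
    "update_centroids",
    "clustering_objective",
    "run_local_clustering",
]

logger = logging.getLogger(__name__)

#: squared IFS distances at or below this are treated as coincident (the
#: zero-distance membership guard); converged prototypes of perfectly flat
#: regions land within float rounding of their members, far below this.
ZERO_TOL = 1e-15


@dataclass(frozen=True)
class SuperpixelParams:
    """IFCM superpixel parameters.

    n_superpixels
        Target superpixel count K (1000 works well for ~256-512 px scans);
        the effective count after grid seeding and connectivity enforcement
        may differ slightly.
    gamma
        Fuzzifier (>= 2): larger values give softer memberships.
    max_iter, tol
        Alternating updates stop after ``max_iter`` sweeps or when no
        prototype triple component moves more than ``tol``.
    """

    n_superpixels: int = 1000
    gamma: float = 2.0
    max_iter: int = 10
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_superpixels < 1:
            raise ParameterError("n_superpixels must be >= 1")
        if self.gamma < 2.0:
            raise ParameterError("gamma must be >= 2")
        if self.max_iter < 0:
            raise ParameterError("max_iter must be >= 0")
        if not self.tol > 0:
            raise ParameterError("tol must be > 0")


@dataclass
class SuperpixelMap:
    """Hard superpixel partition plus per-superpixel centroid records.

    ``labels`` maps each pixel to a compact id in ``[0, n_superpixels)``;
    every id names one connected region and the sizes sum to the pixel count.
    Centroid arrays are indexed by id: ``ifs`` holds the mean (mu, nu, pi)
    triple, ``rows``/``cols`` the mean pixel coordinates, ``sizes`` the
    member counts.
    """

    labels: np.ndarray
    ifs: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    sizes: np.ndarray
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def n_superpixels(self) -> int:
        return int(self.ifs.shape[0])


def init_grid(shape: tuple[int, int], k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Regular-grid seed placement.

    Tiles the M x N image with cells of step ``S = round(sqrt(M*N/K))`` and
    puts one seed at the center of each cell (row-major order).  Returns
    ``(seed_rows, seed_cols, S)``; the number of seeds is
    ``ceil(M/S) * ceil(N/S)``, which may differ slightly from K.
    """
    m, n = shape
    if m < 1 or n < 1:
        raise ContractError("image must have positive dimensions")
    if k > m * n:
        raise ParameterError(f"n_superpixels={k} exceeds pixel count {m * n}")
    step = max(int(round(np.sqrt(m * n / k))), 1)
    r_centers = np.array([(s + min(s + step, m)) // 2 for s in range(0, m, step)])
    c_centers = np.array([(s + min(s + step, n)) // 2 for s in range(0, n, step)])
    rr, cc = np.meshgrid(r_centers, c_centers, indexing="ij")
    return rr.ravel(), cc.ravel(), step


def update_memberships(
    pixels: np.ndarray,
    centroids: np.ndarray,
    gamma: float,
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Membership table U for pixels against centroid prototypes.

    Parameters
    ----------
    pixels : (L, 3) array of IFS triples (an (M, N, 3) array is flattened).
    centroids : (K, 3) array of prototype triples.
    gamma : fuzzifier (> 1).
    candidates : optional (L, K) boolean mask restricting which centroids a
        pixel may join; non-candidate entries of U are 0.  Every pixel needs
        at least one candidate.

    Each row of U sums to 1.  A pixel coinciding with a candidate prototype
    (squared distance <= ZERO_TOL) gives that prototype membership 1 (the
    lowest-id one if several coincide).
    """
    x = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    v = np.asarray(centroids, dtype=np.float64).reshape(-1, 3)
    d = np.sum((x[:, None, :] - v[None, :, :]) ** 2, axis=-1)  # (L, K)
    if candidates is not None:
        cand = np.asarray(candidates, dtype=bool)
        if cand.shape != d.shape:
            raise ContractError("candidates mask must have shape (L, K)")
        if not cand.any(axis=1).all():
            raise ContractError("every pixel needs at least one candidate centroid")
    else:
        cand = np.ones_like(d, dtype=bool)

    expo = 1.0 / (gamma - 1.0)
    with np.errstate(divide="ignore"):
        p = np.where(cand, d, np.inf) ** -expo  # non-candidates -> 0
    zero = (d <= ZERO_TOL) & cand
    u = np.zeros_like(d)
    has_zero = zero.any(axis=1)
    if has_zero.any():
        first = np.argmax(zero[has_zero], axis=1)
        u[np.flatnonzero(has_zero), first] = 1.0
    reg = ~has_zero
    u[reg] = p[reg] / p[reg].sum(axis=1, keepdims=True)
    return u


def update_centroids(
    pixels: np.ndarray, u: np.ndarray, gamma: float, old_centroids: np.ndarray | None = None
) -> np.ndarray:
    """Prototype update: each component of v_k is the u^gamma-weighted mean of
    the member pixels' (mu, nu, pi).

    A superpixel with zero total weight keeps its previous prototype when
    ``old_centroids`` is given (and is logged), else its row is NaN.
    Triples are renormalized onto the simplex if averaging drifts past 1e-10.
    """
    x = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    w = np.asarray(u, dtype=np.float64) ** gamma
    tw = w.sum(axis=0)  # (K,)
    v = w.T @ x  # (K, 3)
    dead = tw <= 0.0
    if dead.any():
        logger.warning("%d superpixels received zero weight; seeds retained", dead.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v = v / tw[:, None]
    if old_centroids is not None:
        old = np.asarray(old_centroids, dtype=np.float64).reshape(-1, 3)
        v[dead] = old[dead]
    s = v.sum(axis=1)
    drift = np.abs(s - 1.0) > 1e-10
    if drift.any():
        v[drift] = v[drift] / s[drift, None]
    return v


def clustering_objective(
    pixels: np.ndarray, centroids: np.ndarray, u: np.ndarray, gamma: float
) -> float:
    """Value of the IFCM functional J = sum u^gamma * d."""
    x = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    v = np.asarray(centroids, dtype=np.float64).reshape(-1, 3)
    d = np.sum((x[:, None, :] - v[None, :, :]) ** 2, axis=-1)
    return float(np.sum(np.asarray(u) ** gamma * d))


# ---------------------------------------------------------------------------
# main driver (blocked implementation: each centroid only ever touches the
# pixels of its fixed 2S x 2S candidate window, so memory stays O(L))
# ---------------------------------------------------------------------------

def run_local_clustering(pixels: IFSImage, params: SuperpixelParams) -> SuperpixelMap:
    """Segment an IFS image into superpixels by windowed IFCM.

    Alternates membership and prototype updates until the largest prototype
    component movement drops below ``params.tol`` or ``params.max_iter`` is
    reached (non-convergence is logged, not raised).  Returns the hard,
    connectivity-enforced partition with per-superpixel centroid statistics
    and the per-iteration objective values.
    """
    x = np.asarray(pixels.values, dtype=np.float64)
    m, n = x.shape[:2]
    seeds_r, seeds_c, step = init_grid((m, n), params.n_superpixels)
    k = seeds_r.size
    gamma = params.gamma
    expo = 1.0 / (gamma - 1.0)

    # fixed candidate windows: pixels within the 2S x 2S box around each seed
    blocks = []
    for r, c in zip(seeds_r, seeds_c):
        blocks.append(
            (
                slice(max(r - step, 0), min(r + step + 1, m)),
                slice(max(c - step, 0), min(c + step + 1, n)),
            )
        )
    v = x[seeds_r, seeds_c].copy()  # (K, 3) prototypes, seeded at grid pixels
    pos = np.stack([seeds_r, seeds_c], axis=1).astype(np.float64)

    row_idx = np.arange(m, dtype=np.float64)
    col_idx = np.arange(n, dtype=np.float64)

    def membership_pass(v, pos):
        """One exact membership update over the candidate windows.

        Returns per-block distance and membership arrays plus the objective
        J(U_new, v).  Coincident pixels (d <= ZERO_TOL) give full membership
        to the spatially nearest coincident centroid (ties: lowest id).
        """
        ptot = np.zeros((m, n))
        zid = np.full((m, n), -1, dtype=np.int32)
        zspat = np.full((m, n), np.inf)
        dists = []
        for kk, (bs, cs) in enumerate(blocks):
            d = np.sum((x[bs, cs] - v[kk]) ** 2, axis=-1)
            dists.append(d)
            zmask = d <= ZERO_TOL
            if zmask.any():
                sp = (row_idx[bs, None] - pos[kk, 0]) ** 2 + (
                    col_idx[None, cs] - pos[kk, 1]
                ) ** 2
                take = zmask & (sp < zspat[bs, cs])
                zid[bs, cs] = np.where(take, kk, zid[bs, cs])
                zspat[bs, cs] = np.where(take, sp, zspat[bs, cs])
            with np.errstate(divide="ignore"):
                ptot[bs, cs] += np.where(zmask, np.inf, d) ** -expo
        memberships = []
        obj = 0.0
        for kk, (bs, cs) in enumerate(blocks):
            d = dists[kk]
            zb = zid[bs, cs]
            with np.errstate(divide="ignore", invalid="ignore"):
                u = np.where(d <= ZERO_TOL, np.inf, d) ** -expo / ptot[bs, cs]
            u = np.where(zb >= 0, (zb == kk).astype(np.float64), u)
            memberships.append(u)
            obj += float(np.sum(u**gamma * d))
        return dists, memberships, obj

    objective: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        _, memberships, obj = membership_pass(v, pos)
        objective.append(obj)
        v_new = v.copy()
        pos_new = pos.copy()
        for kk, (bs, cs) in enumerate(blocks):
            w = memberships[kk] ** gamma
            tw = w.sum()
            if tw <= 0.0:
                logger.warning("superpixel %d received zero weight; seed retained", kk)
                continue
            v_new[kk] = np.tensordot(w, x[bs, cs], axes=([0, 1], [0, 1])) / tw
            pos_new[kk, 0] = (w.sum(axis=1) @ row_idx[bs]) / tw
            pos_new[kk, 1] = (w.sum(axis=0) @ col_idx[cs]) / tw
        s = v_new.sum(axis=1)
        drift = np.abs(s - 1.0) > 1e-10
        if drift.any():
            v_new[drift] /= s[drift, None]
        movement = float(np.abs(v_new - v).max())
        v, pos = v_new, pos_new
        if movement < params.tol:
            converged = True
            break
    if not converged and params.max_iter > 0:
        logger.warning(
            "IFCM did not converge in %d iterations (returning current state)",
            params.max_iter,
        )

    # final hard assignment from memberships at the final prototypes
    _, memberships, _ = membership_pass(v, pos)
    best = np.full((m, n), -1.0)
    labels = np.zeros((m, n), dtype=np.int32)
    for kk, (bs, cs) in enumerate(blocks):  # ascending k: ties -> lowest id
        u = memberships[kk]
        take = u > best[bs, cs]
        labels[bs, cs] = np.where(take, kk, labels[bs, cs])
        best[bs, cs] = np.where(take, u, best[bs, cs])

    labels = _enforce_connectivity(labels, x, min_size=max(step * step // 4, 1))
    return _finalize(labels, x, objective, it, converged)


def _enforce_connectivity(labels: np.ndarray, x: np.ndarray, min_size: int) -> np.ndarray:
    """Absorb connected fragments below ``min_size`` pixels into the adjacent
    region with the most similar mean IFS triple (ties: larger region, then
    lower id), so each final label is one connected region."""
    comp = cc_label(labels, connectivity=1, background=-1)
    ncomp = int(comp.max())
    if ncomp <= 1:
        return labels
    flat = comp.ravel() - 1
    sizes = np.bincount(flat, minlength=ncomp).astype(np.float64)
    sums = np.zeros((ncomp, 3))
    for ch in range(3):
        sums[:, ch] = np.bincount(flat, weights=x[..., ch].ravel(), minlength=ncomp)

    # component adjacency from horizontal/vertical neighbor pairs
    pairs = set()
    a, b = comp[:, :-1].ravel(), comp[:, 1:].ravel()
    for i, j in zip(a[a != b] - 1, b[a != b] - 1):
        pairs.add((min(i, j), max(i, j)))
    a, b = comp[:-1, :].ravel(), comp[1:, :].ravel()
    for i, j in zip(a[a != b] - 1, b[a != b] - 1):
        pairs.add((min(i, j), max(i, j)))
    neigh: list[set[int]] = [set() for _ in range(ncomp)]
    for i, j in pairs:
        neigh[i].add(j)
        neigh[j].add(i)

    parent = np.arange(ncomp)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(ncomp), key=lambda i: (sizes[i], i))
    for i in order:
        if find(i) != i or sizes[i] >= min_size or not neigh[i]:
            continue
        mean_i = sums[i] / sizes[i]
        best_j, best_key = -1, None
        for j0 in neigh[i]:
            j = find(j0)
            if j == i:
                continue
            mean_j = sums[j] / sizes[j]
            key = (float(np.sum((mean_i - mean_j) ** 2)), -sizes[j], j)
            if best_key is None or key < best_key:
                best_j, best_key = j, key
        if best_j < 0:
            continue
        parent[i] = best_j
        sums[best_j] += sums[i]
        sizes[best_j] += sizes[i]
        neigh[best_j] |= neigh[i]

    roots = np.array([find(i) for i in range(ncomp)])
    return roots[comp - 1].astype(np.int32)


def _finalize(
    labels: np.ndarray, x: np.ndarray, objective: list[float], n_iter: int, converged: bool
) -> SuperpixelMap:
    """Compact label ids and compute per-superpixel centroid statistics."""
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(x.shape[:2]).astype(np.int32)
    k = int(labels.max()) + 1
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=k)
    m, n = labels.shape
    rr, cc = np.mgrid[0:m, 0:n]
    rows = np.bincount(flat, weights=rr.ravel(), minlength=k) / sizes
    cols = np.bincount(flat, weights=cc.ravel(), minlength=k) / sizes
    ifs = np.stack(
        [np.bincount(flat, weights=x[..., ch].ravel(), minlength=k) / sizes for ch in range(3)],
        axis=1,
    )
    return SuperpixelMap(
        labels=labels,
        ifs=ifs,
        rows=rows,
        cols=cols,
        sizes=sizes,
        objective=objective,
        n_iter=n_iter,
        converged=converged,
    )
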