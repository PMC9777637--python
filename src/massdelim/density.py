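"""Density-based clustering of superpixels and mass-region extraction.

Each superpixel is summarized by its centroid — the mean (mu, nu, pi) triple,
optionally concatenated with its scaled image coordinates — and the centroids
are grouped by DBSCAN: a superpixel is *core* when at least ``min_neighbors``
centroids (counting itself) lie within radius ``delta``; clusters are the
transitive closure of core-to-core delta-reachability; non-core centroids
within delta of a core are *border* and adopt the cluster of their first core
neighbor in ascending id order; everything else is *noise*.  No cluster count
or initialization is needed, which suits images where the number of tissue
regions is unknown.

Breast masses are hypoechoic (darker than surrounding tissue in B-mode), so
the mass region defaults to the non-noise cluster with the lowest mean raw
intensity; the union of its superpixels, reduced to its largest connected
component with holes filled, is the output mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import ContractError, ParameterError
from .superpixels import SuperpixelMap

__all__ = [
    "DensityParams",
    "ClusterAssignment",
    "CORE",
    "BORDER",
    "NOISE",
    "centroid_features",
    "dbscan_superpixels",
    "extract_mass_mask",
]

logger = logging.getLogger(__name__)

CORE, BORDER, NOISE = 0, 1, 2
ROLE_NAMES = {CORE: "core", BORDER: "border", NOISE: "noise"}


@dataclass(frozen=True)
class DensityParams:
    """DBSCAN-over-superpixels parameters.

    delta
        Neighborhood radius in feature space.  Features live on [0, 1]-ish
        scales (IFS components, normalized coordinates), so delta is
        dimensionless; 0.12 separates hypoechoic mass centroids from
        background centroids on speckle phantoms while keeping same-tissue
        neighbors connected.
    min_neighbors
        Minimum neighbor count (the superpixel itself included) for a
        centroid to be core.
    feature_mode
        ``"ifs"`` clusters on the (mu, nu, pi) triple alone;
        ``"ifs+spatial"`` appends ``(row/M, col/N) * spatial_scale`` so that
        spatially remote look-alike regions must be chained through
        intermediate superpixels rather than merging outright.
    spatial_scale
        Weight of the normalized coordinates in ``"ifs+spatial"`` mode.
    """

    delta: float = 0.12
    min_neighbors: int = 4
    feature_mode: Literal["ifs", "ifs+spatial"] = "ifs+spatial"
    spatial_scale: float = 0.5

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ParameterError("delta must be > 0")
        if self.min_neighbors < 1:
            raise ParameterError("min_neighbors must be >= 1")
        if self.feature_mode not in ("ifs", "ifs+spatial"):
            raise ParameterError(f"unknown feature_mode: {self.feature_mode!r}")
        if self.spatial_scale < 0:
            raise ParameterError("spatial_scale must be >= 0")


@dataclass
class ClusterAssignment:
    """Per-superpixel global cluster id (−1 = noise) and DBSCAN role."""

    cluster_id: np.ndarray
    role: np.ndarray
    n_clusters: int


def centroid_features(spmap: SuperpixelMap, params: DensityParams) -> np.ndarray:
    """Feature vectors for DBSCAN: the centroid IFS triples, plus scaled
    normalized coordinates when ``feature_mode == "ifs+spatial"``."""
    feats = np.asarray(spmap.ifs, dtype=np.float64)
    if params.feature_mode == "ifs+spatial":
        m, n = spmap.labels.shape
        sp = np.stack([spmap.rows / m, spmap.cols / n], axis=1) * params.spatial_scale
        feats = np.concatenate([feats, sp], axis=1)
    return feats


def dbscan_superpixels(features: np.ndarray, params: DensityParams) -> ClusterAssignment:
    """Classical DBSCAN with Euclidean distance over centroid features.

    Deterministic: clusters are numbered by their smallest core superpixel
    id, and border superpixels adopt the cluster of their first (ascending
    id) core neighbor.  A single point with ``min_neighbors > 1`` is noise,
    not an error.
    """
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 2 or f.shape[0] < 1:
        raise ContractError("features must be a non-empty (n, F) array")
    n = f.shape[0]
    within = cdist(f, f) <= params.delta
    core = within.sum(axis=1) >= params.min_neighbors

    cluster_id = np.full(n, -1, dtype=np.int64)
    role = np.full(n, NOISE, dtype=np.int64)
    role[core] = CORE

    # clusters = connected components of the core-core reachability graph
    core_idx = np.flatnonzero(core)
    if core_idx.size:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        sub = within[np.ix_(core_idx, core_idx)]
        _, comp = connected_components(csr_matrix(sub), directed=False)
        # renumber components by smallest member superpixel id
        order = {}
        for i, c in zip(core_idx, comp):
            order.setdefault(c, i)
        ranks = {c: r for r, (c, _) in enumerate(sorted(order.items(), key=lambda t: t[1]))}
        cluster_id[core_idx] = [ranks[c] for c in comp]

    # border points: non-core within delta of a core; first core neighbor wins
    for i in np.flatnonzero(~core):
        nbrs = np.flatnonzero(within[i] & core)
        if nbrs.size:
            cluster_id[i] = cluster_id[nbrs[0]]
            role[i] = BORDER
    return ClusterAssignment(
        cluster_id=cluster_id, role=role, n_clusters=int(cluster_id.max()) + 1
    )


def extract_mass_mask(
    spmap: SuperpixelMap,
    assignment: ClusterAssignment,
    image: np.ndarray,
    select: int | Literal["darkest", "largest"] = "darkest",
    include_border: bool = True,
) -> np.ndarray:
    """Binary mass mask from a superpixel clustering.

    The mass cluster is, by default, the non-noise cluster with the lowest
    size-weighted mean raw intensity (hypoechoic-mass heuristic); pass an
    integer cluster id or ``"largest"`` to override.  Border superpixels of
    the chosen cluster are included unless ``include_border=False`` (the
    strict reading that keeps core superpixels only).  The mask is reduced to
    its largest connected component and its holes are filled.  If every
    superpixel is noise an empty mask is returned with a warning.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != spmap.labels.shape:
        raise ContractError("image shape does not match the superpixel map")
    cid, role = assignment.cluster_id, assignment.role
    if assignment.n_clusters == 0:
        logger.warning("all superpixels are noise; returning an empty mask")
        return np.zeros(img.shape, dtype=bool)

    k = spmap.n_superpixels
    sp_int = np.bincount(spmap.labels.ravel(), weights=img.ravel(), minlength=k)
    sizes = spmap.sizes.astype(np.float64)

    if select == "darkest":
        means = np.array(
            [
                sp_int[cid == c].sum() / sizes[cid == c].sum()
                for c in range(assignment.n_clusters)
            ]
        )
        chosen = int(np.argmin(means))
    elif select == "largest":
        areas = np.array(
            [sizes[cid == c].sum() for c in range(assignment.n_clusters)]
        )
        chosen = int(np.argmax(areas))
    else:
        chosen = int(select)
        if not 0 <= chosen < assignment.n_clusters:
            raise ParameterError(
                f"cluster id {chosen} out of range [0, {assignment.n_clusters})"
            )

    member = cid == chosen
    if not include_border:
        member &= role == CORE
    mask = member[spmap.labels]
    if not mask.any():
        logger.warning("selected cluster covers no pixels; returning an empty mask")
        return mask
    comp, ncomp = ndimage.label(mask)
    if ncomp > 1:
        areas = np.bincount(comp.ravel())[1:]
        mask = comp == (int(np.argmax(areas)) + 1)
    return ndimage.binary_fill_holes(mask)
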