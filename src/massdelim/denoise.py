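"""Edge-preserving Nonlocal Means (NLM) filtering of speckle-corrupted images.

Speckle in B-mode ultrasound is multiplicative, non-Gaussian granular noise
produced by coherent scattering; linear smoothing removes it only at the cost
of the lesion boundaries a radiologist actually needs.  NLM instead replaces
each pixel by a weighted average of pixels whose gray-level *neighborhoods*
look alike:

    NL(x)(i) = sum_j  w(i, j) * x(j),          0 <= w <= 1,  sum_j w = 1
    w(i, j)  = exp(-||x(N_i) - x(N_j)||^2 / h^2) / Z_i

where ``N_k`` is the square patch centered on pixel ``k``, ``Z_i`` the
per-pixel normalizing constant (the sum of the unnormalized affinities over
the search window), and ``h`` the filtering degree controlling the decay of
the exponential.  Pixels in homogeneous tissue find many similar patches and
are averaged strongly; pixels on an edge only find similar patches along the
edge, so the edge survives.

The sum over ``j`` is restricted to a square search window by default (the
standard windowed realization); ``full_search=True`` forces the literal sum
over every pixel, which is only practical for small images.  Patches at the
image border are taken from a mirror-padded image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import ContractError, ParameterError

__all__ = ["NLMParams", "nlm_weight", "nlm_filter", "suggest_h"]


@dataclass(frozen=True)
class NLMParams:
    """Nonlocal Means parameters.

    patch_radius
        Half-width of the square patch ``N_k`` (patch side ``2r+1``).
    search_radius
        Half-width of the search window over which weights are computed.
    h
        Filtering degree on the [0, 255] intensity scale; larger values
        average more aggressively.  A useful rule of thumb for the plain
        (unnormalized-SSD) weights used here is ``h ~ sigma * sqrt(2 * P)``
        with ``sigma`` the noise standard deviation and ``P`` the patch pixel
        count (see :func:`suggest_h`).
    full_search
        If True, sum over every pixel of the image instead of a window.
    """

    patch_radius: int = 3
    search_radius: int = 10
    h: float = 10.0
    full_search: bool = False

    def __post_init__(self) -> None:
        if self.patch_radius < 0:
            raise ParameterError("patch_radius must be >= 0")
        if self.search_radius < 1:
            raise ParameterError("search_radius must be >= 1")
        if not self.h > 0:
            raise ParameterError("h must be > 0")


def suggest_h(sigma: float, patch_radius: int = 3) -> float:
    """Filtering degree matched to noise level: ``sigma * sqrt(2 * P)``.

    With unnormalized squared patch distances, the expected distance between
    two patches drawn from the same homogeneous region is ``2 * sigma^2 * P``;
    choosing ``h`` at that scale gives same-region weights of order
    ``exp(-1)`` while inter-region weights stay negligible.
    """
    patch_pixels = (2 * patch_radius + 1) ** 2
    return float(sigma) * float(np.sqrt(2.0 * patch_pixels))


def nlm_weight(patch_i: np.ndarray, patch_j: np.ndarray, h: float) -> float:
    """Unnormalized NLM affinity ``exp(-||p_i - p_j||^2 / h^2)``.

    Normalization to ``sum_j w = 1`` is applied per pixel across the search
    window inside :func:`nlm_filter`.
    """
    if not h > 0:
        raise ParameterError("h must be > 0")
    a = np.asarray(patch_i, dtype=np.float64).ravel()
    b = np.asarray(patch_j, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ContractError(f"patch length mismatch: {a.shape} vs {b.shape}")
    d2 = float(np.sum((a - b) ** 2))
    return float(np.exp(-d2 / (h * h)))


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ContractError("expected a non-empty 2-D grayscale image")
    if not np.all(np.isfinite(img)):
        raise ContractError("image contains non-finite intensities")
    return img


def nlm_filter(image: np.ndarray, params: NLMParams = NLMParams()) -> np.ndarray:
    """Apply the Nonlocal Means filter; output has the input's shape, and every
    output pixel is a convex combination of (mirror-padded) input pixels."""
    img = _validate_image(image)
    if params.full_search:
        return _nlm_full(img, params)
    return _nlm_windowed(img, params)


def _nlm_windowed(img: np.ndarray, params: NLMParams) -> np.ndarray:
    m, n = img.shape
    pr, sr, h = params.patch_radius, params.search_radius, params.h
    pad = sr + pr
    padded = np.pad(img, pad, mode="reflect")
    side = 2 * pr + 1
    patch_pixels = side * side
    inv_h2 = 1.0 / (h * h)

    acc = np.zeros((m, n))
    wsum = np.zeros((m, n))
    # For each search offset, the patch SSD field is a box sum of the squared
    # difference between the padded image and its shifted copy.
    a0, a1 = pad - pr, pad + m + pr
    b0, b1 = pad - pr, pad + n + pr
    for dr in range(-sr, sr + 1):
        for dc in range(-sr, sr + 1):
            diff = padded[a0:a1, b0:b1] - padded[a0 + dr:a1 + dr, b0 + dc:b1 + dc]
            ssd = uniform_filter(diff * diff, size=side) * patch_pixels
            w = np.exp(-ssd[pr:pr + m, pr:pr + n] * inv_h2)
            acc += w * padded[pad + dr:pad + dr + m, pad + dc:pad + dc + n]
            wsum += w
    return acc / wsum


def _nlm_full(img: np.ndarray, params: NLMParams) -> np.ndarray:
    # Literal sum over every pixel j of the image; O(L^2) memory/time, meant
    # for small images.
    m, n = img.shape
    pr, h = params.patch_radius, params.h
    if m * n > 256 * 256:
        raise ParameterError("full_search is only supported for images up to 256x256")
    padded = np.pad(img, pr, mode="reflect")
    side = 2 * pr + 1
    patches = np.lib.stride_tricks.sliding_window_view(padded, (side, side))
    flat = patches.reshape(m * n, side * side)
    d2 = (
        np.sum(flat * flat, axis=1)[:, None]
        + np.sum(flat * flat, axis=1)[None, :]
        - 2.0 * flat @ flat.T
    )
    np.maximum(d2, 0.0, out=d2)
    w = np.exp(-d2 / (h * h))
    out = (w @ img.ravel()) / w.sum(axis=1)
    return out.reshape(m, n)
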