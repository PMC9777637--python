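"""Intuitionistic fuzzy set (IFS) representation of a grayscale image.

An intuitionistic fuzzy set attaches to each element a membership degree mu,
a non-membership degree nu, and a hesitancy degree pi = 1 - mu - nu that
quantifies the residual uncertainty.  For an image X with intensities x_l:

    mu(x_l) = (x_l - min X) / (max X - min X)          (min-max normalization)
    nu(x_l) = (1 - mu) / (1 + (e^lambda - 1) * mu),    lambda in [0, 1]
    pi(x_l) = 1 - mu - nu

The Sugeno-type generator above makes nu fall below 1 - mu for lambda > 0,
opening a hesitancy margin that is largest at intermediate intensities --
exactly where ultrasound tissue boundaries are ambiguous.  At lambda = 0 the
representation collapses to an ordinary fuzzy set (pi = 0 everywhere).

Clustering operates on the squared Euclidean distance between triples:

    d(a, b) = (mu_a - mu_b)^2 + (nu_a - nu_b)^2 + (pi_a - pi_b)^2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateImageError, ParameterError

__all__ = ["IFSImage", "ifs_transform", "ifs_distance"]

#: tolerance on the simplex constraint mu + nu + pi = 1
SIMPLEX_TOL = 1e-10


@dataclass
class IFSImage:
    """Per-pixel (mu, nu, pi) triples for a grayscale image.

    ``values`` has shape ``(M, N, 3)`` with channels (mu, nu, pi);
    ``lambda_used`` records the generator parameter that produced it.
    """

    values: np.ndarray
    lambda_used: float = field(default=0.5)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def mu(self) -> np.ndarray:
        return self.values[..., 0]

    @property
    def nu(self) -> np.ndarray:
        return self.values[..., 1]

    @property
    def pi(self) -> np.ndarray:
        return self.values[..., 2]


def ifs_transform(image: np.ndarray, lam: float = 0.5) -> IFSImage:
    """Transform a grayscale image into the intuitionistic fuzzy domain.

    Raises
    ------
    DegenerateImageError
        If the image is constant: min-max membership is then undefined
        (zero denominator).
    ParameterError
        If ``lam`` is outside [0, 1].
    """
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lambda must lie in [0, 1], got {lam}")
    img = np.asarray(image, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise DegenerateImageError(
            "constant image: min-max membership normalization is undefined "
            "(max(X) == min(X)); supply an image with at least two distinct "
            "intensities"
        )
    mu = (img - lo) / (hi - lo)
    # expm1 keeps lambda=0 exact: nu == 1 - mu, hence pi == 0 bit-exactly.
    nu = (1.0 - mu) / (1.0 + np.expm1(lam) * mu)
    pi = (1.0 - mu) - nu
    return IFSImage(values=np.stack([mu, nu, pi], axis=-1), lambda_used=float(lam))


def ifs_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray | float:
    """Squared Euclidean distance between IFS triples.

    Broadcasts over leading axes; the last axis must hold (mu, nu, pi).
    Symmetric, non-negative, and zero iff the triples coincide.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    d = np.sum((a - b) ** 2, axis=-1)
    return float(d) if np.ndim(d) == 0 else d
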