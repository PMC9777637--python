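"""Synthetic ultrasound-like phantoms with paired ground-truth masks.

A phantom is a hypoechoic (dark) elliptical or irregular mass on a brighter
background, corrupted by multiplicative speckle: the clean two-level template
is multiplied pixelwise by unit-mean Gamma noise with shape ``speckle_looks``
(the fully-developed-speckle intensity model; an L-look average of
exponential intensity speckle is Gamma(L, 1/L), so lower ``speckle_looks``
means noisier images, with coefficient of variation 1/sqrt(L)).  A Rayleigh
amplitude option is included.  The ground-truth mask is the exact rasterized
geometry; noise never touches it.

Mass boundaries mimic the clinical contrast between lesion types: benign
masses are well-circumscribed (smooth ellipse), malignant ones irregular
(elliptical base radius perturbed by low-order radial harmonics whose
amplitude is ``boundary_roughness``).

No attempt is made to simulate full ultrasound physics (PSF convolution,
attenuation, shadowing); these phantoms exercise the pipeline's contracts
and noise behavior, not clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ParameterError

__all__ = ["PhantomSpec", "generate_phantom", "benign_malignant_suite"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast, and noise of one phantom.

    Intensities are on the [0, 255] scale and must satisfy
    ``mass_intensity < background_intensity`` (hypoechoic mass).
    ``semi_axes`` is (vertical, horizontal) in pixels; ``center`` defaults to
    the image center.  ``noise_model`` is ``"gamma"`` (default),
    ``"rayleigh"``, or ``"none"`` (clean template, the infinite-looks limit).
    """

    height: int = 256
    width: int = 256
    mass_shape: Literal["ellipse", "blob"] = "ellipse"
    semi_axes: tuple[float, float] = (30.0, 40.0)
    center: tuple[float, float] | None = None
    mass_intensity: float = 55.0
    background_intensity: float = 160.0
    speckle_looks: float = 16.0
    boundary_roughness: float = 0.0
    noise_model: Literal["gamma", "rayleigh", "none"] = "gamma"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ParameterError("phantom dimensions must be positive")
        if not self.mass_intensity < self.background_intensity:
            raise ParameterError(
                "mass_intensity must be below background_intensity (hypoechoic mass)"
            )
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ParameterError("semi-axes must be positive")
        if 2 * a >= self.height or 2 * b >= self.width:
            raise ParameterError("mass does not fit inside the image")
        if not self.speckle_looks > 0:
            raise ParameterError("speckle_looks must be > 0")
        if self.boundary_roughness < 0:
            raise ParameterError("boundary_roughness must be >= 0")
        if self.noise_model not in ("gamma", "rayleigh", "none"):
            raise ParameterError(f"unknown noise_model: {self.noise_model!r}")


def _mass_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    m, n = spec.height, spec.width
    cr, cc = spec.center if spec.center is not None else ((m - 1) / 2.0, (n - 1) / 2.0)
    a, b = spec.semi_axes
    rr, cc_grid = np.mgrid[0:m, 0:n]
    dy, dx = rr - cr, cc_grid - cc
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # elliptical base radius r0(theta) = ab / sqrt((b cos t)^2 + (a sin t)^2)
    r0 = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if spec.mass_shape == "blob" and spec.boundary_roughness > 0:
        pert = np.zeros_like(theta)
        for j in range(2, 8):  # low-order harmonics; 1/j amplitude decay
            amp_c = rng.normal(0.0, 1.0 / j)
            amp_s = rng.normal(0.0, 1.0 / j)
            pert += amp_c * np.cos(j * theta) + amp_s * np.sin(j * theta)
        pert = np.clip(spec.boundary_roughness * pert, -0.45, 0.45)
        r0 = r0 * (1.0 + pert)
    return rho <= r0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom: (speckled image, exact binary ground truth).

    Fully reproducible from ``spec.seed``; the mask is computed before any
    noise is drawn and is never altered by it.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _mass_mask(spec, rng)
    clean = np.where(mask, spec.mass_intensity, spec.background_intensity).astype(np.float64)
    if spec.noise_model == "none":
        return clean, mask
    if spec.noise_model == "gamma":
        noise = rng.gamma(shape=spec.speckle_looks, scale=1.0 / spec.speckle_looks, size=clean.shape)
    else:  # rayleigh amplitude, rescaled to unit mean
        noise = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=clean.shape)
    return np.clip(clean * noise, 0.0, 255.0), mask


def benign_malignant_suite(
    n: int,
    seed: int,
    height: int = 256,
    width: int = 256,
    speckle_looks: float = 16.0,
    malignant_roughness: float = 0.35,
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """A balanced suite of (image, mask, label) phantoms.

    Even indices are smooth-boundary "benign" ellipses, odd indices
    rough-boundary "malignant" blobs; geometry and contrast are randomized
    per image (semi-axes U(22, 45) px, center jitter within ±10% of the
    image size, mass intensity U(40, 70), background U(140, 180)).
    Deterministic for a fixed ``seed``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        benign = i % 2 == 0
        axes = tuple(rng.uniform(22.0, 45.0, size=2))
        center = (
            (height - 1) / 2.0 + rng.uniform(-0.1, 0.1) * height,
            (width - 1) / 2.0 + rng.uniform(-0.1, 0.1) * width,
        )
        spec = PhantomSpec(
            height=height,
            width=width,
            mass_shape="ellipse" if benign else "blob",
            semi_axes=axes,
            center=center,
            mass_intensity=float(rng.uniform(40.0, 70.0)),
            background_intensity=float(rng.uniform(140.0, 180.0)),
            speckle_looks=speckle_looks,
            boundary_roughness=0.0 if benign else malignant_roughness,
            seed=int(rng.integers(0, 2**31)),
        )
        img, mask = generate_phantom(spec)
        out.append((img, mask, "benign" if benign else "malignant"))
    return out
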