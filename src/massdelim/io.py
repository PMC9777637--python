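"""Reading and writing of grayscale images, masks, and label maps.

Ultrasound datasets frequently ship grayscale content in RGB-encoded PNGs;
``read_gray`` collapses such images to luminance so the rest of the pipeline
always sees a 2-D float array on the [0, 255] scale.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .errors import ContractError

__all__ = ["read_gray", "write_gray", "read_mask", "write_mask", "write_labels"]

# ITU-R BT.601 luma weights, matching skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read an image as a 2-D float64 array on the [0, 255] intensity scale."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ContractError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    if arr.size == 0:
        raise ContractError(f"empty image: {path}")
    if arr.max() <= 1.0 and arr.dtype != np.uint8:
        arr = arr * 255.0
    return arr


def write_gray(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a [0, 255] float image as 8-bit grayscale."""
    iio.imwrite(path, np.clip(np.asarray(image), 0, 255).astype(np.uint8))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask PNG (any nonzero pixel is foreground)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 0


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_labels(path: str | os.PathLike, labels: np.ndarray) -> None:
    """Write a superpixel label map as 16-bit PNG (for inspection)."""
    if labels.max() >= 2**16:
        raise ContractError("label map has too many labels for 16-bit export")
    iio.imwrite(path, labels.astype(np.uint16))
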