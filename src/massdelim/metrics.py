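"""Segmentation quality metrics: JSC, DM, HD, MCR.

For a predicted mask X and ground truth Y (binary, same shape):

    JSC = |X ∩ Y| / |X ∪ Y|                 Jaccard similarity coefficient
    DM  = 2 |X ∩ Y| / (|X| + |Y|)           Dice measure
    HD  = max(h(X, Y), h(Y, X)),  h(A, B) = max_a min_b ||a - b||_2
    MCR = 100 * |{X != Y}| / L              misclassification ratio (percent)

JSC and DM compare foreground overlap (DM = 2 JSC / (1 + JSC)); HD is the
worst-case boundary error in pixels, computed here over the full foreground
pixel sets (a ``boundary=True`` variant restricts it to boundary pixels);
MCR counts all disagreeing pixels, background included.  Conventions for
cases real data never hits: two empty masks give JSC = DM = 1 and MCR = 0,
while HD is undefined for an empty mask and raises.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import directed_hausdorff

from .errors import ContractError, EmptyMaskError

__all__ = ["MetricsReport", "jaccard", "dice", "hausdorff", "mcr", "evaluate_masks"]


@dataclass(frozen=True)
class MetricsReport:
    """One mask pair's metrics; jsc/dm in [0,1], hd in pixels, mcr in percent."""

    jsc: float
    dm: float
    hd: float
    mcr: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ContractError(f"mask shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """|X ∩ Y| / |X ∪ Y| over foreground pixels; 1 if both masks are empty."""
    x, y = _pair(x, y)
    union = np.count_nonzero(x | y)
    if union == 0:
        return 1.0
    return np.count_nonzero(x & y) / union


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """2 |X ∩ Y| / (|X| + |Y|); 1 if both masks are empty."""
    x, y = _pair(x, y)
    total = np.count_nonzero(x) + np.count_nonzero(y)
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(x & y) / total


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~binary_erosion(mask, border_value=0)


def hausdorff(x: np.ndarray, y: np.ndarray, boundary: bool = False) -> float:
    """Symmetric Hausdorff distance (pixels) between foreground coordinate
    sets; ``boundary=True`` uses boundary pixels only."""
    x, y = _pair(x, y)
    if not x.any() or not y.any():
        raise EmptyMaskError("Hausdorff distance is undefined for an empty mask")
    if boundary:
        x, y = _boundary(x), _boundary(y)
    px = np.argwhere(x).astype(np.float64)
    py = np.argwhere(y).astype(np.float64)
    return max(directed_hausdorff(px, py)[0], directed_hausdorff(py, px)[0])


def mcr(x: np.ndarray, y: np.ndarray) -> float:
    """Percentage of pixels where the two masks disagree."""
    x, y = _pair(x, y)
    return 100.0 * np.count_nonzero(x ^ y) / x.size


def evaluate_masks(x: np.ndarray, y: np.ndarray, boundary_hd: bool = False) -> MetricsReport:
    """All four metrics for one (predicted, ground-truth) mask pair."""
    return MetricsReport(
        jsc=jaccard(x, y),
        dm=dice(x, y),
        hd=hausdorff(x, y, boundary=boundary_hd),
        mcr=mcr(x, y),
    )
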