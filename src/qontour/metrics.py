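"""Shared post-processing operators and segmentation evaluation metrics.

Post-processing applied by every segmentation method in this package:
keep the largest connected component (8-connectivity in 2D, 26 in 3D)
and fill enclosed holes (complementary 4/6 background connectivity).

Metrics: Sørensen-Dice coefficient DSC = 2|X∩Y| / (|X|+|Y|) and the
Hausdorff distance between mask boundary voxel sets (Euclidean, voxel
units by default, millimetres when a spacing is supplied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Any

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from skimage.filters import threshold_multiotsu

from .imaging import BinaryMask, DegenerateInputError

__all__ = [
    "EvalRecord",
    "dice",
    "hausdorff",
    "largest_connected_component",
    "fill_holes",
    "postprocess_mask",
    "multi_otsu_highest",
    "evaluate",
]


@dataclass
class EvalRecord:
    """Per-case evaluation result for one segmentation method."""

    method: str
    dice: float
    hausdorff: float  # math.inf when either mask is empty
    params: dict[str, Any] = dataclass_field(default_factory=dict)
    case_id: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "dice": self.dice,
            "hausdorff": self.hausdorff,
            "params": self.params,
            "case_id": self.case_id,
        }


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.data
    return np.asarray(mask, dtype=bool)


def dice(x: BinaryMask | np.ndarray, y: BinaryMask | np.ndarray) -> float:
    """Sørensen-Dice coefficient; 1.0 when both masks are empty."""
    a, b = _as_bool(x), _as_bool(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: foreground voxels with a background face-neighbor."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def hausdorff(
    x: BinaryMask | np.ndarray,
    y: BinaryMask | np.ndarray,
    spacing: tuple[float, ...] | None = None,
) -> float:
    """Symmetric Hausdorff distance between boundary voxel sets.

    Returns ``math.inf`` when either mask is empty (flag, not an error).
    """
    a, b = _as_bool(x), _as_bool(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        return math.inf
    pa = np.argwhere(_boundary(a)).astype(float)
    pb = np.argwhere(_boundary(b)).astype(float)
    if spacing is not None:
        pa *= np.asarray(spacing, dtype=float)
        pb *= np.asarray(spacing, dtype=float)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def _full_connectivity(ndim: int) -> np.ndarray:
    # 8-connectivity in 2D, 26 in 3D
    return np.ones((3,) * ndim, dtype=bool)


def largest_connected_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest foreground component.

    Size ties are broken in favour of the component containing the lowest
    linear voxel index.
    """
    data = mask.data
    if not data.any():
        return mask
    labels, n = ndimage.label(data, structure=_full_connectivity(data.ndim))
    if n == 1:
        return mask
    flat = labels.ravel()
    sizes = np.bincount(flat)[1:]  # skip background
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) == 1:
        keep = best[0]
    else:
        # earliest linear index among tied components
        first_idx = {lab: np.flatnonzero(flat == lab)[0] for lab in best}
        keep = min(best, key=lambda lab: first_idx[lab])
    return mask.with_data(labels == keep)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background regions not connected to the image border.

    Uses the complementary background connectivity (4 in 2D, 6 in 3D).
    """
    return mask.with_data(ndimage.binary_fill_holes(mask.data))


def postprocess_mask(mask: BinaryMask) -> BinaryMask:
    """Largest connected component followed by hole filling."""
    return fill_holes(largest_connected_component(mask))


def multi_otsu_highest(values: np.ndarray, levels: int = 4) -> float:
    """Highest of the (levels-1) multi-Otsu thresholds of ``values``.

    Thresholds maximize between-class variance on a 256-bin histogram.
    Raises :class:`DegenerateInputError` if the data has fewer distinct
    values than requested classes.
    """
    values = np.asarray(values, dtype=float)
    n_distinct = len(np.unique(values))
    if n_distinct < levels:
        raise DegenerateInputError(
            f"need >= {levels} distinct values for {levels}-level Otsu, got {n_distinct}"
        )
    try:
        thresholds = threshold_multiotsu(values, classes=levels, nbins=256)
    except ValueError as exc:  # fewer distinct histogram bins than classes
        raise DegenerateInputError(str(exc)) from exc
    return float(thresholds[-1])


def evaluate(
    pred: BinaryMask,
    truth: BinaryMask,
    method: str = "",
    params: dict[str, Any] | None = None,
    case_id: str = "",
    spacing: tuple[float, ...] | None = None,
) -> EvalRecord:
    """Compute Dice and Hausdorff distance of a prediction against truth."""
    return EvalRecord(
        method=method,
        dice=dice(pred, truth),
        hausdorff=hausdorff(pred, truth, spacing=spacing),
        params=dict(params or {}),
        case_id=case_id,
    )
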