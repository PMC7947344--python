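"""Cell-size morphometry and clinical normalizations.

Covers the confocal-scale half of the study: cardiomyocyte cross-sectional
areas from label masks of transversely sectioned cells, Du Bois body-surface
area (BSA), atrial volumes indexed to BSA, and Pearson correlation between
per-patient quantities (e.g. indexed right-atrial end-systolic volume vs
mean cardiomyocyte cross-sectional area, the hypertrophy–dilation
relationship).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "du_bois_bsa",
    "indexed_volume",
    "cell_areas",
    "correlate",
    "CorrelationResult",
    "synthetic_cell_masks",
]


def du_bois_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m²) by the Du Bois formula.

    ``BSA = 0.007184 * weight^0.425 * height^0.725`` with weight in kg and
    height in cm.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg ** 0.425 * height_cm ** 0.725


def indexed_volume(raw_ml: float, bsa_m2: float) -> float:
    """Atrial volume indexed to body surface area (mL·m⁻²)."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    return raw_ml / bsa_m2


def cell_areas(label_mask: np.ndarray, um_per_px: float) -> np.ndarray:
    """Per-cell cross-sectional areas (µm²) from a label mask.

    ``label_mask`` holds 0 for background and a distinct positive integer
    per cell; area = pixel count x (µm/px)².  Labels need not be
    consecutive.  An empty mask yields an empty array.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return np.zeros(0)
    counts = np.array([(label_mask == lab).sum() for lab in labels], dtype=float)
    return counts * um_per_px ** 2


class CorrelationResult(NamedTuple):
    r: float
    r2: float
    p: float
    n: int


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation between paired per-patient values.

    Returns r, r², the two-sided p-value from the t transform, and n.
    Requires n >= 3 complete pairs; a zero-variance variable yields NaN with
    a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in correlation input")
    n = len(x)
    if n < 3:
        raise ValueError("correlation requires n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in correlation input; r undefined")
        return CorrelationResult(np.nan, np.nan, np.nan, n)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r, r * r, float(res.pvalue), n)


def synthetic_cell_masks(areas_um2: list[float], um_per_px: float,
                         pad_px: int = 4) -> np.ndarray:
    """Build a label mask of square cells with the requested areas (test fixture).

    Each requested area is realised as a square of
    ``round(sqrt(area) / um_per_px)²`` pixels, so the recovered area matches
    the pixel-quantized request exactly.  Cells are laid out in a row with
    ``pad_px`` background pixels between them.
    """
    sides = [max(1, int(round(np.sqrt(a) / um_per_px))) for a in areas_um2]
    h = max(sides) + 2 * pad_px if sides else 2 * pad_px
    w = sum(sides) + pad_px * (len(sides) + 1)
    mask = np.zeros((h, max(1, w)), dtype=np.int32)
    x = pad_px
    for i, s in enumerate(sides, start=1):
        mask[pad_px:pad_px + s, x:x + s] = i
        x += s + pad_px
    return mask
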