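"""SUV quantification layer: ROI statistics, SUVmax, contrast recovery,
lesion stratification and paired significance testing.

Conventions: SUVmax of a lesion is the mean of its 5 hottest voxels (less
noise-sensitive than the single hottest voxel); SUVstd over a uniform
background ROI is the noise surrogate and uses the population standard
deviation; lesion masks are the true phantom masks dilated by one voxel so
hot voxels displaced by the PSF are captured.  Contrast recovery compares a
reconstruction's tumor-to-background ratio to the reference OSEM's:

    CR = ((SUVmax / SUVmean_bkg) - 1) / ((SUVmax_ref / SUVmean_bkg_ref) - 1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.stats

__all__ = [
    "RoiStats",
    "LesionRecord",
    "roi_stats",
    "suvmax5",
    "contrast_recovery",
    "classify_lesion",
    "wilcoxon_signed_rank",
    "dilate_mask",
    "ContrastRecoveryError",
    "DegenerateDifferencesError",
]


class ContrastRecoveryError(ValueError):
    """Reference lesion not above background: CR denominator non-positive."""


class DegenerateDifferencesError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass(frozen=True)
class RoiStats:
    suv_mean: float
    suv_std: float
    n_voxels: int


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    volume_cm3: float
    suvmax_ref: float
    suvmax: float
    group: str
    cr: float


def roi_stats(image: np.ndarray, mask: np.ndarray) -> RoiStats:
    """Mean and population standard deviation over masked voxels."""
    vals = np.asarray(image)[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    return RoiStats(float(vals.mean()), float(vals.std(ddof=0)), int(vals.size))


def suvmax5(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean of the 5 hottest masked voxels (all voxels if fewer than 5)."""
    vals = np.asarray(image)[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    if vals.size < 5:
        warnings.warn("mask has fewer than 5 voxels; using all", stacklevel=2)
        return float(vals.mean())
    top = np.partition(vals, vals.size - 5)[-5:]
    return float(top.mean())


def contrast_recovery(
    suvmax: float, bkg_mean: float, suvmax_ref: float, bkg_mean_ref: float
) -> float:
    """Contrast recovery ratio vs the reference reconstruction (>1 = better)."""
    denom = suvmax_ref / bkg_mean_ref - 1.0
    if denom <= 0:
        raise ContrastRecoveryError(
            "reference lesion SUVmax not above reference background"
        )
    return (suvmax / bkg_mean - 1.0) / denom


def classify_lesion(volume_cm3: float, suvmax_ref: float) -> str:
    """Stratify a lesion by size and reference-reconstruction uptake.

    small_low:  volume <= 1 cm^3 and SUVmax_ref <= 5 g/ml
    large_high: volume > 10 cm^3 or SUVmax_ref > 10 g/ml
    medium_medium: everything else
    """
    if volume_cm3 <= 0:
        raise ValueError("volume must be > 0")
    if suvmax_ref < 0:
        raise ValueError("suvmax_ref must be >= 0")
    if volume_cm3 > 10.0 or suvmax_ref > 10.0:
        return "large_high"
    if volume_cm3 <= 1.0 and suvmax_ref <= 5.0:
        return "small_low"
    return "medium_medium"


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 nonzero pairs, the normal approximation above.  Returns
    (statistic, two-sided p).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        raise DegenerateDifferencesError("all paired differences are zero")
    method = "exact" if n_nonzero <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def dilate_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Dilate a boolean mask by one voxel (26-connectivity) per iteration."""
    return ndi.binary_dilation(np.asarray(mask, bool), _STRUCT_26, iterations=iterations)
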