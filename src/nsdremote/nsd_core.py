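"""The method under evaluation: mean + n*SD thresholding from a remote ROI.

Remote-ROI statistics, the threshold, whole-myocardium classification,
optional removal of small disconnected supra-threshold islands, and the
per-slice infarct size as a percentage of myocardial pixel area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RemoteStats",
    "SegParams",
    "SegResult",
    "remote_stats",
    "nsd_threshold",
    "classify",
    "remove_spurious",
    "infarct_fraction",
    "segment_slice",
]

DEFAULT_MIN_ROI_PIXELS = 10

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class RemoteStats:
    mu: float
    sigma: float
    pixel_count: int


@dataclass(frozen=True)
class SegParams:
    """n-SD segmentation parameters.

    ``remove_spurious`` selects the variant that deletes disconnected
    supra-threshold islands smaller than ``min_island`` pixels (the
    "no-spurious" variant); the naive variant keeps them.
    """

    n: float = 3.5
    remove_spurious: bool = False
    min_island: int = 10
    connectivity: int = 8

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.min_island < 1:
            raise ValueError("min_island must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SegResult:
    infarct_mask: np.ndarray
    threshold: float
    infarct_fraction_pct: float
    removed_pixels: int
    stats: RemoteStats


def remote_stats(
    image: np.ndarray,
    roi_mask: np.ndarray,
    min_roi_pixels: int = DEFAULT_MIN_ROI_PIXELS,
) -> RemoteStats:
    """Mean and sample SD (ddof=1) of intensities inside the remote ROI."""
    values = np.asarray(image, dtype=float)[np.asarray(roi_mask, dtype=bool)]
    count = values.size
    if count < min_roi_pixels:
        raise ValueError(f"remote ROI has {count} pixels; at least {min_roi_pixels} required")
    if values.max() == values.min():
        # exact noiseless limit: avoid rounding residue from the mean
        return RemoteStats(mu=float(values[0]), sigma=0.0, pixel_count=count)
    sigma = float(values.std(ddof=1)) if count > 1 else 0.0
    return RemoteStats(mu=float(values.mean()), sigma=sigma, pixel_count=count)


def nsd_threshold(stats: RemoteStats, n: float) -> float:
    """Classification threshold: remote mean plus n remote SDs."""
    if n <= 0:
        raise ValueError("n must be positive")
    return stats.mu + n * stats.sigma


def classify(image: np.ndarray, myo_mask: np.ndarray, threshold: float) -> np.ndarray:
    """Myocardial pixels strictly brighter than the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(myo_mask, dtype=bool) & (np.asarray(image, dtype=float) > threshold)


def remove_spurious(
    mask: np.ndarray, min_island: int = 10, connectivity: int = 8
) -> tuple[np.ndarray, int]:
    """Delete connected components smaller than ``min_island`` pixels.

    Returns the cleaned mask and the number of pixels removed.
    """
    if min_island < 1:
        raise ValueError("min_island must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels, n_comp = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n_comp == 0:
        return mask.copy(), 0
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_island
    keep[0] = False
    cleaned = keep[labels]
    return cleaned, int(mask.sum() - cleaned.sum())


def infarct_fraction(infarct_mask: np.ndarray, myo_mask: np.ndarray) -> float:
    """Infarct size as percent of myocardial pixel count (pure area ratio)."""
    myo_count = int(np.asarray(myo_mask, dtype=bool).sum())
    if myo_count == 0:
        raise ValueError("myocardium mask is empty")
    inf = np.asarray(infarct_mask, dtype=bool)
    if np.any(inf & ~np.asarray(myo_mask, dtype=bool)):
        raise ValueError("infarct mask extends outside the myocardium")
    return 100.0 * int(inf.sum()) / myo_count


def segment_slice(
    image: np.ndarray,
    myo_mask: np.ndarray,
    roi_mask: np.ndarray,
    params: SegParams,
    min_roi_pixels: int = DEFAULT_MIN_ROI_PIXELS,
) -> SegResult:
    """Full n-SD-from-remote segmentation of one slice.

    MVO-like pixels darker than the threshold are not captured: there is no
    rescue step, by design of the method under evaluation.
    """
    stats = remote_stats(image, roi_mask, min_roi_pixels=min_roi_pixels)
    threshold = nsd_threshold(stats, params.n)
    mask = classify(image, myo_mask, threshold)
    removed = 0
    if params.remove_spurious:
        mask, removed = remove_spurious(mask, params.min_island, params.connectivity)
    pct = infarct_fraction(mask, myo_mask)
    return SegResult(
        infarct_mask=mask,
        threshold=threshold,
        infarct_fraction_pct=pct,
        removed_pixels=removed,
        stats=stats,
    )
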