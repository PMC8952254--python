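"""Region-of-interest container and gray-level discretization."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class RoiSample:
    """A masked (sub)volume ready for feature computation.

    ``volume`` and ``mask`` share shape; ``levels`` holds the discretized
    gray levels (1..n_bins inside the mask, 0 outside) once
    :func:`discretize` has run.
    """

    volume: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    levels: Optional[np.ndarray] = None
    n_bins: Optional[int] = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.volume.shape != self.mask.shape:
            raise ValueError("volume and mask shapes differ")
        if not self.mask.any():
            raise ValueError("ROI mask has no foreground voxel")

    @property
    def intensities(self) -> np.ndarray:
        """Foreground intensity values, flattened."""
        return self.volume[self.mask]

    @property
    def discrete_values(self) -> np.ndarray:
        if self.levels is None:
            raise ValueError("ROI has not been discretized")
        return self.levels[self.mask]


def crop_to_mask(volume: np.ndarray, mask: np.ndarray, margin: int = 2):
    """Crop volume and mask to the mask bounding box plus ``margin`` voxels."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask has no foreground voxel")
    slices = []
    for ax in range(mask.ndim):
        proj = mask.any(axis=tuple(a for a in range(mask.ndim) if a != ax))
        idx = np.flatnonzero(proj)
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + margin + 1, mask.shape[ax])
        slices.append(slice(lo, hi))
    sl = tuple(slices)
    return np.asarray(volume)[sl], mask[sl]


def discretize(roi: RoiSample, n_bins: int = 32) -> RoiSample:
    """Fixed-bin-count quantization of foreground intensities.

    Gray level g(x) = ceil((x - min) / w) with w = (max - min) / n_bins and
    g(min) := 1, i.e. right-closed bins (lo, hi]: the minimum maps to level
    1 and the maximum to level n_bins. A constant ROI maps every voxel to
    level 1 (a single occupied level; downstream texture features then take
    their documented degenerate limits).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = roi.intensities
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(roi.mask.shape, dtype=np.int32)
    if hi == lo:
        levels[roi.mask] = 1
    else:
        width = (hi - lo) / n_bins
        g = np.ceil((roi.volume - lo) / width)
        g = np.clip(g, 1, n_bins).astype(np.int32)
        levels[roi.mask] = g[roi.mask]
    return RoiSample(roi.volume, roi.mask, roi.spacing, levels=levels, n_bins=n_bins)
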