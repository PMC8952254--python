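"""Single-level 3D wavelet subband features: 8 subbands x 57 = 456.

The volume is decomposed once with a separable 3D discrete wavelet
transform in periodization mode, which yields eight subbands (LLL..HHH,
L = approximation, H = detail, one letter per axis) of shape ceil(n/2) per
axis. The mask is aligned to the subband grid by nearest-neighbor
downsampling (every second voxel), and on each subband the 18 first-order
plus 39 texture features are recomputed over the aligned mask. Shape
features are not recomputed per subband: the mask geometry does not change
with filtering, which is how 57 = 18 + 39 comes about.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pywt

from .intensity import intensity_features
from .roi import RoiSample, discretize
from .texture import texture_features, texture_matrices

#: subband names in canonical order; 'L' = lowpass per axis
SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def wavelet_subbands(volume: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Decompose a 3D volume into its 8 single-level subbands."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    coeffs = pywt.dwtn(volume, wavelet, mode="periodization")
    out = {}
    for name in SUBBAND_NAMES:
        key = "".join("a" if c == "L" else "d" for c in name)
        out[name] = coeffs[key]
    return out


def downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Nearest-neighbor mask alignment to the half-resolution subband grid."""
    return np.asarray(mask).astype(bool)[::2, ::2, ::2]


def wavelet_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing,
    wavelet: str = "coif1",
    n_bins: int = 32,
) -> pd.Series:
    """456 features: 18 intensity + 39 texture on each of the 8 subbands.

    Raises if the downsampled mask is empty (names the subband so pipeline
    errors point at the offending stage).
    """
    bands = wavelet_subbands(volume, wavelet)
    sub_mask = downsample_mask(mask)
    sub_spacing = tuple(2.0 * s for s in spacing)
    parts = []
    for name in SUBBAND_NAMES:
        band = bands[name]
        if band.shape != sub_mask.shape:
            raise ValueError(
                f"subband {name}: shape {band.shape} does not match downsampled "
                f"mask {sub_mask.shape}"
            )
        if not sub_mask.any():
            raise ValueError(f"mask empty after alignment to wavelet subband {name}")
        roi = discretize(RoiSample(band, sub_mask, sub_spacing), n_bins)
        feats = pd.concat(
            [
                intensity_features(roi).add_prefix("intensity."),
                texture_features(texture_matrices(roi)),
            ]
        )
        parts.append(feats.add_prefix(f"wavelet-{name}."))
    return pd.concat(parts)
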