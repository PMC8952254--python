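"""First-order (intensity histogram) features: 18 statistics of the ROI.

Entropy and uniformity are computed on the discretized gray-level
histogram; everything else on the raw foreground intensities. Dispersion
statistics use the population convention (ddof=0). Degenerate conventions:
a constant or single-voxel ROI has variance/MAD/IQR 0, skewness and
(excess) kurtosis defined as 0, entropy 0 and uniformity 1.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .roi import RoiSample, discretize

INTENSITY_FEATURE_NAMES = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Energy",
    "RootMeanSquared",
    "Entropy",
    "Uniformity",
    "10Percentile",
    "90Percentile",
    "InterquartileRange",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
)


def intensity_features(roi: RoiSample) -> pd.Series:
    """The 18 first-order statistics as a named series."""
    x = roi.intensities.astype(float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))

    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    else:
        skew = 0.0
        kurt = 0.0

    if roi.levels is not None:
        disc = roi.discrete_values
    else:
        disc = discretize(roi, 32).discrete_values
    counts = np.bincount(disc)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    values = {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x**2).sum()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
    }
    return pd.Series([values[k] for k in INTENSITY_FEATURE_NAMES], index=list(INTENSITY_FEATURE_NAMES))
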