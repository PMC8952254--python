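"""Gray-level texture matrices and their 39 features (8+13+13+5).

Conventions (the common 3D radiomics choices, stated here because several
are ambiguous in the literature):

* GLCM: distance-1 offsets over the 13 unique 3D directions; each
  directional matrix is symmetrized and normalized, then the normalized
  matrices are averaged over directions with at least one voxel pair.
* GLRLM: runs of equal gray level along the same 13 directions, restricted
  to mask voxels (a masked-out voxel breaks a run); directional count
  matrices are summed ("merged"); RunPercentage divides by
  n_voxels * n_directions so it stays in (0, 1].
* GLSZM: 26-connected zones of equal gray level, one matrix per ROI
  (zones are direction-free).
* NGTDM: per Amadasun & King, neighborhood = the 26-neighbors inside the
  mask; a voxel contributes if it has at least one masked neighbor.

Degenerate single-gray-level ROIs take documented limits (GLCM energy 1,
contrast 0, correlation 1; NGTDM coarseness capped at 1e6, busyness and
strength 0).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .roi import RoiSample

#: the 13 unique direction vectors of a 3D distance-1 neighborhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

_COARSENESS_CAP = 1e6

GLCM_FEATURE_NAMES = (
    "JointEnergy",
    "Contrast",
    "Correlation",
    "JointEntropy",
    "InverseDifferenceMoment",
    "Dissimilarity",
    "ClusterShade",
    "ClusterProminence",
)
GLRLM_FEATURE_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "RunLengthNonUniformity",
    "RunPercentage",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "GrayLevelVariance",
    "RunLengthVariance",
)
GLSZM_FEATURE_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "SizeZoneNonUniformity",
    "ZonePercentage",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "GrayLevelVariance",
    "ZoneVariance",
)
NGTDM_FEATURE_NAMES = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)


@dataclass
class TextureMatrices:
    """The four gray-level matrices of one discretized ROI."""

    glcm: np.ndarray  # n_bins x n_bins, normalized (sums to 1)
    glrlm: np.ndarray  # n_bins x max_run, raw counts
    glszm: np.ndarray  # n_bins x max_zone, raw counts
    ngtdm_n: np.ndarray  # per-level voxel counts n_i (length n_bins)
    ngtdm_s: np.ndarray  # per-level summed absolute differences s_i
    n_voxels: int
    n_bins: int

    @property
    def ngtdm_p(self) -> np.ndarray:
        """Occupancy probabilities p_i (sum to 1 over occupied levels)."""
        total = self.ngtdm_n.sum()
        return self.ngtdm_n / total if total > 0 else self.ngtdm_n


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------

def _offset_slices(shape, d):
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm_matrix(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Direction-averaged, symmetrized, normalized co-occurrence matrix."""
    mats = []
    for d in DIRECTIONS_13:
        src, dst = _offset_slices(levels.shape, d)
        a = levels[src].ravel()
        b = levels[dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        a, b = a[valid] - 1, b[valid] - 1
        m = np.zeros((n_bins, n_bins), dtype=np.float64)
        np.add.at(m, (a, b), 1.0)
        m = m + m.T
        mats.append(m / m.sum())
    if not mats:
        raise ValueError("no co-occurring voxel pairs in ROI")
    return np.mean(mats, axis=0)


def glrlm_matrix(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Run-length counts summed over the 13 directions.

    Runs are maximal straight segments of constant gray level consisting of
    mask voxels only.
    """
    shape = levels.shape
    max_run = int(max(shape))
    R = np.zeros((n_bins, max_run), dtype=np.float64)
    idx = np.indices(shape).reshape(3, -1)
    lv = levels.ravel()
    for d in DIRECTIONS_13:
        # parametrize each line by t along the first nonzero axis of d
        axis = next(a for a in range(3) if d[a] != 0)
        t = idx[axis] * d[axis]
        u = [idx[a] - t * d[a] for a in range(3)]
        order = np.lexsort((t, u[2], u[1], u[0]))
        lv_s = lv[order]
        # line boundaries: any line-invariant coordinate changes
        u_sorted = np.stack([ua[order] for ua in u])
        boundary = np.ones(lv_s.size, dtype=bool)
        boundary[1:] = (np.diff(u_sorted, axis=1) != 0).any(axis=0)
        run_start = boundary.copy()
        run_start[1:] |= lv_s[1:] != lv_s[:-1]
        starts = np.flatnonzero(run_start)
        lengths = np.diff(np.append(starts, lv_s.size))
        keep = lv_s[starts] > 0
        np.add.at(R, (lv_s[starts[keep]] - 1, lengths[keep] - 1), 1.0)
    return R


def glszm_matrix(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Zone-size counts: 26-connected components of equal gray level."""
    structure = np.ones((3, 3, 3), dtype=int)
    n_voxels = int((levels > 0).sum())
    Z = np.zeros((n_bins, max(n_voxels, 1)), dtype=np.float64)
    for g in np.unique(levels[levels > 0]):
        lab, n_zones = ndimage.label(levels == g, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            Z[g - 1, s - 1] += 1.0
    return Z


def ngtdm_components(levels: np.ndarray, n_bins: int):
    """Per-level counts n_i and summed neighborhood differences s_i."""
    mask = levels > 0
    kernel = np.ones((3, 3, 3), dtype=np.float64)
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.correlate(levels.astype(np.float64) * mask, kernel, mode="constant")
    neigh_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant")
    valid = mask & (neigh_cnt > 0)
    diffs = np.zeros_like(neigh_sum)
    diffs[valid] = np.abs(levels[valid] - neigh_sum[valid] / neigh_cnt[valid])
    n = np.zeros(n_bins, dtype=np.float64)
    s = np.zeros(n_bins, dtype=np.float64)
    lv = levels[valid]
    np.add.at(n, lv - 1, 1.0)
    np.add.at(s, lv - 1, diffs[valid])
    return n, s


def texture_matrices(roi: RoiSample) -> TextureMatrices:
    """Build all four matrices from a discretized ROI."""
    if roi.levels is None or roi.n_bins is None:
        raise ValueError("ROI must be discretized before texture analysis")
    levels = roi.levels
    n_bins = roi.n_bins
    n, s = ngtdm_components(levels, n_bins)
    return TextureMatrices(
        glcm=glcm_matrix(levels, n_bins),
        glrlm=glrlm_matrix(levels, n_bins),
        glszm=glszm_matrix(levels, n_bins),
        ngtdm_n=n,
        ngtdm_s=s,
        n_voxels=int(roi.mask.sum()),
        n_bins=n_bins,
    )


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------

def glcm_features(tm: TextureMatrices) -> pd.Series:
    """8 co-occurrence features of the direction-averaged GLCM."""
    P = tm.glcm
    n = P.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    contrast = float((P * (ii - jj) ** 2).sum())
    if sigma2 > 0:
        correlation = float((P * (ii - mu) * (jj - mu)).sum() / sigma2)
    else:
        correlation = 1.0  # single occupied level: perfectly correlated limit

    values = {
        "JointEnergy": float((P**2).sum()),
        "Contrast": contrast,
        "Correlation": correlation,
        "JointEntropy": entropy,
        "InverseDifferenceMoment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Dissimilarity": float((P * np.abs(ii - jj)).sum()),
        "ClusterShade": float((P * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterProminence": float((P * (ii + jj - 2 * mu) ** 4).sum()),
    }
    return pd.Series([values[k] for k in GLCM_FEATURE_NAMES], index=list(GLCM_FEATURE_NAMES))


def _run_zone_features(M: np.ndarray, n_voxels: int, names, percentage_denom: float) -> pd.Series:
    """Shared Galloway-style statistics for run-length and size-zone matrices."""
    total = M.sum()
    if total == 0:
        raise ValueError("empty run/zone matrix")
    g = np.arange(1, M.shape[0] + 1, dtype=float)
    r = np.arange(1, M.shape[1] + 1, dtype=float)
    gg, rr = np.meshgrid(g, r, indexing="ij")
    p = M / total
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mu_g = float((g * pg).sum())
    mu_r = float((r * pr).sum())

    values = {
        names[0]: float((p / rr**2).sum()),  # short emphasis
        names[1]: float((p * rr**2).sum()),  # long emphasis
        names[2]: float((M.sum(axis=1) ** 2).sum() / total),  # gray-level non-uniformity
        names[3]: float((M.sum(axis=0) ** 2).sum() / total),  # length non-uniformity
        names[4]: float(total / percentage_denom),
        names[5]: float((p / gg**2).sum()),
        names[6]: float((p * gg**2).sum()),
        names[7]: float((p / (gg**2 * rr**2)).sum()),
        names[8]: float((p * gg**2 / rr**2).sum()),
        names[9]: float((p * rr**2 / gg**2).sum()),
        names[10]: float((p * rr**2 * gg**2).sum()),
        names[11]: float((p * (gg - mu_g) ** 2).sum()),
        names[12]: float((p * (rr - mu_r) ** 2).sum()),
    }
    return pd.Series([values[k] for k in names], index=list(names))


def glrlm_features(tm: TextureMatrices) -> pd.Series:
    """13 run-length features (counts merged over the 13 directions)."""
    return _run_zone_features(
        tm.glrlm, tm.n_voxels, GLRLM_FEATURE_NAMES, percentage_denom=tm.n_voxels * len(DIRECTIONS_13)
    )


def glszm_features(tm: TextureMatrices) -> pd.Series:
    """13 size-zone features."""
    return _run_zone_features(tm.glszm, tm.n_voxels, GLSZM_FEATURE_NAMES, percentage_denom=tm.n_voxels)


def ngtdm_features(tm: TextureMatrices) -> pd.Series:
    """The 5 Amadasun-King neighborhood gray-tone difference features."""
    n = tm.ngtdm_n
    s = tm.ngtdm_s
    p = tm.ngtdm_p
    occupied = np.flatnonzero(n > 0)
    g = occupied + 1.0
    n_vp = n.sum()
    n_gp = occupied.size

    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, _COARSENESS_CAP) if ps > 0 else _COARSENESS_CAP

    if n_gp > 1:
        pi = p[occupied]
        si = s[occupied]
        gi, gj = np.meshgrid(g, g, indexing="ij")
        pii, pjj = np.meshgrid(pi, pi, indexing="ij")
        contrast = float(
            (pii * pjj * (gi - gj) ** 2).sum() / (n_gp * (n_gp - 1)) * (s.sum() / n_vp)
        )
        denom_busy = float(np.abs(gi * pii - gj * pjj).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            (np.abs(gi - gj) * (pii * si[:, None] + pjj * si[None, :]) / (pii + pjj)).sum() / n_vp
        )
        ssum = s.sum()
        strength = float(((pii + pjj) * (gi - gj) ** 2).sum() / ssum) if ssum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    values = {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
    return pd.Series([values[k] for k in NGTDM_FEATURE_NAMES], index=list(NGTDM_FEATURE_NAMES))


def texture_features(tm: TextureMatrices) -> pd.Series:
    """All 39 texture features, family-prefixed (glcm/glrlm/glszm/ngtdm)."""
    parts = [
        glcm_features(tm).add_prefix("glcm."),
        glrlm_features(tm).add_prefix("glrlm."),
        glszm_features(tm).add_prefix("glszm."),
        ngtdm_features(tm).add_prefix("ngtdm."),
    ]
    return pd.concat(parts)
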