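"""Per-modality and multi-modality feature extraction (528 / 1584 columns).

Feature names follow ``{modality}.{image}.{family}.{name}`` where image is
``original`` or ``wavelet-XXX`` and family one of intensity / shape / glcm
/ glrlm / glszm / ngtdm, e.g. ``T2WI.wavelet-HLH.glrlm.RunLengthNonUniformity``.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import pandas as pd

from ..containers import MODALITIES, FeatureMatrix, MultimodalCase
from .intensity import intensity_features
from .roi import RoiSample, crop_to_mask, discretize
from .shape import shape_features
from .texture import texture_features, texture_matrices
from .wavelet import wavelet_features

#: binding per-family feature counts
N_INTENSITY = 18
N_SHAPE = 15
N_TEXTURE = 39
N_PER_SUBBAND = N_INTENSITY + N_TEXTURE  # 57
N_WAVELET = 8 * N_PER_SUBBAND  # 456
N_PER_MODALITY = N_INTENSITY + N_SHAPE + N_TEXTURE + N_WAVELET  # 528
N_COMBINED = len(MODALITIES) * N_PER_MODALITY  # 1584


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings, recorded alongside every feature CSV."""

    n_bins: int = 32
    wavelet: str = "coif1"
    crop_margin: int = 4

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def extract_modality(
    case: MultimodalCase, modality: str, config: ExtractionConfig | None = None
) -> pd.Series:
    """The 528-feature vector of one modality of one case."""
    config = config or ExtractionConfig()
    if modality not in case.volumes:
        raise KeyError(f"case {case.case_id!r}: modality {modality!r} not present")
    try:
        volume, mask = crop_to_mask(case.volumes[modality], case.mask, config.crop_margin)
        roi = discretize(RoiSample(volume, mask, case.spacing), config.n_bins)
        parts = [
            intensity_features(roi).add_prefix("original.intensity."),
            shape_features(mask, case.spacing).add_prefix("original.shape."),
            texture_features(texture_matrices(roi)).add_prefix("original."),
            wavelet_features(volume, mask, case.spacing, config.wavelet, config.n_bins),
        ]
    except Exception as exc:
        raise RuntimeError(
            f"feature extraction failed for case {case.case_id!r}, modality {modality!r}: {exc}"
        ) from exc
    vec = pd.concat(parts).add_prefix(f"{modality}.")
    assert len(vec) == N_PER_MODALITY, f"expected {N_PER_MODALITY} features, got {len(vec)}"
    return vec


def extract_all(
    cases: Sequence[MultimodalCase],
    config: ExtractionConfig | None = None,
    modalities: Sequence[str] = MODALITIES,
) -> FeatureMatrix:
    """Feature matrix over cases: per-modality blocks concatenated in order.

    With the default three modalities each row has 1584 columns; a
    single-modality run yields 528.
    """
    config = config or ExtractionConfig()
    rows = {}
    labels = {}
    for case in cases:
        vec = pd.concat([extract_modality(case, m, config) for m in modalities])
        rows[case.case_id] = vec
        labels[case.case_id] = case.label
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return FeatureMatrix(frame, pd.Series(labels, name="label"))
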