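"""Shared in-memory containers for the radiomics pipeline.

The pipeline moves data through two containers: :class:`MultimodalCase`
(three co-registered MRI volumes plus a tumor mask, the unit feature
extraction consumes) and :class:`FeatureMatrix` (cases x named features with
per-case labels, the object the selection and classification stages operate
on).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical modality names, in concatenation order
MODALITIES: tuple[str, ...] = ("CE-T1WI", "T2WI", "DWI")

#: label vocabulary for the binary aggressiveness endpoint
AGGRESSIVE = "aggressive"
NON_AGGRESSIVE = "non_aggressive"
LABELS = (NON_AGGRESSIVE, AGGRESSIVE)


@dataclass
class MultimodalCase:
    """One patient: aligned modality volumes, tumor mask, spacing and label.

    All volumes and the mask must share shape; the mask must contain at
    least one foreground voxel. ``spacing`` is millimetres per axis.
    """

    case_id: str
    volumes: Mapping[str, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float]
    label: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if set(self.volumes) != set(MODALITIES):
            raise ValueError(
                f"case {self.case_id!r}: modality names must be exactly "
                f"{set(MODALITIES)}, got {set(self.volumes)}"
            )
        for name, vol in self.volumes.items():
            if np.asarray(vol).shape != self.mask.shape:
                raise ValueError(
                    f"case {self.case_id!r}: volume {name!r} shape "
                    f"{np.asarray(vol).shape} != mask shape {self.mask.shape}"
                )
        if not self.mask.any():
            raise ValueError(f"case {self.case_id!r}: mask has no foreground voxel")
        if self.label not in LABELS:
            raise ValueError(f"case {self.case_id!r}: unknown label {self.label!r}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]


@dataclass
class FeatureMatrix:
    """Cases x named features together with per-case labels.

    ``frame`` is indexed by case id with one column per feature name;
    ``labels`` is aligned on the same index and takes values from
    :data:`LABELS`.
    """

    frame: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.frame.index)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"labels missing for cases: {missing[:5]}")
        if self.frame.columns.duplicated().any():
            dupes = list(self.frame.columns[self.frame.columns.duplicated()])
            raise ValueError(f"duplicate feature names: {dupes[:5]}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_cases(self) -> int:
        return self.frame.shape[0]

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def case_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def encoded_labels(self, positive: str = AGGRESSIVE) -> np.ndarray:
        """Labels encoded as +1 (positive class) / -1."""
        return np.where(self.labels.to_numpy() == positive, 1.0, -1.0)

    # -- subsetting --------------------------------------------------------
    def select_features(self, which: Sequence) -> "FeatureMatrix":
        """Restrict to a subset of features, by name or integer position."""
        which = list(which)
        if which and isinstance(which[0], (int, np.integer)):
            frame = self.frame.iloc[:, which]
        else:
            frame = self.frame.loc[:, which]
        return FeatureMatrix(frame, self.labels)

    def select_cases(self, case_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(case_ids)
        return FeatureMatrix(self.frame.loc[ids], self.labels.loc[ids])

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="case_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="case_id")
        labels = df.pop("label")
        return cls(df, labels)


def concat_feature_matrices(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature matrices over the same cases."""
    if not parts:
        raise ValueError("nothing to concatenate")
    index = parts[0].frame.index
    for p in parts[1:]:
        if not p.frame.index.equals(index):
            raise ValueError("feature matrices do not share the same cases")
        if not p.labels.equals(parts[0].labels):
            raise ValueError("feature matrices disagree on labels")
    frame = pd.concat([p.frame for p in parts], axis=1)
    return FeatureMatrix(frame, parts[0].labels)
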