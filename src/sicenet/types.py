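"""Shared lightweight containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PET = "PET"
GM = "GM"
MODALITIES = (PET, GM)

GROUPS = ("CN", "MCI", "AD")
# clinical severity order, used to orient sensitivity/specificity
SEVERITY = {"CN": 0, "MCI": 1, "AD": 2}


@dataclass
class FeatureMatrix:
    """n subjects x p regions of real-valued features with group labels.

    Rows are subjects (x_i), columns are region features (f_1..f_p) in
    region-id order.
    """

    values: np.ndarray  # (n, p)
    labels: np.ndarray  # (n,) group label per subject
    region_ids: tuple[int, ...]
    modality: str = PET
    subject_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x regions)")
        if self.values.shape[1] != len(self.region_ids):
            raise ValueError("column count does not match region_ids")
        if len(self.region_ids) < 2:
            raise ValueError("need at least 2 regions")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length does not match row count")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if not self.subject_ids:
            self.subject_ids = tuple(f"S{i:04d}" for i in range(self.n))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def group(self, label: str) -> np.ndarray:
        """Rows of subjects with the given group label."""
        return self.values[self.labels == label]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        """Row subset (boolean or index mask), preserving metadata."""
        idx = np.arange(self.n)[mask] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return FeatureMatrix(
            values=self.values[idx],
            labels=self.labels[idx],
            region_ids=self.region_ids,
            modality=self.modality,
            subject_ids=tuple(self.subject_ids[i] for i in idx),
        )
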