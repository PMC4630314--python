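"""Voxel volumes -> region-feature matrix.

PET volumes are first normalised in intensity against the mean
(template) volume so that activation levels are comparable across
subjects; GM tissue-probability volumes are summarised per region as
gray-matter density (fraction of region voxels classified as GM).  A
two-sample pooled-variance t-test preselects discriminative voxels; the
region feature is then the mean intensity over the selected voxels of
the region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import FeatureMatrix, GM, PET


@dataclass
class VoxelSelectionMask:
    """Boolean voxel mask from discriminative preselection.

    ``fit_scope`` records which training split the mask was computed on
    (leakage bookkeeping for cross-validation).
    """

    selected: np.ndarray  # bool, volume shape
    p_threshold: float = 0.01
    fit_scope: str = "all"


def normalize_pet_intensity(volumes: np.ndarray, top_fraction: float = 0.01) -> np.ndarray:
    """Divide every volume by the mean of the brightest voxels of the
    template (the voxelwise mean volume across subjects).

    The brightest set is the top ``ceil(top_fraction * n_voxels)``
    voxels of the template, including every voxel tied with the value at
    the cut, which makes the rule deterministic.  Scale-equivariant:
    scaling all inputs by c > 0 leaves the outputs unchanged.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim < 2 or volumes.shape[0] < 1:
        raise ValueError("need at least one subject volume")
    template = volumes.mean(axis=0)
    flat = np.sort(template.ravel())[::-1]
    k = math.ceil(top_fraction * flat.size)
    cut = flat[k - 1]
    top = flat[flat >= cut]
    normalizer = float(top.mean())
    if normalizer <= 0:
        raise ValueError("degenerate input: nonpositive intensity normalizer")
    return volumes / normalizer


def gm_density(
    gm_volume: np.ndarray,
    label_volume: np.ndarray,
    region_ids: tuple[int, ...],
    gm_threshold: float = 0.5,
) -> np.ndarray:
    """Per-region gray-matter density rho_i = #(GM voxels in region i) /
    #(voxels in region i), a GM voxel being one whose tissue probability
    is >= ``gm_threshold``."""
    gm_volume = np.asarray(gm_volume, dtype=float)
    if gm_volume.shape != label_volume.shape:
        raise ValueError(
            f"shape mismatch: GM volume {gm_volume.shape} vs labels {label_volume.shape}"
        )
    if gm_volume.min() < 0 or gm_volume.max() > 1:
        raise ValueError("GM volume must hold probabilities in [0, 1]")
    rho = np.empty(len(region_ids))
    for k, rid in enumerate(region_ids):
        region = label_volume == rid
        total = int(region.sum())
        if total == 0:
            raise ValueError(f"region {rid} has no voxels in the label volume")
        rho[k] = (gm_volume[region] >= gm_threshold).sum() / total
    return rho


def select_voxels_ttest(
    volumes_a: np.ndarray,
    volumes_b: np.ndarray,
    label_volume: np.ndarray,
    p_threshold: float = 0.01,
    fit_scope: str = "all",
) -> VoxelSelectionMask:
    """Two-sample pooled-variance t-test per labeled voxel; a voxel is
    selected iff its two-sided p-value is below ``p_threshold``.

    Zero-variance voxels with equal group means are never selected.
    """
    volumes_a = np.asarray(volumes_a, dtype=float)
    volumes_b = np.asarray(volumes_b, dtype=float)
    if volumes_a.shape[0] < 2 or volumes_b.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects for a pooled-variance t-test")
    if volumes_a.shape[1:] != label_volume.shape or volumes_b.shape[1:] != label_volume.shape:
        raise ValueError("volumes and label volume shapes differ")
    labeled = label_volume > 0
    a = volumes_a[:, labeled]
    b = volumes_b[:, labeled]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=0, equal_var=True)
    # identical constant voxels give nan -> not selected; constant-but-
    # different voxels give p = 0 -> selected
    sel = np.zeros(label_volume.shape, dtype=bool)
    sel[labeled] = np.nan_to_num(pvals, nan=1.0) < p_threshold
    return VoxelSelectionMask(selected=sel, p_threshold=p_threshold, fit_scope=fit_scope)


def extract_region_features(
    volumes: np.ndarray,
    label_volume: np.ndarray,
    region_ids: tuple[int, ...],
    labels: np.ndarray,
    mask: VoxelSelectionMask | None = None,
    modality: str = PET,
    gm_threshold: float = 0.5,
    subject_ids: tuple[str, ...] = (),
) -> FeatureMatrix:
    """Summarise each subject volume into one feature per region.

    PET: mean voxel value over the region intersected with the selection
    mask, falling back to the whole region when the intersection is
    empty.  GM: gray-matter density (mask ignored).
    """
    volumes = np.asarray(volumes, dtype=float)
    n = volumes.shape[0]
    values = np.empty((n, len(region_ids)))
    if modality == GM:
        for s in range(n):
            values[s] = gm_density(volumes[s], label_volume, region_ids, gm_threshold)
    elif modality == PET:
        for k, rid in enumerate(region_ids):
            region = label_volume == rid
            if not region.any():
                raise ValueError(f"region {rid} has no voxels in the label volume")
            voxels = region & mask.selected if mask is not None else region
            if not voxels.any():
                voxels = region  # documented fallback: whole region
            values[:, k] = volumes[:, voxels].mean(axis=1)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels),
        region_ids=region_ids,
        modality=modality,
        subject_ids=subject_ids,
    )
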