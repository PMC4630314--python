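"""Synthetic ground truth for the connectivity pipeline.

Subjects are drawn from group-specific multivariate Gaussians
N(mu_g, Theta_g^-1) whose precision matrices Theta_g are sparse and
lobe-block structured: conditional dependencies (edges) are far more
likely within a lobe than between lobes, and intra-lobe edges are
stronger.  Group differences are planted by removing or attenuating
edges (and optionally shifting regional means) for the impaired groups
relative to controls, emulating the loss of strong connections the
degenerative process produces.

Toy labeled volumes carry these regional features into voxel space so
that the voxel-level stages (intensity normalisation, t-test
preselection, region-feature extraction) can be exercised without any
imaging data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atlas import LobePartition, aal42_partition
from .types import FeatureMatrix, GROUPS, PET

# (region_i, region_j, scale): multiply the base edge weight by `scale`
# (0 removes the edge entirely)
EdgeEffect = tuple[int, int, float]


@dataclass
class GroundTruth:
    """True group models: precision matrices, means and edge supports."""

    partition: LobePartition
    theta_by_group: dict[str, np.ndarray]
    mu_by_group: dict[str, np.ndarray]
    edge_support: dict[str, frozenset[tuple[int, int]]]

    def __post_init__(self) -> None:
        for g, theta in self.theta_by_group.items():
            theta = np.asarray(theta, dtype=float)
            if not np.allclose(theta, theta.T):
                raise ValueError(f"Theta for {g} is not symmetric")
            if np.linalg.eigvalsh(theta).min() <= 0:
                raise ValueError(f"Theta for {g} is not positive definite")
            self.theta_by_group[g] = theta

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.theta_by_group)

    @property
    def p(self) -> int:
        return self.partition.p


def _support_of(theta: np.ndarray, region_ids: tuple[int, ...]) -> frozenset[tuple[int, int]]:
    p = theta.shape[0]
    pairs = set()
    for i in range(p):
        for j in range(i + 1, p):
            if theta[i, j] != 0.0:
                pairs.add((region_ids[i], region_ids[j]))
    return frozenset(pairs)


def _dominant_diagonal(off: np.ndarray) -> np.ndarray:
    """Diagonal = row absolute off-diagonal sum + 1 (strict diagonal
    dominance, hence strictly positive definite)."""
    theta = off.copy()
    np.fill_diagonal(theta, 0.0)
    np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 1.0)
    return theta


def make_group_precision(
    partition: LobePartition,
    intra_edge_prob: float = 0.3,
    inter_edge_prob: float = 0.02,
    strength_range: tuple[float, float] = (0.2, 0.5),
    group_effects: dict[str, list[EdgeEffect]] | None = None,
    seed: int = 0,
    groups: tuple[str, ...] = GROUPS,
    mean_shifts: dict[str, dict[int, float]] | None = None,
    base_mean: float = 1.0,
) -> GroundTruth:
    """Generate sparse, lobe-block-structured true precision matrices.

    Intra-lobe region pairs receive an edge with probability
    ``intra_edge_prob`` and a weight drawn uniformly from
    ``strength_range`` with random sign; inter-lobe pairs use
    ``inter_edge_prob`` and the weak end of the range, so intra-lobe
    conditional dependencies are both denser and stronger.  Positive
    definiteness is enforced by diagonal dominance.  ``group_effects``
    rescales listed edges per group (scale 0 removes an edge);
    ``mean_shifts`` adds per-region offsets to that group's mean vector.
    Deterministic given ``seed``.
    """
    for name, prob in (("intra_edge_prob", intra_edge_prob), ("inter_edge_prob", inter_edge_prob)):
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {prob}")
    lo, hi = strength_range
    if not (0.0 < lo <= hi):
        raise ValueError("strength_range must be a positive interval")
    p = partition.p
    if p < 2:
        raise ValueError("need at least 2 regions")

    rng = np.random.default_rng(seed)
    ids = partition.region_ids
    base = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            intra = partition.lobe_of[ids[i]] == partition.lobe_of[ids[j]]
            prob = intra_edge_prob if intra else inter_edge_prob
            if rng.random() < prob:
                w = rng.uniform(lo, hi) if intra else lo
                w *= rng.choice((-1.0, 1.0))
                base[i, j] = base[j, i] = w

    group_effects = group_effects or {}
    mean_shifts = mean_shifts or {}
    theta_by_group: dict[str, np.ndarray] = {}
    mu_by_group: dict[str, np.ndarray] = {}
    support: dict[str, frozenset[tuple[int, int]]] = {}
    for g in groups:
        off = base.copy()
        for (ri, rj, scale) in group_effects.get(g, []):
            a, b = partition.index_of(ri), partition.index_of(rj)
            off[a, b] *= scale
            off[b, a] *= scale
        theta = _dominant_diagonal(off)
        mu = np.full(p, float(base_mean))
        for region, delta in mean_shifts.get(g, {}).items():
            mu[partition.index_of(region)] += delta
        theta_by_group[g] = theta
        mu_by_group[g] = mu
        support[g] = _support_of(theta, ids)

    return GroundTruth(
        partition=partition,
        theta_by_group=theta_by_group,
        mu_by_group=mu_by_group,
        edge_support=support,
    )


# Regions whose connectivity and mean level degrade in the default
# scenario: medial/inferior temporal structures (temporal poles,
# fusiform, hippocampus, parahippocampal gyrus).
DEFAULT_AFFECTED_REGIONS: tuple[int, ...] = (33, 34, 37, 38, 39, 40, 41, 42)


def default_scenario(
    seed: int = 0,
    affected_regions: tuple[int, ...] = DEFAULT_AFFECTED_REGIONS,
    ad_edge_scale: float = 0.0,
    mci_edge_scale: float = 0.5,
    ad_mean_shift: float = -1.0,
    mci_mean_shift: float = -0.5,
) -> GroundTruth:
    """Three-group (CN/MCI/AD) ground truth over the 42-region atlas.

    Every edge incident to an affected temporal-lobe region is removed
    for AD and attenuated for MCI — degeneration disconnects these
    regions from the rest of the network — and the affected regions'
    mean levels drop by roughly 1.4 within-group standard deviations for
    AD (half that for MCI), mirroring the strong regional hypometabolism
    the disease produces.  Both the edge-difference and mean-difference
    stages of the pipeline therefore have signal to find.
    """
    partition = aal42_partition()
    # deterministic probe of which edges the base draw creates: replay
    # generation once to learn the support, then build effects
    probe = make_group_precision(partition, seed=seed, groups=("CN",))
    affected = set(affected_regions)
    effects_ad: list[EdgeEffect] = []
    effects_mci: list[EdgeEffect] = []
    for (ri, rj) in sorted(probe.edge_support["CN"]):
        if ri in affected or rj in affected:
            effects_ad.append((ri, rj, ad_edge_scale))
            effects_mci.append((ri, rj, mci_edge_scale))
    return make_group_precision(
        partition,
        group_effects={"AD": effects_ad, "MCI": effects_mci},
        mean_shifts={
            "AD": {r: ad_mean_shift for r in affected_regions},
            "MCI": {r: mci_mean_shift for r in affected_regions},
        },
        seed=seed,
    )


def sample_subjects(truth: GroundTruth, n_per_group: int, seed: int = 0) -> FeatureMatrix:
    """Draw ``n_per_group`` subjects per group from N(mu_g, Theta_g^-1)."""
    if n_per_group < 0:
        raise ValueError("n_per_group must be nonnegative")
    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for g in truth.groups:
        theta = truth.theta_by_group[g]
        if np.linalg.eigvalsh(theta).min() <= 0:
            raise ValueError(f"ground-truth Theta for {g} is not positive definite")
        cov = np.linalg.inv(theta)
        cov = (cov + cov.T) / 2.0
        draws = rng.multivariate_normal(truth.mu_by_group[g], cov, size=n_per_group, method="cholesky")
        blocks.append(draws.reshape(n_per_group, truth.p))
        labels.extend([g] * n_per_group)
    values = np.vstack(blocks) if blocks else np.empty((0, truth.p))
    return FeatureMatrix(
        values=values,
        labels=np.array(labels, dtype=object),
        region_ids=truth.partition.region_ids,
        modality=PET,
    )


@dataclass
class SyntheticVolumeSet:
    """Toy labeled volumes: a shared integer label volume plus one real
    volume per subject."""

    label_volume: np.ndarray  # int, 0 = background
    subject_volumes: np.ndarray  # (n, *label_volume.shape)
    voxel_noise_sd: float
    labels: np.ndarray = field(default=None)  # group label per subject
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subject_volumes.shape[1:] != self.label_volume.shape:
            raise ValueError("subject volumes do not share the label volume's shape")


def make_label_volume(p: int, voxels_per_region: int) -> np.ndarray:
    """Block-grid label volume: region r occupies one contiguous block of
    exactly ``voxels_per_region`` voxels; unused grid cells stay 0."""
    if voxels_per_region < 1:
        raise ValueError("voxels_per_region must be >= 1")
    gx = math.ceil(math.sqrt(p))
    gy = math.ceil(p / gx)
    vol = np.zeros((gx, gy, voxels_per_region), dtype=np.int16)
    for r in range(1, p + 1):
        ix, iy = divmod(r - 1, gy)
        vol[ix, iy, :] = r
    return vol


def render_voxel_images(
    features: FeatureMatrix,
    voxels_per_region: int = 50,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticVolumeSet:
    """Render each subject's regional features into a toy volume: region
    r's voxels equal that subject's feature f_r plus i.i.d. Gaussian
    noise; the label volume is shared across subjects."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    label = make_label_volume(features.p, voxels_per_region)
    rng = np.random.default_rng(seed)
    vols = np.zeros((features.n,) + label.shape)
    for s in range(features.n):
        for k, rid in enumerate(features.region_ids):
            region = label == rid
            vols[s][region] = features.values[s, k]
        if noise_sd > 0:
            vols[s][label > 0] += rng.normal(0.0, noise_sd, size=int((label > 0).sum()))
    return SyntheticVolumeSet(
        label_volume=label,
        subject_volumes=vols,
        voxel_noise_sd=noise_sd,
        labels=features.labels.copy(),
        subject_ids=features.subject_ids,
    )
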