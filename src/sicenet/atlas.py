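"""Region atlas: the 42 AAL regions used for connectivity modelling.

The 42 regions are the subset of the 116-region Automated Anatomical
Labeling (AAL) parcellation most commonly implicated in Alzheimer's
disease, grouped into four lobes: frontal (12 regions), parietal (8),
occipital (6) and temporal (16).  Region ids run 1..42 and index the
rows/columns of every matrix in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FRONTAL = "frontal"
PARIETAL = "parietal"
OCCIPITAL = "occipital"
TEMPORAL = "temporal"

LOBES = (FRONTAL, PARIETAL, OCCIPITAL, TEMPORAL)

# id -> (name, lobe), ids 1..42
_REGIONS: dict[int, tuple[str, str]] = {
    1: ("Frontal_Sup_L", FRONTAL),
    2: ("Frontal_Sup_R", FRONTAL),
    3: ("Frontal_Mid_L", FRONTAL),
    4: ("Frontal_Mid_R", FRONTAL),
    5: ("Frontal_Sup_Medial_L", FRONTAL),
    6: ("Frontal_Sup_Medial_R", FRONTAL),
    7: ("Frontal_Mid_Orb_L", FRONTAL),
    8: ("Frontal_Mid_Orb_R", FRONTAL),
    9: ("Rectus_L", FRONTAL),
    10: ("Rectus_R", FRONTAL),
    11: ("Cingulum_Ant_L", FRONTAL),
    12: ("Cingulum_Ant_R", FRONTAL),
    13: ("Parietal_Sup_L", PARIETAL),
    14: ("Parietal_Sup_R", PARIETAL),
    15: ("Parietal_Inf_L", PARIETAL),
    16: ("Parietal_Inf_R", PARIETAL),
    17: ("Precuneus_L", PARIETAL),
    18: ("Precuneus_R", PARIETAL),
    19: ("Cingulum_Post_L", PARIETAL),
    20: ("Cingulum_Post_R", PARIETAL),
    21: ("Occipital_Sup_L", OCCIPITAL),
    22: ("Occipital_Sup_R", OCCIPITAL),
    23: ("Occipital_Mid_L", OCCIPITAL),
    24: ("Occipital_Mid_R", OCCIPITAL),
    25: ("Occipital_Inf_L", OCCIPITAL),
    26: ("Occipital_Inf_R", OCCIPITAL),
    27: ("Temporal_Sup_L", TEMPORAL),
    28: ("Temporal_Sup_R", TEMPORAL),
    29: ("Temporal_Pole_Sup_L", TEMPORAL),
    30: ("Temporal_Pole_Sup_R", TEMPORAL),
    31: ("Temporal_Mid_L", TEMPORAL),
    32: ("Temporal_Mid_R", TEMPORAL),
    33: ("Temporal_Pole_Mid_L", TEMPORAL),
    34: ("Temporal_Pole_Mid_R", TEMPORAL),
    35: ("Temporal_Inf_L", TEMPORAL),
    36: ("Temporal_Inf_R", TEMPORAL),
    37: ("Fusiform_L", TEMPORAL),
    38: ("Fusiform_R", TEMPORAL),
    39: ("Hippocampus_L", TEMPORAL),
    40: ("Hippocampus_R", TEMPORAL),
    41: ("ParaHippocampal_L", TEMPORAL),
    42: ("ParaHippocampal_R", TEMPORAL),
}


@dataclass(frozen=True)
class LobePartition:
    """Assignment of regions to lobes.

    Parameters
    ----------
    region_ids
        Region ids in matrix column order (1-based).
    region_names
        Text label per region, aligned with ``region_ids``.
    lobe_of
        Map region id -> lobe name.
    """

    region_ids: tuple[int, ...]
    region_names: tuple[str, ...]
    lobe_of: dict[int, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.region_names):
            raise ValueError("region_ids and region_names length mismatch")
        if len(self.region_ids) < 2:
            raise ValueError("a partition needs at least 2 regions")
        missing = [r for r in self.region_ids if r not in self.lobe_of]
        if missing:
            raise ValueError(f"regions without a lobe: {missing}")
        bad = {l for l in self.lobe_of.values()} - set(LOBES)
        if bad:
            raise ValueError(f"unknown lobes: {sorted(bad)}")

    @property
    def p(self) -> int:
        return len(self.region_ids)

    def lobe_members(self, lobe: str) -> list[int]:
        """Region ids belonging to ``lobe``."""
        return [r for r in self.region_ids if self.lobe_of[r] == lobe]

    def index_of(self, region_id: int) -> int:
        """0-based matrix index of a region id."""
        return self.region_ids.index(region_id)

    def lobe_sizes(self) -> dict[str, int]:
        return {l: len(self.lobe_members(l)) for l in LOBES}


def aal42_partition() -> LobePartition:
    """The standard 42-region partition (frontal 12, parietal 8, occipital 6,
    temporal 16)."""
    ids = tuple(sorted(_REGIONS))
    return LobePartition(
        region_ids=ids,
        region_names=tuple(_REGIONS[r][0] for r in ids),
        lobe_of={r: _REGIONS[r][1] for r in ids},
    )


def toy_partition(p: int, seed: int | None = None) -> LobePartition:
    """A small partition for tests/simulations: ``p`` regions split over the
    four lobes as evenly as possible (first lobes get the remainder)."""
    if p < 2:
        raise ValueError("p must be >= 2")
    base, extra = divmod(p, len(LOBES))
    sizes = [base + (1 if i < extra else 0) for i in range(len(LOBES))]
    lobe_of: dict[int, str] = {}
    rid = 1
    for lobe, size in zip(LOBES, sizes):
        for _ in range(size):
            lobe_of[rid] = lobe
            rid += 1
    ids = tuple(range(1, p + 1))
    return LobePartition(
        region_ids=ids,
        region_names=tuple(f"Region_{r:02d}" for r in ids),
        lobe_of=lobe_of,
    )
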