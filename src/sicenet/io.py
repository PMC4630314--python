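"""Readers and writers for the pipeline's interchange formats.

Volumes are NIfTI (via nibabel); tabular interchange is TSV with a
header row; matrices carry region-id headers; networks are written as
edge-list TSV and GraphML; ground truth and configuration as JSON.
Atlas label volumes round-trip exactly as integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import LobePartition
from .sice import BinarizedNetwork, CumulativeNetwork
from .synthetic import GroundTruth
from .types import FeatureMatrix, GROUPS, MODALITIES

MANIFEST_COLUMNS = ("subject_id", "group", "modality", "path")


@dataclass
class Manifest:
    """Validated subject manifest (one row per subject x modality)."""

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self, modality: str | None = None) -> pd.DataFrame:
        f = self.frame
        return f[f["modality"] == modality] if modality else f


def write_volume(path: Path | str, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        img = nib.Nifti1Image(np.asarray(data, dtype=np.int16), affine)
    else:
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (array, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as err:  # malformed file
        raise ValueError(f"cannot parse NIfTI volume {path}: {err}") from err
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.integer):
        return np.asarray(data), img.affine
    return np.asarray(data, dtype=float), img.affine


def check_shapes(subject: np.ndarray, atlas: np.ndarray) -> None:
    if subject.shape != atlas.shape:
        raise ValueError(
            f"shape mismatch: subject volume {subject.shape} vs atlas {atlas.shape}"
        )


def load_manifest(path: Path | str, allowed_groups: tuple[str, ...] = GROUPS) -> Manifest:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest misses columns {sorted(missing)}")
    for i, row in frame.iterrows():
        if row["group"] not in allowed_groups:
            raise ValueError(
                f"manifest row {i}: unknown group {row['group']!r}; allowed: {allowed_groups}"
            )
        if row["modality"] not in MODALITIES:
            raise ValueError(
                f"manifest row {i}: unknown modality {row['modality']!r}; allowed: {MODALITIES}"
            )
        if not Path(row["path"]).exists():
            raise ValueError(f"manifest row {i}: path does not exist: {row['path']}")
    dup = frame.duplicated(subset=["subject_id", "modality"])
    if dup.any():
        first = frame[dup].iloc[0]
        raise ValueError(
            f"duplicate (subject, modality) in manifest: ({first['subject_id']}, {first['modality']})"
        )
    return Manifest(frame=frame)


def write_manifest(path: Path | str, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_features(path: Path | str, features: FeatureMatrix) -> None:
    df = pd.DataFrame(features.values, columns=[str(r) for r in features.region_ids])
    df.insert(0, "subject_id", list(features.subject_ids))
    df.insert(1, "group", features.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_features(path: Path | str, modality: str = "PET") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    region_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    return FeatureMatrix(
        values=df[region_cols].to_numpy(float),
        labels=df["group"].to_numpy(),
        region_ids=tuple(int(c) for c in region_cols),
        modality=modality,
        subject_ids=tuple(df["subject_id"].astype(str)),
    )


def write_matrix(path: Path | str, matrix: np.ndarray, region_ids: tuple[int, ...]) -> None:
    pd.DataFrame(matrix, columns=[str(r) for r in region_ids]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_matrix(path: Path | str) -> tuple[np.ndarray, tuple[int, ...]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float), tuple(int(c) for c in df.columns)


def network_to_graph(network: BinarizedNetwork) -> nx.Graph:
    g = nx.Graph()
    part = network.partition
    for rid, name in zip(part.region_ids, part.region_names):
        g.add_node(rid, name=name, lobe=part.lobe_of[rid])
    s = network.strengths
    for (ri, rj) in network.arc_list():
        i, j = part.index_of(ri), part.index_of(rj)
        attrs = {"strength": float(s[i, j])} if s is not None else {}
        g.add_edge(ri, rj, **attrs)
    return g


def write_network(path_prefix: Path | str, network: BinarizedNetwork, quantized: list[tuple[int, int, int]] | None = None) -> None:
    """Write edge-list TSV and GraphML for one binarized network."""
    prefix = Path(path_prefix)
    g = network_to_graph(network)
    if quantized:
        for (ri, rj, level) in quantized:
            if g.has_edge(ri, rj):
                g.edges[ri, rj]["level"] = level
    rows = [
        {"region_i": ri, "region_j": rj, **{k: v for k, v in d.items()}}
        for ri, rj, d in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    nx.write_graphml(g, prefix.with_suffix(".graphml"))


def write_ground_truth(path: Path | str, truth: GroundTruth) -> None:
    payload = {
        "region_ids": list(truth.partition.region_ids),
        "groups": list(truth.groups),
        "theta_by_group": {g: truth.theta_by_group[g].tolist() for g in truth.groups},
        "mu_by_group": {g: truth.mu_by_group[g].tolist() for g in truth.groups},
        "edge_support": {g: sorted(map(list, truth.edge_support[g])) for g in truth.groups},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_json(path: Path | str, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
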