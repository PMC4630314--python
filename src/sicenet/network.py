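"""Graph analysis of binarized connectivity networks.

Two small-world-oriented metrics are computed for binary undirected
graphs: the average clustering coefficient

    C = (1/n) sum_i C_i,   C_i = 2 t_i / (k_i (k_i - 1)),

with t_i the number of triangles around node i (C_i = 0 when k_i < 2),
and the average number of connections per hub

    E = (1/n) sum_i E_i,   E_i = sum_j a_ij k_j,

which sums the degrees of each node's neighbours.  Alongside these the
module provides cluster/hub extraction, lobe-block connection
accounting, a fold-wise matrix-difference measure, and uniform strength
quantization for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .atlas import LOBES, LobePartition
from .sice import BinarizedNetwork, CumulativeNetwork, PrecisionEstimate

ALL = "all"
NON_ISOLATED = "non_isolated"


@dataclass
class NetworkMetrics:
    """Per-node and aggregate graph metrics for one binary network."""

    degrees: np.ndarray
    triangles: np.ndarray
    node_clustering: np.ndarray
    avg_clustering: float
    node_connections: np.ndarray
    avg_connections_per_hub: float
    clusters: list[list[int]] = field(default_factory=list)  # region ids
    hubs: list[int] = field(default_factory=list)  # region ids


@dataclass
class LobeConnectionStats:
    """Lobe-block shares of matrix cells and of realized arcs.

    Cell accounting covers all p*p cells of the full (symmetric) matrix,
    diagonal included; with the 42-region atlas the inter-lobe share is
    1264/1764 and the occipital block 36/1764.  Printed percentages are
    truncated to whole numbers; exact fractions are kept alongside.
    """

    block_cell_share: dict[tuple[str, str], float]
    block_arc_share: dict[tuple[str, str], float]
    intra_share: float
    inter_share: float
    intra_arc_share: float
    inter_arc_share: float

    @staticmethod
    def printed(share: float) -> int:
        """Truncate a percentage for report output."""
        return int(share)


def _scoped_mean(values: np.ndarray, degrees: np.ndarray, node_scope: str) -> float:
    if node_scope == ALL:
        return float(values.mean()) if values.size else 0.0
    if node_scope == NON_ISOLATED:
        keep = degrees > 0
        return float(values[keep].mean()) if keep.any() else 0.0
    raise ValueError(f"unknown node_scope {node_scope!r}")


def clustering_coefficient(network: BinarizedNetwork, node_scope: str = ALL) -> NetworkMetrics:
    """Node and average clustering coefficients from triangle counts."""
    a = network.adjacency.astype(float)
    k = a.sum(axis=1)
    t = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    metrics = connections_per_hub(network, node_scope)
    metrics.triangles = t
    metrics.node_clustering = c
    metrics.avg_clustering = _scoped_mean(c, k, node_scope)
    return metrics


def connections_per_hub(network: BinarizedNetwork, node_scope: str = ALL) -> NetworkMetrics:
    """E_i = sum_j a_ij k_j (total degree of node i's neighbours)."""
    a = network.adjacency.astype(float)
    k = a.sum(axis=1)
    e = a @ k
    return NetworkMetrics(
        degrees=k.astype(int),
        triangles=np.zeros_like(k),
        node_clustering=np.zeros_like(k),
        avg_clustering=0.0,
        node_connections=e,
        avg_connections_per_hub=_scoped_mean(e, k, node_scope),
    )


def find_clusters_and_hubs(network: BinarizedNetwork, hub_top_k: int = 3) -> NetworkMetrics:
    """Connected components with >= 2 nodes (isolated nodes excluded)
    and the highest-degree nodes (ties at the cut included)."""
    metrics = clustering_coefficient(network, node_scope=NON_ISOLATED)
    ids = network.partition.region_ids
    n_comp, comp = connected_components(network.adjacency, directed=False)
    clusters: list[list[int]] = []
    for c in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(comp == c)]
        if len(members) >= 2:
            clusters.append(members)
    clusters.sort(key=lambda m: (-len(m), m))
    k = metrics.degrees
    order = sorted(range(len(ids)), key=lambda i: (-k[i], i))
    top_k = min(hub_top_k, len(order))
    cutoff = k[order[top_k - 1]]
    hubs = [ids[i] for i in order if k[i] >= cutoff and k[i] > 0]
    metrics.clusters = clusters
    metrics.hubs = hubs
    return metrics


def lobe_connection_stats(
    partition: LobePartition, network: BinarizedNetwork | None = None
) -> LobeConnectionStats:
    """Share of matrix cells and of realized arcs per lobe-pair block.

    Cell shares depend only on the partition (full p*p matrix, diagonal
    included); arc shares require a network and count each arc once in
    its unordered lobe-pair block.
    """
    sizes = partition.lobe_sizes()
    p = partition.p
    total_cells = p * p
    cell_share: dict[tuple[str, str], float] = {}
    for la, lb in combinations_with_replacement(LOBES, 2):
        cells = sizes[la] ** 2 if la == lb else 2 * sizes[la] * sizes[lb]
        cell_share[(la, lb)] = 100.0 * cells / total_cells
    intra = sum(v for (la, lb), v in cell_share.items() if la == lb)
    inter = sum(v for (la, lb), v in cell_share.items() if la != lb)

    arc_share: dict[tuple[str, str], float] = {pair: 0.0 for pair in cell_share}
    intra_arc = inter_arc = 0.0
    if network is not None and network.arcs > 0:
        counts: dict[tuple[str, str], int] = {pair: 0 for pair in cell_share}
        for (ri, rj) in network.arc_list():
            la, lb = sorted((partition.lobe_of[ri], partition.lobe_of[rj]), key=LOBES.index)
            counts[(la, lb)] += 1
        total = network.arcs
        arc_share = {pair: 100.0 * c / total for pair, c in counts.items()}
        intra_arc = sum(v for (la, lb), v in arc_share.items() if la == lb)
        inter_arc = sum(v for (la, lb), v in arc_share.items() if la != lb)

    return LobeConnectionStats(
        block_cell_share=cell_share,
        block_arc_share=arc_share,
        intra_share=intra,
        inter_share=inter,
        intra_arc_share=intra_arc,
        inter_arc_share=inter_arc,
    )


def matrix_difference_measure(
    fold_matrices_a: np.ndarray,
    fold_matrices_b: np.ndarray,
    alpha: float = 0.05,
) -> float:
    """Percentage of lower-triangular entries whose absolute values
    differ between two fold collections at significance ``alpha``.

    Each collection holds one connectivity matrix per cross-validation
    fold; per off-diagonal entry a two-sample t-test compares the
    absolute entry values across folds.  Zero-variance equal-mean
    entries count as not different.
    """
    a = np.asarray(fold_matrices_a, dtype=float)
    b = np.asarray(fold_matrices_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("collections must be stacks of equally-shaped matrices")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 matrices (folds) per collection")
    p = a.shape[1]
    rows, cols = np.tril_indices(p, k=-1)
    va = np.abs(a[:, rows, cols])
    vb = np.abs(b[:, rows, cols])
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(va, vb, axis=0, equal_var=True)
    n_diff = int((np.nan_to_num(pvals, nan=1.0) < alpha).sum())
    return 100.0 * n_diff / len(rows)


def quantize_strengths(
    network: CumulativeNetwork | PrecisionEstimate | BinarizedNetwork,
    levels: int = 10,
    partition: LobePartition | None = None,
) -> list[tuple[int, int, int]]:
    """Uniformly quantize arc strengths onto integer levels 1..``levels``.

    level = 1 + floor((levels-1) * (s - min)/(max - min)), with the
    maximum clamped to ``levels``; when all strengths are equal every
    arc maps to the top level.
    Returns (region_i, region_j, level) tuples, i < j.
    """
    if isinstance(network, CumulativeNetwork):
        strength, partition = network.theta_c, network.partition
    elif isinstance(network, BinarizedNetwork):
        if network.strengths is None:
            raise ValueError("binarized network carries no strengths")
        strength, partition = network.strengths, network.partition
    elif isinstance(network, PrecisionEstimate):
        if partition is None:
            raise ValueError("a partition is required to quantize a raw estimate")
        strength = np.abs(network.theta_hat.copy())
        np.fill_diagonal(strength, 0.0)
        strength[strength <= network.zero_tol] = 0.0
    else:
        raise TypeError("expected a CumulativeNetwork, BinarizedNetwork or PrecisionEstimate")
    strength = np.abs(np.asarray(strength, dtype=float))
    p = strength.shape[0]
    ids = partition.region_ids
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p) if strength[i, j] > 0]
    if not pairs:
        raise ValueError("network has no arcs to quantize")
    vals = np.array([strength[i, j] for (i, j) in pairs])
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        lv = np.full(len(pairs), levels, dtype=int)
    else:
        lv = 1 + np.floor((levels - 1) * (vals - lo) / (hi - lo)).astype(int)
        lv[vals == hi] = levels
    return [(ids[i], ids[j], int(l)) for (i, j), l in zip(pairs, lv)]
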