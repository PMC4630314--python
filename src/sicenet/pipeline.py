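"""End-to-end orchestration of the connectivity analysis.

The flow mirrors the two-part design of the method: an exploratory part
(features -> per-group sparse precision at several arc levels ->
networks, graph metrics, lobe statistics, fold-wise difference measure,
cumulative network) and a discriminative part (per-class regression
residuals -> linear SVM -> cross-validated metrics and region ranking).
Every run writes a self-describing artifact directory containing the
serialized configuration actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .atlas import aal42_partition
from .classify import cross_validate
from .network import (
    clustering_coefficient,
    find_clusters_and_hubs,
    lobe_connection_stats,
    matrix_difference_measure,
    quantize_strengths,
)
from .preprocess import extract_region_features, normalize_pet_intensity, select_voxels_ttest
from .sice import (
    DEFAULT_ARC_LEVELS,
    binarize,
    empirical_covariance,
    sweep_lambda_to_arcs,
)
from .synthetic import default_scenario, render_voxel_images, sample_subjects
from .types import FeatureMatrix, PET

log = logging.getLogger("sicenet")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, serialized with every artifact set."""

    class_pair: tuple[str, str] = ("CN", "AD")
    modalities: tuple[str, ...] = (PET,)
    arc_levels: tuple[int, ...] = DEFAULT_ARC_LEVELS
    target_arcs: int = 100
    zero_tol: float = 1e-8
    p_threshold: float = 0.01
    alpha: float = 0.05
    k: int = 10
    seed: int = 17
    gm_threshold: float = 0.5
    soft_margin: float = 1.0
    # synthetic-mode knobs
    n_per_group: int = 60
    voxels_per_region: int = 30
    noise_sd: float = 0.05

    def validate(self, class_counts: dict[str, int] | None = None) -> None:
        if not (0 < self.p_threshold < 1 and 0 < self.alpha < 1):
            raise ValueError("significance levels must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.target_arcs < 0:
            raise ValueError("target_arcs must be nonnegative")
        if class_counts is not None and min(class_counts.values()) < self.k:
            raise ValueError(
                f"class counts {class_counts} smaller than k={self.k}"
            )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def synthetic_features(config: PipelineConfig, out_dir: Path | None = None) -> FeatureMatrix:
    """Generate the synthetic study: ground truth, subject samples, toy
    volumes, then run the voxel stages (intensity normalisation, t-test
    preselection, region extraction) to recover the feature matrix.

    When ``out_dir`` is given, volumes, manifest and ground truth are
    written there in their interchange formats.
    """
    truth = default_scenario(seed=config.seed)
    features = sample_subjects(truth, config.n_per_group, seed=config.seed + 1)
    volumes = render_voxel_images(
        features, voxels_per_region=config.voxels_per_region,
        noise_sd=config.noise_sd, seed=config.seed + 2,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vol_dir = out_dir / "volumes"
        vol_dir.mkdir(exist_ok=True)
        sio.write_volume(vol_dir / "atlas_labels.nii.gz", volumes.label_volume)
        rows = []
        for i, sid in enumerate(volumes.subject_ids):
            p = vol_dir / f"{sid}_pet.nii.gz"
            sio.write_volume(p, volumes.subject_volumes[i])
            rows.append({"subject_id": sid, "group": volumes.labels[i], "modality": "PET", "path": str(p)})
        sio.write_manifest(out_dir / "manifest.tsv", rows)
        sio.write_ground_truth(out_dir / "ground_truth.json", truth)

    normalized = normalize_pet_intensity(volumes.subject_volumes)
    a, b = config.class_pair
    mask = select_voxels_ttest(
        normalized[volumes.labels == a],
        normalized[volumes.labels == b],
        volumes.label_volume,
        p_threshold=config.p_threshold,
    )
    return extract_region_features(
        normalized,
        volumes.label_volume,
        features.region_ids,
        volumes.labels,
        mask=mask,
        modality=PET,
        subject_ids=volumes.subject_ids,
    )


def run_pipeline(config: PipelineConfig, features: FeatureMatrix | None = None, out_dir: Path | str = "artifacts") -> Path:
    """Run the full exploratory + discriminative analysis and write all
    artifacts under ``out_dir``.  With no features given, the synthetic
    study conditions are generated first."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    partition = aal42_partition()

    if features is None:
        features = synthetic_features(config, out_dir=out_dir)
    counts = {g: int((features.labels == g).sum()) for g in config.class_pair}
    config.validate(class_counts=counts)
    stage = "configuration"
    try:
        stage = "features"
        sio.write_features(out_dir / "features.tsv", features)

        stage = "exploratory SICE"
        part = partition if features.p == partition.p else None
        if part is None:
            from .atlas import toy_partition

            part = toy_partition(features.p)
        realized: dict[str, dict[int, int]] = {}
        metric_rows = []
        for g in config.class_pair:
            cov = empirical_covariance(features.group(g))
            realized[g] = {}
            cum_theta = np.zeros((part.p, part.p))
            for n_arcs in config.arc_levels:
                est = sweep_lambda_to_arcs(cov, n_arcs, zero_tol=config.zero_tol)
                net = binarize(est, part)
                realized[g][n_arcs] = net.arcs
                log.info("group %s: target %d arcs -> lambda %.5g, realized %d", g, n_arcs, est.lam, net.arcs)
                quant = quantize_strengths(net) if net.arcs else None
                sio.write_network(out_dir / f"network_{g}_{n_arcs}arcs", net, quantized=quant)
                cum_theta += (10.0 / n_arcs) * net.adjacency
                m = clustering_coefficient(net, node_scope="all")
                ch = find_clusters_and_hubs(net)
                stats = lobe_connection_stats(part, net)
                metric_rows.append(
                    {
                        "group": g,
                        "arcs": n_arcs,
                        "realized_arcs": net.arcs,
                        "avg_clustering": m.avg_clustering,
                        "avg_connections_per_hub": m.avg_connections_per_hub,
                        "n_clusters": len(ch.clusters),
                        "intra_lobe_arc_pct": stats.intra_arc_share,
                        "inter_lobe_arc_pct": stats.inter_arc_share,
                    }
                )
            sio.write_matrix(out_dir / f"cumulative_{g}.tsv", cum_theta, part.region_ids)

        stage = "network metrics"
        import pandas as pd

        pd.DataFrame(metric_rows).to_csv(out_dir / "network_metrics.tsv", sep="\t", index=False)

        stage = "fold-wise difference measure"
        rng = np.random.default_rng(config.seed + 3)
        fold_mats = {}
        for g in config.class_pair:
            rows = features.group(g)
            order = rng.permutation(rows.shape[0])
            folds = np.array_split(order, config.k)
            mats = []
            for f in range(config.k):
                tr = np.concatenate([folds[j] for j in range(config.k) if j != f])
                cov = empirical_covariance(rows[tr])
                est = sweep_lambda_to_arcs(cov, config.target_arcs, zero_tol=config.zero_tol)
                mats.append(est.theta_hat)
            fold_mats[g] = np.stack(mats)
        a, b = config.class_pair
        diff_pct = matrix_difference_measure(fold_mats[a], fold_mats[b], alpha=config.alpha)

        stage = "cross-validated classification"
        report = cross_validate(
            features,
            config.class_pair,
            target_arcs=config.target_arcs,
            k=config.k,
            seed=config.seed,
            soft_margin=config.soft_margin,
        )
        fold_rows = [dict(fold=i, **f) for i, f in enumerate(report.per_fold)]
        pd.DataFrame(fold_rows).to_csv(out_dir / "cv_folds.tsv", sep="\t", index=False)
        ranking = report.region_ranking
        rank_rows = [
            {
                "region_id": rid,
                "region_name": part.region_names[part.index_of(rid)] if rid in part.region_ids else str(rid),
                "combined_weight": float(ranking.combined_weights[i]),
                "rescaled": float(ranking.rescaled[i]),
            }
            for i, rid in enumerate(ranking.region_ids)
        ]
        pd.DataFrame(rank_rows).to_csv(out_dir / "region_ranking.tsv", sep="\t", index=False)

        summary = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "class_pair": list(config.class_pair),
            "realized_arcs": realized,
            "difference_measure_pct": diff_pct,
            "accuracy": report.accuracy,
            "accuracy_sd": report.accuracy_sd,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "auc": report.auc,
        }
        sio.write_json(out_dir / "summary.json", summary)
        sio.write_json(out_dir / "config.json", {**asdict(config), "hash": config.config_hash()})
    except Exception as err:
        sio.write_json(out_dir / "failure.json", {"stage": stage, "error": str(err)})
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {err}") from err
    return out_dir
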