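"""Discriminative stage: residual features, linear SVM, CV evaluation.

For each class the estimated precision matrix induces multiple-regression
coefficients

    beta_ij = -Theta_ij / Theta_ii   (beta_ii = 0),

the best linear prediction of region i's feature from all other
regions under that class's Gaussian model.  The residual

    eps_i = f_i - sum_{j != i} beta_ij f_j

has variance 1/Theta_ii when x is drawn from the model.  A subject's
residual vectors under the two class models are concatenated (class A
regions 1..p, then class B regions 1..p; 2*42 = 84 features on the
standard atlas) and fed to a linear soft-margin SVM: residuals are
systematically smaller under the subject's own class model, which makes
the concatenation discriminative.  The SVM's primal weight vector —
recoverable from the dual as W = sum_j y_j lambda_j x_j — ranks regions
by discriminative relevance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .sice import (
    PrecisionEstimate,
    empirical_covariance,
    sweep_lambda_to_arcs,
)
from .types import FeatureMatrix, SEVERITY


@dataclass
class ClassModels:
    """Per-class regression coefficient matrices (rows regress feature i
    on the remaining features)."""

    beta_by_class: dict[str, np.ndarray]
    class_order: tuple[str, str]
    source_arc_count: int = 0


@dataclass
class ResidualFeatures:
    """Reconstruction errors under each class model, plus their
    concatenation (class A residuals then class B residuals)."""

    residuals_by_class: dict[str, np.ndarray]  # class -> (n, p)
    concatenated: np.ndarray  # (n, 2p)
    class_order: tuple[str, str]
    labels: np.ndarray


@dataclass
class TrainedClassifier:
    """Linear maximal-margin classifier with dual support information."""

    weight_vector: np.ndarray  # primal W, length = feature dim
    bias: float
    support_vectors: np.ndarray
    dual_signed_alphas: np.ndarray  # y_j * lambda_j per support vector
    classes: tuple[str, str]  # (negative, positive)
    regularization: float
    model: SVC = field(repr=False, default=None)

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weight_vector + self.bias

    def dual_weight_vector(self) -> np.ndarray:
        """W = sum_j y_j lambda_j x_j reconstructed from the support set."""
        return self.dual_signed_alphas @ self.support_vectors


@dataclass
class EvaluationReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: list[dict[str, float]]
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    auc: float
    fold_assignments: np.ndarray  # fold index per subject
    positive_class: str = ""
    region_ranking: "RegionRanking | None" = None


@dataclass
class RegionRanking:
    """Per-region SVM-weight relevance, rescaled to [1, p]."""

    region_ids: tuple[int, ...]
    combined_weights: np.ndarray
    rescaled: np.ndarray

    def top(self, k: int) -> list[int]:
        order = np.argsort(-self.rescaled, kind="stable")
        return [self.region_ids[i] for i in order[:k]]


def regression_coefficients(estimate: PrecisionEstimate | np.ndarray) -> np.ndarray:
    """beta_ij = -Theta_ij / Theta_ii for i != j; beta_ii = 0."""
    theta = estimate.theta_hat if isinstance(estimate, PrecisionEstimate) else np.asarray(estimate, float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision estimate has a nonpositive diagonal")
    beta = -theta / d[:, None]
    np.fill_diagonal(beta, 0.0)
    return beta


def class_models(
    features: FeatureMatrix,
    class_pair: tuple[str, str],
    target_arcs: int = 100,
    lam_bounds: tuple[float, float] | None = None,
) -> ClassModels:
    """Fit one sparse precision matrix per class (independently, on that
    class's subjects only) at a matched arc count, then derive beta."""
    betas: dict[str, np.ndarray] = {}
    for g in class_pair:
        rows = features.group(g)
        if rows.shape[0] < 2:
            raise ValueError(f"class {g} needs >= 2 subjects")
        cov = empirical_covariance(rows)
        est = sweep_lambda_to_arcs(cov, target_arcs, lam_bounds=lam_bounds)
        betas[g] = regression_coefficients(est)
    return ClassModels(beta_by_class=betas, class_order=tuple(class_pair), source_arc_count=target_arcs)


def reconstruction_errors(features: FeatureMatrix, models: ClassModels) -> ResidualFeatures:
    """eps = f - beta f per subject under each class model, concatenated
    in class order."""
    x = features.values
    res: dict[str, np.ndarray] = {}
    for g in models.class_order:
        beta = models.beta_by_class[g]
        if beta.shape != (features.p, features.p):
            raise ValueError("beta dimension does not match features")
        res[g] = x - x @ beta.T
    concat = np.hstack([res[g] for g in models.class_order])
    return ResidualFeatures(
        residuals_by_class=res,
        concatenated=concat,
        class_order=models.class_order,
        labels=features.labels.copy(),
    )


def _orient_pair(class_pair: tuple[str, str]) -> tuple[str, str]:
    """(negative, positive) with the clinically worse group positive."""
    a, b = class_pair
    if SEVERITY.get(a, 0) <= SEVERITY.get(b, 1):
        return a, b
    return b, a


def train_svm(
    x: np.ndarray,
    labels: np.ndarray,
    class_pair: tuple[str, str],
    soft_margin: float = 1.0,
) -> TrainedClassifier:
    """Linear soft-margin SVM; the clinically worse class is coded +1."""
    neg, pos = _orient_pair(class_pair)
    keep = np.isin(labels, list(class_pair))
    x = np.asarray(x, float)[keep]
    y = np.where(labels[keep] == pos, 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(kernel="linear", C=soft_margin)
    svc.fit(x, y)
    w = svc.coef_.ravel().copy()
    return TrainedClassifier(
        weight_vector=w,
        bias=float(svc.intercept_[0]),
        support_vectors=svc.support_vectors_.copy(),
        dual_signed_alphas=svc.dual_coef_.ravel().copy(),
        classes=(neg, pos),
        regularization=soft_margin,
        model=svc,
    )


def evaluate_metrics(
    scores: np.ndarray,
    truth: np.ndarray,
    positive: str,
    threshold: float = 0.0,
) -> dict[str, float]:
    """Accuracy/sensitivity/specificity at the decision threshold, plus
    trapezoidal AUC (nan when only one class is present)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    is_pos = truth == positive
    pred_pos = scores > threshold
    tp = int((pred_pos & is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    total = len(truth)
    out = {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
    if is_pos.all() or (~is_pos).all():
        out["auc"] = float("nan")
    else:
        out["auc"] = float(roc_auc_score(is_pos.astype(int), scores))
    return out


def rank_regions(classifier: TrainedClassifier, p: int, region_ids: tuple[int, ...] | None = None) -> RegionRanking:
    """Combine the SVM weights of the two class slots per region
    (W_i + W_{i+p}) and rescale affinely onto [1, p]."""
    w = classifier.weight_vector
    if len(w) != 2 * p:
        raise ValueError(f"weight vector length {len(w)} != 2p = {2 * p}")
    combined = w[:p] + w[p:]
    mag = np.abs(combined)
    lo, hi = mag.min(), mag.max()
    if hi == lo:
        rescaled = np.ones(p)
    else:
        rescaled = 1.0 + (p - 1.0) * (mag - lo) / (hi - lo)
    ids = region_ids if region_ids is not None else tuple(range(1, p + 1))
    return RegionRanking(region_ids=tuple(ids), combined_weights=combined, rescaled=rescaled)


def cross_validate(
    features: FeatureMatrix | list[FeatureMatrix],
    class_pair: tuple[str, str],
    target_arcs: int = 100,
    k: int = 10,
    seed: int = 0,
    soft_margin: float = 1.0,
    feature_builder=None,
) -> EvaluationReport:
    """Stratified k-fold evaluation of the full discriminative pipeline.

    Within each training split only: per-class precision matrices (with
    the lambda sweep to ``target_arcs``), regression coefficients and
    the SVM are fit; the held-out fold is transformed with those
    training artifacts and scored.  When several modalities are given
    their residual vectors are concatenated before the SVM.

    ``feature_builder(train_idx, test_idx)``, if given, must return
    (train FeatureMatrix list, test FeatureMatrix list); it is the hook
    through which voxel-level preselection is fit on the training split
    only.
    """
    mats = features if isinstance(features, list) else [features]
    labels = mats[0].labels
    keep = np.isin(labels, list(class_pair))
    idx_all = np.flatnonzero(keep)
    labels_pair = labels[idx_all]
    neg, pos = _orient_pair(class_pair)
    counts = {g: int((labels_pair == g).sum()) for g in class_pair}
    if min(counts.values()) < k:
        raise ValueError(
            f"class counts {counts} are smaller than k={k}; lower k or add subjects"
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assign = np.full(len(labels), -1, dtype=int)
    per_fold: list[dict[str, float]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    for fold, (tr, te) in enumerate(skf.split(idx_all, labels_pair)):
        tr_idx, te_idx = idx_all[tr], idx_all[te]
        fold_assign[te_idx] = fold
        if feature_builder is not None:
            train_mats, test_mats = feature_builder(tr_idx, te_idx)
        else:
            train_mats = [m.subset(tr_idx) for m in mats]
            test_mats = [m.subset(te_idx) for m in mats]
        train_blocks, test_blocks = [], []
        for m_tr, m_te in zip(train_mats, test_mats):
            models = class_models(m_tr, class_pair, target_arcs=target_arcs)
            train_blocks.append(reconstruction_errors(m_tr, models).concatenated)
            test_blocks.append(reconstruction_errors(m_te, models).concatenated)
        x_tr = np.hstack(train_blocks)
        x_te = np.hstack(test_blocks)
        clf = train_svm(x_tr, train_mats[0].labels, class_pair, soft_margin=soft_margin)
        scores = clf.decision_scores(x_te)
        truth = test_mats[0].labels
        per_fold.append(evaluate_metrics(scores, truth, positive=pos))
        pooled_scores.append(scores)
        pooled_truth.append(truth)

    def agg(key: str) -> tuple[float, float]:
        vals = np.array([f[key] for f in per_fold])
        vals = vals[~np.isnan(vals)]
        return (float(vals.mean()), float(vals.std())) if vals.size else (float("nan"), float("nan"))

    acc, acc_sd = agg("accuracy")
    sen, sen_sd = agg("sensitivity")
    spe, spe_sd = agg("specificity")
    all_scores = np.concatenate(pooled_scores)
    all_truth = np.concatenate(pooled_truth)
    auc = float(roc_auc_score((all_truth == pos).astype(int), all_scores))

    # region ranking from a model refit on all pair subjects (reporting
    # artifact; CV metrics above never see this fit)
    full = [m.subset(idx_all) for m in mats]
    models = class_models(full[0], class_pair, target_arcs=target_arcs)
    res = reconstruction_errors(full[0], models)
    clf_full = train_svm(res.concatenated, full[0].labels, class_pair, soft_margin=soft_margin)
    ranking = rank_regions(clf_full, full[0].p, region_ids=full[0].region_ids)

    return EvaluationReport(
        per_fold=per_fold,
        accuracy=acc,
        accuracy_sd=acc_sd,
        sensitivity=sen,
        sensitivity_sd=sen_sd,
        specificity=spe,
        specificity_sd=spe_sd,
        auc=auc,
        fold_assignments=fold_assign,
        positive_class=pos,
        region_ranking=ranking,
    )
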