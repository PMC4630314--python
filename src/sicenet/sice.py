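"""Sparse inverse covariance estimation (SICE / graphical lasso).

The estimator maximises the l1-penalised Gaussian log-likelihood

    log det(Theta) - tr(S Theta) - lambda * ||Theta||_1

over symmetric positive-definite Theta, where S is the empirical
covariance (divisor n).  Off-diagonal zeros of the solution encode
conditional independence between region pairs, so the estimate doubles
as an undirected connectivity graph ("arcs" = nonzero off-diagonal
pairs).  Sparseness is controlled through lambda; comparisons across
groups are made at matched arc counts by sweeping lambda.

The penalty here covers all entries of Theta, including the diagonal.
Because the diagonal of a positive-definite matrix is positive, that
objective is equivalent to penalising only the off-diagonal after
shifting the covariance to S + lambda*I, which is how the solve is
delegated to the coordinate-descent graphical-lasso routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso

from .atlas import LobePartition
from .types import FeatureMatrix

ZERO_TOL = 1e-8  # off-diagonal entries at or below this magnitude count as zero


@dataclass
class EmpiricalCovariance:
    """S = (1/n) sum_i (x_i - mu)(x_i - mu)^T with mu the sample mean."""

    S: np.ndarray
    mean: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass
class PrecisionEstimate:
    """A penalised-likelihood estimate of the precision matrix."""

    theta_hat: np.ndarray
    lam: float
    arc_count: int
    objective_value: float
    converged: bool
    zero_tol: float = ZERO_TOL


@dataclass
class BinarizedNetwork:
    """Symmetric 0/1 adjacency over regions (zero diagonal)."""

    adjacency: np.ndarray
    partition: LobePartition
    source_arcs: int = 0
    strengths: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(int)

    @property
    def arcs(self) -> int:
        return int(self.adjacency.sum()) // 2

    def arc_list(self) -> list[tuple[int, int]]:
        """Arcs as region-id pairs (i < j)."""
        ids = self.partition.region_ids
        p = self.adjacency.shape[0]
        return [
            (ids[i], ids[j])
            for i in range(p)
            for j in range(i + 1, p)
            if self.adjacency[i, j]
        ]


@dataclass
class CumulativeNetwork:
    """Weighted sum of binarized precision matrices across arc levels.

    An arc that survives at sparse levels (few arcs, strong
    relationships) accumulates larger weight than one appearing only at
    dense levels, so entries of ``theta_c`` act as a proxy for
    connection strength.
    """

    theta_c: np.ndarray
    arc_levels: tuple[int, ...]
    weights: dict[int, float]
    partition: LobePartition
    realized_arcs: dict[int, int] = field(default_factory=dict)


def empirical_covariance(features: FeatureMatrix | np.ndarray) -> EmpiricalCovariance:
    """Empirical covariance with divisor n (maximum-likelihood form)."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("need an n x p matrix with n >= 1")
    mu = x.mean(axis=0)
    d = x - mu
    S = d.T @ d / x.shape[0]
    return EmpiricalCovariance(S=(S + S.T) / 2.0, mean=mu, n=x.shape[0])


def penalized_objective(theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """log det(Theta) - tr(S Theta) - lam * ||Theta||_1 (all entries)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S @ theta) - lam * np.abs(theta).sum())


def count_arcs(theta: np.ndarray, zero_tol: float = ZERO_TOL) -> int:
    off = np.abs(theta - np.diag(np.diag(theta)))
    return int((off > zero_tol).sum()) // 2


def estimate_sparse_precision(
    cov: EmpiricalCovariance,
    lam: float,
    zero_tol: float = ZERO_TOL,
    penalize_diagonal: bool = True,
    max_iter: int = 200,
) -> PrecisionEstimate:
    """Solve the l1-penalised precision-matrix problem at one lambda.

    With ``lam = 0`` this is the unpenalised MLE, i.e. direct inversion
    of S (S must then be nonsingular).  Entries with magnitude at or
    below ``zero_tol`` are truncated to exact zeros.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    S = cov.S
    p = S.shape[0]
    if lam == 0.0:
        if np.linalg.matrix_rank(S) < p:
            raise np.linalg.LinAlgError("singular empirical covariance: MLE requires regularization")
        theta = np.linalg.inv(S)
        theta = (theta + theta.T) / 2.0
        converged = True
    else:
        # full-matrix l1 penalty == off-diagonal penalty on S + lam*I
        target = S + lam * np.eye(p) if penalize_diagonal else S
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                _, theta = graphical_lasso(target, alpha=lam, max_iter=max_iter)
            except FloatingPointError:
                # coordinate descent can fail on near-singular problems at
                # tiny lambda; the LARS mode is slower but more robust there
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso(target, alpha=lam, max_iter=max_iter, mode="lars")
            except Warning:
                converged = False
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso(target, alpha=lam, max_iter=max_iter)
        theta = (theta + theta.T) / 2.0
    off_mask = ~np.eye(p, dtype=bool)
    theta[off_mask & (np.abs(theta) <= zero_tol)] = 0.0
    if penalize_diagonal:
        obj = penalized_objective(theta, S, lam)
    else:
        obj = penalized_objective(theta, S, 0.0) - lam * np.abs(theta[off_mask]).sum()
    return PrecisionEstimate(
        theta_hat=theta,
        lam=lam,
        arc_count=count_arcs(theta, zero_tol),
        objective_value=obj,
        converged=converged,
        zero_tol=zero_tol,
    )


def default_lambda_bounds(cov: EmpiricalCovariance) -> tuple[float, float]:
    """[1e-4 * s_max, s_max] with s_max the largest off-diagonal |S|;
    above s_max the estimated graph is empty."""
    off = np.abs(cov.S - np.diag(np.diag(cov.S)))
    s_max = float(off.max())
    if s_max <= 0:
        s_max = 1.0
    return 1e-4 * s_max, s_max


def sweep_lambda_to_arcs(
    cov: EmpiricalCovariance,
    target_arcs: int,
    lam_bounds: tuple[float, float] | None = None,
    max_iter: int = 40,
    zero_tol: float = ZERO_TOL,
    penalize_diagonal: bool = True,
) -> PrecisionEstimate:
    """Bisection over lambda for the estimate whose arc count is closest
    to ``target_arcs``.

    Arc counts are non-increasing in lambda, so bisection brackets the
    target; when the exact count is unattainable (the solution path
    jumps over it) the sparser of the two bracketing solutions is
    returned, with the realized count recorded on the estimate.
    """
    p = cov.p
    max_arcs = p * (p - 1) // 2
    if not 0 <= target_arcs <= max_arcs:
        raise ValueError(f"target_arcs must be in [0, {max_arcs}]")
    lo, hi = lam_bounds if lam_bounds is not None else default_lambda_bounds(cov)
    if not (0 <= lo < hi):
        raise ValueError("invalid lambda bounds")

    est_hi = estimate_sparse_precision(cov, hi, zero_tol, penalize_diagonal)
    if est_hi.arc_count >= target_arcs:
        return est_hi

    # bisection invariant: arcs(lo) > target_arcs > arcs(hi); the lower
    # endpoint is evaluated lazily (it is the most ill-conditioned solve)
    est_lo = None
    span = hi - lo
    for _ in range(max_iter):
        if hi - lo < 1e-6 * span:
            break
        mid = 0.5 * (lo + hi)
        est_mid = estimate_sparse_precision(cov, mid, zero_tol, penalize_diagonal)
        if est_mid.arc_count == target_arcs:
            return est_mid
        if est_mid.arc_count > target_arcs:
            lo, est_lo = mid, est_mid
        else:
            hi, est_hi = mid, est_mid
    if est_lo is None:
        est_lo = estimate_sparse_precision(cov, lo, zero_tol, penalize_diagonal)
        if est_lo.arc_count <= target_arcs:
            return est_lo
    # unattainable exact count: closest bracketing solution, ties to the
    # sparser (larger-lambda) side
    if abs(est_lo.arc_count - target_arcs) < abs(est_hi.arc_count - target_arcs):
        return est_lo
    return est_hi


def binarize(
    estimate: PrecisionEstimate,
    partition: LobePartition,
    zero_tol: float | None = None,
) -> BinarizedNetwork:
    """Threshold-at-zero binarization: a_ij = 1 iff i != j and
    |theta_hat_ij| exceeds the zero tolerance."""
    tol = estimate.zero_tol if zero_tol is None else zero_tol
    theta = estimate.theta_hat
    a = (np.abs(theta) > tol).astype(int)
    np.fill_diagonal(a, 0)
    a = ((a + a.T) > 0).astype(int)
    return BinarizedNetwork(
        adjacency=a,
        partition=partition,
        source_arcs=estimate.arc_count,
        strengths=np.abs(theta) * (a > 0),
    )


DEFAULT_ARC_LEVELS = (10, 25, 50, 75, 100)


def inverse_arc_weight(n_arcs: int) -> float:
    """Weight 10/n for the binarized matrix estimated at n arcs, so the
    sparsest level dominates the cumulative sum."""
    return 10.0 / n_arcs


def cumulative_precision(
    cov: EmpiricalCovariance,
    partition: LobePartition,
    arc_levels: tuple[int, ...] = DEFAULT_ARC_LEVELS,
    weight_fn=inverse_arc_weight,
    lam_bounds: tuple[float, float] | None = None,
    zero_tol: float = ZERO_TOL,
) -> CumulativeNetwork:
    """Cumulative inverse covariance: the weighted sum of binarized
    estimates across arc levels.  An edge's accumulated value measures
    its resistance to disappearing as sparseness increases."""
    if not arc_levels:
        raise ValueError("arc_levels must be nonempty")
    max_arcs = partition.p * (partition.p - 1) // 2
    if any(not 0 < n <= max_arcs for n in arc_levels):
        raise ValueError(f"arc levels must lie in (0, {max_arcs}]")
    theta_c = np.zeros((partition.p, partition.p))
    weights: dict[int, float] = {}
    realized: dict[int, int] = {}
    for n in sorted(arc_levels):
        est = sweep_lambda_to_arcs(cov, n, lam_bounds=lam_bounds, zero_tol=zero_tol)
        net = binarize(est, partition)
        w = float(weight_fn(n))
        weights[n] = w
        realized[n] = net.arcs
        theta_c += w * net.adjacency
    return CumulativeNetwork(
        theta_c=theta_c,
        arc_levels=tuple(sorted(arc_levels)),
        weights=weights,
        partition=partition,
        realized_arcs=realized,
    )


def top_arcs(network: CumulativeNetwork | PrecisionEstimate, partition: LobePartition, k: int) -> BinarizedNetwork:
    """Keep the k strongest arcs (by theta_c entry, or |theta_hat| for a
    raw estimate); ties at the cut break by lexicographic region-pair
    order."""
    if isinstance(network, CumulativeNetwork):
        strength = network.theta_c
    else:
        strength = np.abs(network.theta_hat.copy())
        np.fill_diagonal(strength, 0.0)
    p = strength.shape[0]
    pairs = [
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if strength[i, j] > 0
    ]
    if k < 1 or k > len(pairs):
        raise ValueError(f"k must be in [1, {len(pairs)}] (available arcs)")
    pairs.sort(key=lambda ij: (-strength[ij], ij))
    a = np.zeros((p, p), dtype=int)
    for (i, j) in pairs[:k]:
        a[i, j] = a[j, i] = 1
    return BinarizedNetwork(adjacency=a, partition=partition, source_arcs=k, strengths=strength * (a > 0))
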