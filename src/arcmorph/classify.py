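"""Group discrimination: CVA, balanced cross-validated LDA, Mahalanobis
distances between group means, and discriminant-axis shape endpoints.

Classification uses linear discriminant analysis with a pooled within-group
covariance and equal priors: a specimen is assigned to the group mean at
the smallest Mahalanobis distance.  Because archaeological group sizes are
very unequal, cross-validation percentages are computed on balanced
resamples: each group is subsampled without replacement to the smallest
group size, leave-one-out CV is run, and the replicate percentages are
summarized as their mean with an empirical 90% interval (5th and 95th
percentiles of the replicate values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .shapespace import PCASpace, pca, select_pc_count


def _pooled_within_cov(x: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Pooled within-group covariance (SSCP / (n - g)) and group means."""
    names = sorted(set(labels.tolist()))
    n, p = x.shape
    sscp = np.zeros((p, p))
    means = {}
    for name in names:
        sub = x[labels == name]
        mu = sub.mean(axis=0)
        means[name] = mu
        centered = sub - mu
        sscp += centered.T @ centered
    dof = n - len(names)
    if dof <= 0:
        raise np.linalg.LinAlgError("no error degrees of freedom for pooled covariance")
    return sscp / dof, means


def loo_cv_lda(scores: np.ndarray, groups: Sequence[str]) -> float:
    """Leave-one-out cross-validated LDA accuracy, as a percentage.

    For each specimen the pooled-covariance LDA is refit without it and the
    held-out specimen is classified by smallest Mahalanobis distance to the
    group means, with equal priors.
    """
    x = np.atleast_2d(np.asarray(scores, float))
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    if any(np.sum(labels == g) < 2 for g in names):
        raise ValueError("every group needs at least 2 specimens")
    n, p = x.shape
    if p >= n - len(names):
        raise ValueError(f"p={p} too large for n={n} with {len(names)} groups")
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        cov, means = _pooled_within_cov(x[mask], labels[mask])
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular pooled within-group covariance during LOO refit"
            ) from None
        best, best_d = None, np.inf
        for name, mu in means.items():
            diff = x[i] - mu
            d = float(diff @ cov_inv @ diff)
            if d < best_d:
                best, best_d = name, d
        if best == labels[i]:
            correct += 1
    return 100.0 * correct / n


@dataclass
class CrossValidationSummary:
    """Balanced-resample CV summary: replicate percentages, their mean, and
    the empirical 90% interval (5th/95th percentiles)."""

    replicate_cv: list[float]
    mean_cv: float
    ci_low: float
    ci_high: float
    n_pcs_used: int
    balanced_n: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_cv": self.mean_cv,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_replicates": len(self.replicate_cv),
            "n_pcs_used": self.n_pcs_used,
            "balanced_n": self.balanced_n,
            "replicate_cv": self.replicate_cv,
        }


def balanced_cv_summary(
    scores: np.ndarray,
    groups: Sequence[str],
    n_replicates: int = 100,
    seed: int = 0,
    n_pcs_used: int | None = None,
) -> CrossValidationSummary:
    """Run ``n_replicates`` balanced leave-one-out LDA cross-validations.

    Per replicate every group is subsampled without replacement to the
    smallest group size.  ``n_pcs_used`` is carried through for reporting
    only; the scores passed in are used as-is.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    x = np.atleast_2d(np.asarray(scores, float))
    if x.shape[0] != len(groups):
        x = x.T
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    n_min = min(int(np.sum(labels == g)) for g in names)
    if n_min < 3:
        raise ValueError("smallest group must have at least 3 specimens")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        take = []
        for g in names:
            members = np.flatnonzero(labels == g)
            take.append(rng.choice(members, size=n_min, replace=False))
        sel = np.concatenate(take)
        reps.append(loo_cv_lda(x[sel], labels[sel]))
    reps_arr = np.array(reps)
    return CrossValidationSummary(
        replicate_cv=[float(r) for r in reps],
        mean_cv=float(reps_arr.mean()),
        ci_low=float(np.percentile(reps_arr, 5)),
        ci_high=float(np.percentile(reps_arr, 95)),
        n_pcs_used=n_pcs_used if n_pcs_used is not None else x.shape[1],
        balanced_n=n_min,
        extra={"seed": seed},
    )


def cva_axes(scores: np.ndarray, groups: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Canonical variate axes: eigenvectors of (pooled within)^-1 (between).

    Returns (axes, eigenvalues) with axes as columns, sorted by decreasing
    eigenvalue; min(groups - 1, p) axes are kept.
    """
    x = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    g = len(names)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n, p = x.shape
    sw, means = _pooled_within_cov(x, labels)
    grand = x.mean(axis=0)
    sb = np.zeros((p, p))
    for name in names:
        n_g = int(np.sum(labels == name))
        diff = means[name] - grand
        sb += n_g * np.outer(diff, diff)
    sb /= max(g - 1, 1)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(sb, sw)
    except scipy.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular pooled within-group covariance") from None
    order = np.argsort(eigvals)[::-1]
    n_axes = min(g - 1, p)
    eigvals = eigvals[order][:n_axes]
    eigvecs = eigvecs[:, order][:, :n_axes]
    return eigvecs, np.maximum(eigvals, 0.0)


@dataclass
class MahalanobisMatrix:
    """Symmetric matrix of Mahalanobis distances D between group means."""

    groups: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, float)
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(d, 0.0)
        self.distances = d


def mahalanobis_matrix(scores: np.ndarray, groups: Sequence[str]) -> MahalanobisMatrix:
    """Pairwise Mahalanobis distances D (not D^2) between group means, using
    the pooled within-group covariance on the retained PCs."""
    x = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    cov, means = _pooled_within_cov(x, labels)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular pooled within-group covariance") from None
    g = len(names)
    d = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            diff = means[names[i]] - means[names[j]]
            d[i, j] = d[j, i] = float(np.sqrt(diff @ cov_inv @ diff))
    return MahalanobisMatrix(groups=names, distances=d)


@dataclass
class DiscriminantShapePair:
    """Shapes at the two ends of the discriminant axis between two groups,
    back-projected to landmark coordinate space."""

    endpoint_minus: np.ndarray
    endpoint_plus: np.ndarray
    grand_mean: np.ndarray
    magnitude_sd: float
    n_pcs_used: int


def discriminant_shape_endpoints(
    shapes: np.ndarray,
    groups: Sequence[str],
    magnitude_sd: float = 3.0,
    n_pcs: int | None = None,
    variance_threshold: float = 0.90,
) -> DiscriminantShapePair:
    """Mean shape displaced +/- ``magnitude_sd`` pooled SDs along the
    discriminant axis between two groups.

    ``shapes`` is an (n, k, m) stack of aligned shapes.  The discriminant
    axis is computed in retained-PC space and mapped back to coordinate
    space through the PCA loadings, so the endpoint difference lies in the
    span of the retained components.
    """
    arr = np.asarray(shapes, float)
    n, k, m = arr.shape
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError("discriminant endpoints need exactly 2 groups")
    flat = arr.reshape(n, -1)
    space = pca(flat)
    if n_pcs is None:
        sizes = [int(np.sum(labels == g)) for g in names]
        n_pcs = select_pc_count(space, sizes, variance_threshold)
    sc = space.scores[:, :n_pcs]
    cov, means = _pooled_within_cov(sc, labels)
    axis = np.linalg.solve(cov, means[names[1]] - means[names[0]])
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise ValueError("degenerate discriminant axis (identical group means)")
    axis = axis / norm
    disc = sc @ axis
    _, disc_means = _pooled_within_cov(disc[:, None], labels)
    pooled_var = _pooled_within_cov(disc[:, None], labels)[0][0, 0]
    sd = float(np.sqrt(pooled_var))
    direction = (axis @ space.axes[:n_pcs]).reshape(k, m)
    grand = flat.mean(axis=0).reshape(k, m)
    delta = magnitude_sd * sd * direction
    return DiscriminantShapePair(
        endpoint_minus=grand - delta,
        endpoint_plus=grand + delta,
        grand_mean=grand,
        magnitude_sd=magnitude_sd,
        n_pcs_used=n_pcs,
    )
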