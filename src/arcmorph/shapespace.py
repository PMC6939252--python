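"""PCA of shape and form, and the dimensionality-reduction rule.

All multivariate tests and classifiers downstream run on a reduced number of
principal-component scores.  The reduction rule keeps the smallest number of
components reaching a cumulative-variance threshold (default 90%), capped at
one less than the smallest group size so pooled covariance matrices stay
invertible.  PCA is on the covariance matrix — Procrustes and form
coordinates share units, so no correlation scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .superimpose import GPAResult


@dataclass
class PCASpace:
    """Principal components of a data matrix.

    ``axes`` holds one orthonormal loading vector per row (component x
    variable); ``scores`` is specimens x components with zero column means;
    ``variances`` are the non-increasing component variances.
    """

    mean: np.ndarray
    axes: np.ndarray
    variances: np.ndarray
    scores: np.ndarray

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.variances / self.variances.sum()

    def reconstruct(self) -> np.ndarray:
        return self.mean + self.scores @ self.axes

    def backproject(self, component_vector: np.ndarray) -> np.ndarray:
        """Map a vector in score space back to the original coordinate space."""
        return np.asarray(component_vector, float) @ self.axes


def pca(data: np.ndarray, drop_tol: float = 1e-12) -> PCASpace:
    """Covariance PCA via SVD of the row-centered data matrix.

    Components with variance below ``drop_tol`` times the total are dropped.
    Loading signs follow a deterministic convention (largest-magnitude
    loading positive) so results are reproducible across runs.
    """
    x = np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs a matrix with at least 2 rows")
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2 / (x.shape[0] - 1)
    total = variances.sum()
    keep = variances > drop_tol * total if total > 0 else variances > 0
    if not np.any(keep):
        keep = np.zeros(len(variances), bool)
        keep[0] = True
    u, s, vt, variances = u[:, keep], s[keep], vt[keep], variances[keep]
    # deterministic sign: largest-|loading| entry of each axis is positive
    pivots = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), pivots])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    scores = (u * s) * signs[None, :]
    return PCASpace(mean=mean, axes=vt, variances=variances, scores=scores)


def select_pc_count(
    space: PCASpace,
    group_sizes: Sequence[int],
    variance_threshold: float = 0.90,
) -> int:
    """Number of leading PCs to retain.

    The smallest count whose cumulative variance fraction reaches
    ``variance_threshold``, capped at (smallest group size - 1), and never
    below 1.
    """
    if len(space.variances) < 1:
        raise ValueError("no retained components")
    cum = np.cumsum(space.variance_fractions)
    by_variance = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    by_variance = min(by_variance, len(space.variances))
    n_min = min(group_sizes)
    return max(1, min(by_variance, n_min - 1))


def to_form_matrix(aligned: GPAResult) -> np.ndarray:
    """Form-space data matrix: flattened Procrustes coordinates plus a final
    column of log centroid size, so size and shape are analysed jointly."""
    sizes = aligned.centroid_sizes
    if np.any(sizes <= 0):
        raise ValueError("non-positive centroid size in aligned dataset")
    return np.hstack([aligned.flat, np.log(sizes)[:, None]])
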