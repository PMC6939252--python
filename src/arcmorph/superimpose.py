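"""Procrustes superimposition.

Ordinary (two-shape) and generalized Procrustes analysis with tangent-direction
sliding of semilandmarks under the Procrustes-distance criterion, and
object-symmetry symmetrization (reflect, relabel, align, average).  Rotations
are restricted to proper rotations (determinant +1): left/right side
standardization is an I/O concern, and allowing reflections here would
silently merge mirrored forms.

Shapes are scaled to unit centroid size inside GPA (full Procrustes); sizes
are carried separately as centroid size and its natural log, which is the
quantity analysed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import LandmarkConfiguration, SliderScheme, SymmetryScheme

logger = logging.getLogger(__name__)


def centroid_size(points: np.ndarray) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty k x m matrix")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _standardize(points: np.ndarray) -> np.ndarray:
    """Center at the origin and scale to unit centroid size."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs <= 0.0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||source @ R - target||_F.

    Both inputs must already be centered.  This is the Kabsch solution with
    the reflection branch excluded.
    """
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.ones(h.shape[0])
    correction[-1] = d
    return (u * correction) @ vt


def opa_align(
    target: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes alignment of ``target`` onto ``reference``.

    Both configurations are translated to the origin and scaled to unit
    centroid size; the target is then rotated (proper rotation only) to
    minimize the summed squared distance to the reference.  Returns the
    aligned target and the minimized root-sum-of-squares (the partial
    Procrustes distance between the standardized shapes).
    """
    t = np.asarray(target, float)
    r = np.asarray(reference, float)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    ts = _standardize(t)
    rs = _standardize(r)
    rot = optimal_rotation(ts, rs)
    aligned = ts @ rot
    dist = float(np.sqrt(np.sum((aligned - rs) ** 2)))
    return aligned, dist


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-sum-of-squares residual after optimal superimposition of unit-size shapes."""
    return opa_align(a, b)[1]


def slide_semilandmarks(
    points: np.ndarray, reference: np.ndarray, sliders: SliderScheme
) -> np.ndarray:
    """Slide semilandmarks along their tangent toward the reference.

    The tangent at a semilandmark is the unit chord from its *before* to its
    *after* neighbour; the point moves by the signed projection of
    (reference - current) onto that tangent, the 1-D least-squares optimum
    along the tangent line.  Fixed landmarks are untouched.  Both
    configurations must already live in a common superimposed frame.
    """
    pts = np.asarray(points, float).copy()
    ref = np.asarray(reference, float)
    for before, idx, after in sliders.triples:
        chord = pts[after] - pts[before]
        norm = np.linalg.norm(chord)
        if norm < 1e-12:
            logger.warning(
                "semilandmark %d has coincident neighbours; left unmoved", idx
            )
            continue
        u = chord / norm
        pts[idx] = pts[idx] + np.dot(ref[idx] - pts[idx], u) * u
    return pts


def symmetrize(points: np.ndarray, symmetry: SymmetryScheme, axis: int = 0) -> np.ndarray:
    """Symmetric component of a configuration under object symmetry.

    Builds the mirrored configuration (one coordinate axis reflected, left and
    right labels swapped), rotates it onto the original, and returns the
    pointwise average.  The result is a fixed point of the reflect-and-relabel
    operator, and the operation is idempotent.
    """
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    perm = symmetry.permutation(pts.shape[0])
    mirrored = centered.copy()
    mirrored[:, axis] *= -1.0
    mirrored = mirrored[perm]
    rot = optimal_rotation(mirrored, centered)
    return (centered + mirrored @ rot) / 2.0 + centroid


@dataclass
class AlignedSample:
    """One superimposed specimen: unit-size shape plus its original size."""

    specimen_id: str
    shape: np.ndarray
    centroid_size: float

    @property
    def log_size(self) -> float:
        return float(np.log(self.centroid_size))


@dataclass
class GPAResult:
    consensus: np.ndarray
    aligned: list[AlignedSample]
    iterations: int
    converged: bool
    final_change: float

    @property
    def shapes(self) -> np.ndarray:
        """(n, k, m) stack of aligned shapes."""
        return np.stack([a.shape for a in self.aligned])

    @property
    def flat(self) -> np.ndarray:
        """(n, k*m) flattened aligned shapes."""
        s = self.shapes
        return s.reshape(s.shape[0], -1)

    @property
    def centroid_sizes(self) -> np.ndarray:
        return np.array([a.centroid_size for a in self.aligned])

    @property
    def log_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def specimen_ids(self) -> list[str]:
        return [a.specimen_id for a in self.aligned]


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Deterministic proper rotation taking the consensus to a canonical pose.

    The pose is anchored on landmark geometry, which is stable even for
    highly symmetric shapes: the first distinct landmark pair defines the +x
    direction, and (in 3-D) the first landmark off that baseline pins the
    x-y plane.  This fixes the otherwise arbitrary global orientation of a
    GPA solution, so outputs are invariant to rigid motions of the inputs.
    """
    k, m = consensus.shape
    e1 = None
    for j in range(1, k):
        u = consensus[j] - consensus[0]
        norm = np.linalg.norm(u)
        if norm > 1e-6:
            e1 = u / norm
            break
    if e1 is None:
        return np.eye(m)
    if m == 2:
        e2 = np.array([-e1[1], e1[0]])
        return np.column_stack([e1, e2])
    e2 = None
    for j in range(1, k):
        v = consensus[j] - consensus[0]
        w = v - np.dot(v, e1) * e1
        norm = np.linalg.norm(w)
        if norm > 1e-6:
            e2 = w / norm
            break
    if e2 is None:
        return np.eye(m)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def gpa(
    configs: list[LandmarkConfiguration] | list[np.ndarray],
    sliders: SliderScheme | None = None,
    symmetry: SymmetryScheme | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    n_slide_passes: int = 3,
    slide_tol: float = 1e-7,
) -> GPAResult:
    """Generalized Procrustes analysis.

    Iterates {align all configurations to the consensus, slide semilandmarks
    against it (if a slider scheme is given), symmetrize (if a symmetry
    scheme is given), recompute the consensus} until the mean consensus
    landmark displacement falls below ``tol`` or ``max_iter`` is reached.
    Non-convergence is flagged on the result, not raised.

    Sliding leaves the semilandmarks' positions along the curve as a soft
    mode, so interleaved sliding alone approaches its fixed point only
    geometrically.  Sliding is therefore frozen once it has effectively
    converged — when the consensus displacement falls below ``slide_tol`` or
    stops improving between outer iterations — after which plain GPA
    iterations finish the convergence.

    All aligned shapes have unit centroid size; the original centroid sizes
    are recorded before scaling.  The final solution is rotated to a
    canonical orientation so repeated runs on rigidly transformed inputs
    agree to numerical precision.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if isinstance(configs[0], LandmarkConfiguration):
        ids = [c.specimen_id for c in configs]
        raw = [c.points for c in configs]
    else:
        ids = [f"s{i}" for i in range(len(configs))]
        raw = [np.asarray(c, float) for c in configs]
    k, m = raw[0].shape
    for p in raw:
        if p.shape != (k, m):
            raise ValueError("inconsistent landmark dimensions across configurations")
    sizes = np.array([centroid_size(p) for p in raw])
    shapes = np.stack([_standardize(p) for p in raw])

    # Initialization.  With sliding, the solution set is a continuum (the
    # semilandmarks' positions along the curve are a soft mode), so the
    # iteration path must be exactly rotation-equivariant for outputs to be
    # invariant under rigid motions of the inputs: initialize from the first
    # shape.  Without sliding the fixed point is unique, and initializing
    # from the raw mean lets an already-superimposed dataset reconverge in a
    # single iteration; fall back to the first shape if that mean collapses.
    if sliders is not None:
        consensus = shapes[0].copy()
    else:
        raw_mean = shapes.mean(axis=0)
        mean_size = np.sqrt(np.sum((raw_mean - raw_mean.mean(axis=0)) ** 2))
        consensus = _standardize(raw_mean) if mean_size > 0.2 else shapes[0].copy()
    iterations = 0
    final_change = np.inf
    prev_change = np.inf
    converged = False
    sliding_active = sliders is not None
    for iterations in range(1, max_iter + 1):
        for i in range(len(shapes)):
            rot = optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ rot
        if sliding_active:
            for _ in range(n_slide_passes):
                for i in range(len(shapes)):
                    slid = slide_semilandmarks(shapes[i], consensus, sliders)
                    slid = _standardize(slid)
                    shapes[i] = slid @ optimal_rotation(slid, consensus)
        if symmetry is not None:
            for i in range(len(shapes)):
                sym = _standardize(symmetrize(shapes[i], symmetry))
                shapes[i] = sym @ optimal_rotation(sym, consensus)
        new_consensus = _standardize(shapes.mean(axis=0))
        new_consensus = new_consensus @ optimal_rotation(new_consensus, consensus)
        final_change = float(
            np.mean(np.linalg.norm(new_consensus - consensus, axis=1))
        )
        if sliding_active and (
            final_change < slide_tol or final_change > 0.9 * prev_change
        ):
            sliding_active = False
        prev_change = final_change
        consensus = new_consensus
        if final_change < tol:
            converged = True
            break

    # polish: re-align to the final consensus so the output is at the GPA
    # fixed point (not one rotation update behind it)
    for i in range(len(shapes)):
        shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
    consensus = _standardize(shapes.mean(axis=0))
    canon = _canonical_rotation(consensus)
    consensus = consensus @ canon
    shapes = shapes @ canon
    # the consensus contract: mean of aligned shapes, rescaled to unit size
    consensus = _standardize(shapes.mean(axis=0))
    aligned = [
        AlignedSample(specimen_id=ids[i], shape=shapes[i], centroid_size=float(sizes[i]))
        for i in range(len(shapes))
    ]
    return GPAResult(
        consensus=consensus,
        aligned=aligned,
        iterations=iterations,
        converged=converged,
        final_change=final_change,
    )
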