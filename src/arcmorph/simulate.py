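"""Synthetic landmark datasets and haplotype assignments.

The generator mirrors the structure the analysis assumes: each group has a
mean-shape offset from a shared template, isotropic Gaussian landmark noise,
log-normal centroid sizes (so log size is Gaussian, as analysed), and an
optional allometric slope linking shape to log size.  Specimens are then
subjected to random rigid motions and scaled to their drawn size, which GPA
must undo.  Ground truth (realized offsets, slopes, sizes) is returned so
recovery tests can compare estimates with the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    FIXED,
    SEMILANDMARK,
    LandmarkConfiguration,
    SliderScheme,
    SpecimenMetadata,
    SymmetryScheme,
)


@dataclass
class Template:
    points: np.ndarray
    roles: list[str]
    sliders: SliderScheme | None
    symmetry: SymmetryScheme | None
    element: str
    curves: list[list[int]] = field(default_factory=list)


def make_template(kind: str, n_semilandmarks: int = 49) -> Template:
    """Deterministic base configurations emulating the three skeletal elements.

    - ``ellipse_outline``: two fixed endpoint landmarks plus equally spaced
      sliding semilandmarks along an elliptical arc (a tooth-outline design).
    - ``toy_mandible``: 15 fixed 2-D landmarks on a mandible-like outline.
    - ``toy_cranium_3d``: 30 3-D landmarks (6 midline + 12 bilateral pairs)
      with a left/right symmetry scheme; exactly symmetric under
      reflect-and-relabel.
    """
    if kind == "ellipse_outline":
        if n_semilandmarks < 0:
            raise ValueError("n_semilandmarks must be >= 0")
        a, b = 1.0, 0.6
        fixed = np.array([[-a, 0.0], [a, 0.0]])
        # semilandmarks along the upper arc from (-a,0) to (a,0)
        angles = np.linspace(np.pi, 0.0, n_semilandmarks + 2)[1:-1]
        curve = np.column_stack([a * np.cos(angles), b * np.sin(angles)])
        points = np.vstack([fixed, curve])
        roles = [FIXED, FIXED] + [SEMILANDMARK] * n_semilandmarks
        # curve order: fixed endpoint 0, semis 2..n+1, fixed endpoint 1
        chain = [0] + list(range(2, 2 + n_semilandmarks)) + [1]
        triples = tuple(
            (chain[i - 1], chain[i], chain[i + 1]) for i in range(1, len(chain) - 1)
        )
        sliders = SliderScheme(triples) if triples else None
        return Template(points, roles, sliders, None, "lower_m1")
    if kind == "toy_mandible":
        t = np.linspace(0.1, 2.6, 10)
        body = np.column_stack([np.cos(t), 0.45 * np.sin(t)])
        ramus = np.array(
            [[-1.05, 0.55], [-0.85, 0.75], [-0.6, 0.65], [-0.35, 0.3], [0.2, -0.25]]
        )
        points = np.vstack([body, ramus])
        return Template(points, [FIXED] * 15, None, None, "mandible")
    if kind == "toy_cranium_3d":
        midline = np.array(
            [
                [0.0, 1.2, 0.0],
                [0.0, 0.8, 0.45],
                [0.0, 0.2, 0.6],
                [0.0, -0.4, 0.5],
                [0.0, -0.9, 0.25],
                [0.0, -1.1, 0.0],
            ]
        )
        t = np.linspace(0.2, 2.9, 12)
        left = np.column_stack(
            [0.35 + 0.25 * np.sin(1.7 * t), np.cos(t), 0.3 * np.sin(t)]
        )
        right = left.copy()
        right[:, 0] *= -1.0
        points = np.vstack([midline, left, right])
        paired = tuple((6 + i, 18 + i) for i in range(12))
        symmetry = SymmetryScheme(paired=paired, midline=tuple(range(6)))
        return Template(points, [FIXED] * 30, None, symmetry, "crania")
    raise ValueError(f"unknown template kind {kind!r}")


@dataclass
class GroupSpec:
    """Generating parameters for one group.

    ``offset`` is either a (k, m) displacement of the mean shape from the
    template (in template units, i.e. fractions of a unit-centroid-size
    shape) or a scalar magnitude from which a random direction is drawn.
    ``allometry_slope`` is an optional (k, m) shape displacement per unit log
    size.  Sizes are log-normal: log centroid size ~ N(size_log_mean,
    size_log_sd).
    """

    name: str
    n: int
    offset: np.ndarray | float = 0.0
    size_log_mean: float = 4.0
    size_log_sd: float = 0.1
    allometry_slope: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass
class SimulationSpec:
    template: Template
    groups: list[GroupSpec]
    landmark_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SimulatedDataset:
    configs: list[LandmarkConfiguration]
    metadata: list[SpecimenMetadata]
    sliders: SliderScheme | None
    symmetry: SymmetryScheme | None
    truth: dict


def _random_rotation(m: int, rng: np.random.Generator) -> np.ndarray:
    if m == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        return np.array([[c, -s], [s, c]])
    q, r = np.linalg.qr(rng.normal(size=(m, m)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1.0
    return q


def _resolve_offset(
    offset: np.ndarray | float, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    if np.isscalar(offset):
        mag = float(offset)
        if mag == 0.0:
            return np.zeros(shape)
        direction = rng.normal(size=shape)
        direction -= direction.mean(axis=0)
        return direction / np.linalg.norm(direction) * mag
    arr = np.asarray(offset, float)
    if arr.shape != shape:
        raise ValueError(f"offset shape {arr.shape} != template shape {shape}")
    return arr


def simulate_landmarks(spec: SimulationSpec) -> SimulatedDataset:
    """Draw a multi-group landmark dataset plus its ground truth.

    Per specimen: shape = template + group offset + slope x (log size -
    group log mean) + isotropic Gaussian landmark noise; the shape is then
    scaled so its centroid size equals the drawn size, randomly rotated and
    translated.  Identical (spec, seed) pairs give identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    tpl = spec.template
    k, m = tpl.points.shape
    configs: list[LandmarkConfiguration] = []
    metadata: list[SpecimenMetadata] = []
    truth: dict = {"offsets": {}, "slopes": {}, "sizes": {}, "log_sizes": {},
                   "template": tpl.points.copy()}
    for group in spec.groups:
        offset = _resolve_offset(group.offset, (k, m), rng)
        truth["offsets"][group.name] = offset
        slope = (
            np.zeros((k, m))
            if group.allometry_slope is None
            else np.asarray(group.allometry_slope, float)
        )
        truth["slopes"][group.name] = slope
        log_sizes = rng.normal(group.size_log_mean, group.size_log_sd, size=group.n)
        sizes = np.exp(log_sizes)
        truth["sizes"][group.name] = sizes
        truth["log_sizes"][group.name] = log_sizes
        for i in range(group.n):
            shape = (
                tpl.points
                + offset
                + slope * (log_sizes[i] - group.size_log_mean)
                + rng.normal(scale=spec.landmark_noise_sd, size=(k, m))
            )
            centered = shape - shape.mean(axis=0)
            cs = np.sqrt(np.sum(centered**2))
            pts = centered / cs * sizes[i]
            pts = pts @ _random_rotation(m, rng).T
            pts = pts + rng.uniform(-10.0, 10.0, size=m)
            sid = f"{group.name}_{i:03d}"
            configs.append(
                LandmarkConfiguration(
                    specimen_id=sid,
                    element=tpl.element,
                    points=pts,
                    roles=list(tpl.roles),
                    curves=[list(c) for c in tpl.curves],
                )
            )
            metadata.append(SpecimenMetadata(sid, group.name, tpl.element))
    return SimulatedDataset(
        configs=configs,
        metadata=metadata,
        sliders=tpl.sliders,
        symmetry=tpl.symmetry,
        truth=truth,
    )


def simulate_haplotypes(
    frequencies: dict[str, dict[str, float]],
    n_per_group: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial haplotype assignments per group.

    ``frequencies`` maps group -> {haplotype: frequency}; frequencies must be
    nonnegative and sum to 1 within each group.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, freqs in frequencies.items():
        haps = sorted(freqs)
        p = np.array([freqs[h] for h in haps], float)
        if np.any(p < 0):
            raise ValueError(f"negative frequency in group {group!r}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies for group {group!r} do not sum to 1")
        n = n_per_group[group]
        draws = rng.multinomial(n, p)
        counter = 0
        for hap, count in zip(haps, draws):
            for _ in range(count):
                rows.append(
                    {"specimen_id": f"{group}_{counter:04d}", "group": group,
                     "haplotype": hap}
                )
                counter += 1
    return pd.DataFrame(rows, columns=["specimen_id", "group", "haplotype"])
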