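"""Reading and writing landmark datasets, digitizing schemes and specimen metadata.

Two carriers are supported: the TPS format produced by 2-D digitizing software
(mandibles and lower first molars, with semilandmark curves) and a long-format
CSV table for 3-D cranial landmarks.  Slider triples, bilateral symmetry pairs
and specimen metadata travel as small CSV files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ELEMENTS = ("crania", "mandible", "lower_m1")
GROUPS = (
    "pleistocene_wolf",
    "modern_wolf",
    "palaeo_inuit",
    "inuit",
    "historical",
    "modern_greenland",
)

FIXED = "fixed"
SEMILANDMARK = "semilandmark"


class TPSParseError(ValueError):
    """Raised for malformed TPS records; the message names the offending line."""


class ValidationError(ValueError):
    """Raised when a landmark table or metadata join violates its contract."""


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark configuration.

    ``points`` is a k x m array (m = 2 or 3) in millimetres once any SCALE
    factor has been applied.  ``roles`` marks each point as a fixed landmark
    or a sliding semilandmark.  ``curves`` records the index runs of any
    semilandmark curves, so a slider scheme can be derived when none is
    supplied explicitly.
    """

    specimen_id: str
    element: str
    points: np.ndarray
    roles: list[str] = field(default_factory=list)
    curves: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: points must be k x 2 or k x 3, "
                f"got shape {self.points.shape}"
            )
        if self.points.shape[0] < 2:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: need at least 2 points"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )
        if not self.roles:
            self.roles = [FIXED] * self.points.shape[0]
        if len(self.roles) != self.points.shape[0]:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: {len(self.roles)} roles for "
                f"{self.points.shape[0]} points"
            )

    @property
    def k(self) -> int:
        return self.points.shape[0]

    @property
    def m(self) -> int:
        return self.points.shape[1]

    @property
    def semilandmark_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == SEMILANDMARK]


@dataclass(frozen=True)
class SliderScheme:
    """Ordered (before, slider, after) index triples for tangent sliding."""

    triples: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for t in self.triples:
            if len(t) != 3:
                raise ValidationError(f"slider triple {t} must have 3 indices")
            if t in seen:
                raise ValidationError(f"duplicate slider triple {t}")
            seen.add(t)

    def validate_against(self, config: LandmarkConfiguration) -> None:
        k = config.k
        for b, s, a in self.triples:
            if not (0 <= b < k and 0 <= s < k and 0 <= a < k):
                raise ValidationError(f"slider triple ({b},{s},{a}) out of range for k={k}")
            if config.roles[s] != SEMILANDMARK:
                raise ValidationError(
                    f"slider triple middle index {s} is not a semilandmark"
                )


@dataclass(frozen=True)
class SymmetryScheme:
    """Bilateral pairing for object symmetry: left/right pairs plus midline points."""

    paired: tuple[tuple[int, int], ...]
    midline: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        used: set[int] = set()
        for pair in self.paired:
            for i in pair:
                if i in used:
                    raise ValidationError(f"index {i} appears twice in symmetry scheme")
                used.add(i)
        for i in self.midline:
            if i in used:
                raise ValidationError(f"index {i} appears twice in symmetry scheme")
            used.add(i)

    def permutation(self, k: int) -> np.ndarray:
        """Relabelling permutation that swaps each left/right pair."""
        perm = np.arange(k)
        for left, right in self.paired:
            if left >= k or right >= k:
                raise ValidationError(f"symmetry pair ({left},{right}) out of range for k={k}")
            perm[left], perm[right] = right, left
        return perm


@dataclass(frozen=True)
class SpecimenMetadata:
    specimen_id: str
    group: str
    element: str


@dataclass
class MorphDataset:
    """Analysis-ready, metadata-joined landmark dataset for one element."""

    element: str
    configs: list[LandmarkConfiguration]
    groups: dict[str, str]
    unmatched: list[str] = field(default_factory=list)

    @property
    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.configs:
            g = self.groups[c.specimen_id]
            counts[g] = counts.get(g, 0) + 1
        return counts

    @property
    def labels(self) -> list[str]:
        return [self.groups[c.specimen_id] for c in self.configs]


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_KEY_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\s*=\s*(.*)$")


def read_tps(path: str | Path, element: str = "mandible") -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    Supports LM= (2-D) and LM3= (3-D) records, CURVES=/POINTS= semilandmark
    blocks (appended after the fixed landmarks with role ``semilandmark``),
    SCALE= (multiplies all coordinates), and ID=/IMAGE= identifiers with ID
    taking precedence.  Unknown keys are skipped with a logged warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, n = 0, len(lines)
    record_no = 0

    def parse_coords(count: int, dim: int, start: int, what: str) -> tuple[np.ndarray, int]:
        rows = []
        j = start
        for _ in range(count):
            if j >= n or _KEY_RE.match(lines[j].strip()):
                raise TPSParseError(
                    f"{path.name}:{j + 1}: expected {count} {what} coordinate "
                    f"lines, got {len(rows)}"
                )
            fields = lines[j].split()
            if len(fields) != dim:
                raise TPSParseError(
                    f"{path.name}:{j + 1}: expected {dim} coordinates, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError:
                raise TPSParseError(
                    f"{path.name}:{j + 1}: non-numeric coordinate {lines[j]!r}"
                ) from None
            j += 1
        return np.array(rows, dtype=float).reshape(count, dim), j

    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEY_RE.match(line)
        if m is None or m.group(1).upper() not in ("LM", "LM3"):
            raise TPSParseError(
                f"{path.name}:{i + 1}: expected an LM=/LM3= record header, got {line!r}"
            )
        key = m.group(1).upper()
        dim = 2 if key == "LM" else 3
        try:
            n_lm = int(m.group(2))
        except ValueError:
            raise TPSParseError(
                f"{path.name}:{i + 1}: malformed landmark count {m.group(2)!r}"
            ) from None
        record_no += 1
        fixed_pts, i = parse_coords(n_lm, dim, i + 1, "landmark")

        curve_pts: list[np.ndarray] = []
        curve_sizes: list[int] = []
        scale = None
        spec_id = None
        image = None
        # trailing keys until next LM=/LM3=
        while i < n:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            km = _KEY_RE.match(line)
            if km is None:
                raise TPSParseError(f"{path.name}:{i + 1}: unexpected line {line!r}")
            k_up = km.group(1).upper()
            if k_up in ("LM", "LM3"):
                break
            if k_up == "CURVES":
                try:
                    n_curves = int(km.group(2))
                except ValueError:
                    raise TPSParseError(
                        f"{path.name}:{i + 1}: malformed CURVES count"
                    ) from None
                i += 1
                for _ in range(n_curves):
                    pm = _KEY_RE.match(lines[i].strip()) if i < n else None
                    if pm is None or pm.group(1).upper() != "POINTS":
                        raise TPSParseError(
                            f"{path.name}:{i + 1}: expected POINTS= after CURVES="
                        )
                    try:
                        n_pts = int(pm.group(2))
                    except ValueError:
                        raise TPSParseError(
                            f"{path.name}:{i + 1}: malformed POINTS count"
                        ) from None
                    pts, i = parse_coords(n_pts, dim, i + 1, "curve")
                    curve_pts.append(pts)
                    curve_sizes.append(n_pts)
            elif k_up == "SCALE":
                try:
                    scale = float(km.group(2))
                except ValueError:
                    raise TPSParseError(
                        f"{path.name}:{i + 1}: malformed SCALE value"
                    ) from None
                i += 1
            elif k_up == "ID":
                spec_id = km.group(2).strip()
                i += 1
            elif k_up == "IMAGE":
                image = km.group(2).strip()
                i += 1
            else:
                logger.warning("%s:%d: ignoring unknown TPS key %s", path.name, i + 1, k_up)
                i += 1

        pts = np.vstack([fixed_pts] + curve_pts) if curve_pts else fixed_pts
        if scale is not None:
            pts = pts * scale
        roles = [FIXED] * n_lm + [SEMILANDMARK] * sum(curve_sizes)
        curves = []
        start = n_lm
        for sz in curve_sizes:
            curves.append(list(range(start, start + sz)))
            start += sz
        ident = spec_id if spec_id is not None else (image if image else f"record_{record_no}")
        configs.append(
            LandmarkConfiguration(
                specimen_id=ident, element=element, points=pts, roles=roles, curves=curves
            )
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as TPS records (scale already folded into coordinates)."""
    path = Path(path)
    out: list[str] = []
    for c in configs:
        key = "LM" if c.m == 2 else "LM3"
        curve_idx = {i for curve in c.curves for i in curve}
        fixed = [i for i in range(c.k) if i not in curve_idx]
        out.append(f"{key}={len(fixed)}")
        for i in fixed:
            out.append(" ".join(repr(float(v)) for v in c.points[i]))
        if c.curves:
            out.append(f"CURVES={len(c.curves)}")
            for curve in c.curves:
                out.append(f"POINTS={len(curve)}")
                for i in curve:
                    out.append(" ".join(repr(float(v)) for v in c.points[i]))
        out.append(f"ID={c.specimen_id}")
    path.write_text("\n".join(out) + "\n")


def derive_sliders(config: LandmarkConfiguration) -> SliderScheme:
    """Slider triples from CURVES blocks: interior curve points slide between
    their neighbours; curve endpoints stay fixed in the scheme."""
    triples = []
    for curve in config.curves:
        for prev_i, i, next_i in zip(curve, curve[1:], curve[2:]):
            triples.append((prev_i, i, next_i))
    return SliderScheme(tuple(triples))


# ---------------------------------------------------------------------------
# Tabular carriers
# ---------------------------------------------------------------------------

def read_landmark_table(path: str | Path, element: str = "crania") -> list[LandmarkConfiguration]:
    """Read a long-format 3-D landmark CSV (specimen_id, point_index, x, y, z)."""
    df = pd.read_csv(path)
    required = {"specimen_id", "point_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"landmark table missing columns: {sorted(missing)}")
    if df.empty:
        return []
    if df[["x", "y", "z"]].isna().any().any():
        bad = df.loc[df[["x", "y", "z"]].isna().any(axis=1), "specimen_id"].unique()
        raise ValidationError(f"missing coordinate cells for specimens: {list(bad)}")

    counts = df.groupby("specimen_id")["point_index"].count()
    if counts.nunique() > 1:
        # tie-break the expected count upward: a missing point is the usual culprit
        mode = int(counts.mode().max())
        offenders = sorted(counts.index[counts != mode])
        raise ValidationError(
            f"ragged point counts across specimens (expected {mode}): {offenders}"
        )
    configs = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        sub = sub.sort_values("point_index")
        expected = np.arange(len(sub))
        if not np.array_equal(sub["point_index"].to_numpy(), expected):
            missing_idx = sorted(set(expected) - set(sub["point_index"]))
            raise ValidationError(
                f"specimen {sid!r}: point indices not contiguous, missing {missing_idx}"
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(sid),
                element=element,
                points=sub[["x", "y", "z"]].to_numpy(float),
            )
        )
    return configs


def write_landmark_table(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    rows = []
    for c in configs:
        for i, p in enumerate(c.points):
            rows.append({"specimen_id": c.specimen_id, "point_index": i,
                         "x": p[0], "y": p[1], "z": p[2] if c.m == 3 else 0.0})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[SpecimenMetadata]:
    df = pd.read_csv(path)
    required = {"specimen_id", "group", "element"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    return [
        SpecimenMetadata(str(r.specimen_id), str(r.group), str(r.element))
        for r in df.itertuples()
    ]


def read_slider_scheme(path: str | Path) -> SliderScheme:
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValidationError("slider scheme needs 3 columns (before, slider, after)")
    triples = tuple(
        (int(r[0]), int(r[1]), int(r[2])) for r in df.iloc[:, :3].itertuples(index=False)
    )
    return SliderScheme(triples)


def read_symmetry_scheme(pairs_path: str | Path, midline: Sequence[int] = ()) -> SymmetryScheme:
    df = pd.read_csv(pairs_path)
    if df.shape[1] < 2:
        raise ValidationError("symmetry scheme needs 2 columns (left, right)")
    paired = tuple((int(r[0]), int(r[1])) for r in df.iloc[:, :2].itertuples(index=False))
    return SymmetryScheme(paired, tuple(int(i) for i in midline))


def reflect_configuration(config: LandmarkConfiguration, axis: int = 0) -> LandmarkConfiguration:
    """Mirror a configuration across one coordinate axis (side standardization)."""
    pts = config.points.copy()
    pts[:, axis] *= -1.0
    return LandmarkConfiguration(config.specimen_id, config.element, pts,
                                 list(config.roles), [list(c) for c in config.curves])


def join_metadata(
    configs: Sequence[LandmarkConfiguration],
    meta: Sequence[SpecimenMetadata],
) -> MorphDataset:
    """Inner-join configurations with metadata on (specimen_id, element).

    Configurations without a metadata row are reported in ``unmatched`` and
    excluded.  Duplicate specimen ids within an element are an error.
    """
    if not configs:
        raise ValidationError("no configurations to join")
    element = configs[0].element
    seen: set[str] = set()
    for c in configs:
        if c.element != element:
            raise ValidationError("join_metadata expects a single element per call")
        if c.specimen_id in seen:
            raise ValidationError(f"duplicate specimen_id {c.specimen_id!r} in element {element}")
        seen.add(c.specimen_id)
    meta_map: dict[str, str] = {}
    for m in meta:
        if m.element != element:
            continue
        if m.specimen_id in meta_map:
            raise ValidationError(f"duplicate specimen_id {m.specimen_id!r} in metadata")
        meta_map[m.specimen_id] = m.group
    matched = [c for c in configs if c.specimen_id in meta_map]
    unmatched = [c.specimen_id for c in configs if c.specimen_id not in meta_map]
    if unmatched:
        logger.warning("%d configurations without metadata: %s", len(unmatched), unmatched)
    return MorphDataset(
        element=element,
        configs=matched,
        groups={c.specimen_id: meta_map[c.specimen_id] for c in matched},
        unmatched=unmatched,
    )
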