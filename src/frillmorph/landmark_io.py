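"""Reading, writing and editing 2D landmark configurations.

Landmark data live in TPS files (``LM=`` / coordinate lines / ``ID=`` /
optional ``SCALE=`` records, y increasing upward).  TPS cannot express which
points are fixed landmarks versus curve semilandmarks, so each TPS file may be
accompanied by a sidecar role table (CSV with header ``index,role,curve,side``,
1-based indices) and a specimen metadata table
(``specimen_id,species,group,stage,basal_skull_length_mm``).

Indices are 1-based in files and 0-based in memory.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "SpecimenMeta",
    "read_tps",
    "write_tps",
    "read_role_table",
    "read_metadata",
    "resample_curve",
    "mirror_fill",
    "subset_landmarks",
]

ROLE_FIXED = "fixed"
ROLE_SEMI = "semilandmark"


class TPSParseError(ValueError):
    """Raised when a TPS record is malformed."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark/semilandmark configuration."""

    specimen_id: str
    coords: np.ndarray  # (k, 2)
    species: str = ""
    group: str = "other"
    roles: list[str] = field(default_factory=list)  # per point: fixed|semilandmark
    midline_ids: list[int] = field(default_factory=list)  # 0-based
    pair_map: list[tuple[int, int]] = field(default_factory=list)  # (left, right), 0-based
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinate in specimen {self.specimen_id!r}")
        k = len(self.coords)
        if not self.roles:
            self.roles = [ROLE_FIXED] * k
        if len(self.roles) != k:
            raise ValueError("roles length must equal number of points")
        paired = {i for pair in self.pair_map for i in pair}
        for idx in list(self.midline_ids) + sorted(paired):
            if not 0 <= idx < k:
                raise ValueError(f"point index {idx} out of range for {k} points")
        overlap = paired & set(self.midline_ids)
        if overlap:
            raise ValueError(f"indices {sorted(overlap)} appear in both midline_ids and pair_map")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def copy(self) -> "LandmarkConfiguration":
        return replace(
            self,
            coords=self.coords.copy(),
            roles=list(self.roles),
            midline_ids=list(self.midline_ids),
            pair_map=list(self.pair_map),
        )


@dataclass
class SpecimenMeta:
    """Per-specimen metadata (ontogenetic stage and basal skull length)."""

    specimen_id: str
    species: str = ""
    group: str = "other"
    stage: str = "unknown"
    basal_skull_length: float | None = None

    def __post_init__(self) -> None:
        if self.basal_skull_length is not None and not self.basal_skull_length > 0:
            raise ValueError("basal_skull_length must be positive when present")


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into a list of configurations, in file order.

    Coordinates are multiplied by the record's SCALE when present.  Roles and
    symmetry structure are not stored in TPS; apply them afterwards from a
    sidecar table (see :func:`read_role_table`).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{path}:{i + 1}: expected LM= line, got {line!r}")
        try:
            n_points = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}:{i + 1}: malformed LM= line {line!r}") from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < n_points:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row:
                break  # next keyword; record had too few coordinate lines
            parts = row.split()
            if len(parts) != 2:
                raise TPSParseError(f"{path}:{i + 1}: expected 'x y', got {row!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(f"{path}:{i + 1}: non-numeric coordinate {row!r}") from exc
            i += 1
        if len(coords) != n_points:
            raise TPSParseError(
                f"{path}: record starting with LM={n_points} has {len(coords)} coordinate lines"
            )
        specimen_id = ""
        scale: float | None = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            upper = row.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("ID="):
                specimen_id = row.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(row.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSParseError(f"{path}:{i + 1}: malformed SCALE line") from exc
            # other keywords (IMAGE=, COMMENT=) are ignored
            i += 1
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        configs.append(LandmarkConfiguration(specimen_id=specimen_id, coords=arr, scale=scale))
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file; :func:`read_tps` inverts it.

    Stored coordinates are divided by the scale (when set) so that the
    SCALE= line restores them on read.
    """
    if not configs:
        raise ValueError("cannot write an empty configuration sequence")
    out = []
    for cfg in configs:
        out.append(f"LM={cfg.n_points}")
        coords = cfg.coords if cfg.scale is None else cfg.coords / cfg.scale
        for x, y in coords:
            out.append(f"{x:.12g} {y:.12g}")
        out.append(f"ID={cfg.specimen_id}")
        if cfg.scale is not None:
            out.append(f"SCALE={cfg.scale:.12g}")
    Path(path).write_text("\n".join(out) + "\n")


def read_role_table(path: str | Path) -> dict:
    """Read a sidecar role table CSV (``index,role,curve,side``; 1-based index).

    Returns a dict with keys ``roles`` (list, file order by index), ``curves``
    (curve id -> ordered 0-based point indices), ``midline_ids`` and
    ``pair_map`` built from the ``side`` column (mid | left | right; left/right
    rows are paired by order of appearance on each side).
    """
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(rec)
    rows.sort(key=lambda r: int(r["index"]))
    roles = []
    curves: dict[str, list[int]] = {}
    mids: list[int] = []
    left: list[int] = []
    right: list[int] = []
    for rec in rows:
        idx = int(rec["index"]) - 1
        roles.append(rec["role"].strip())
        curve = (rec.get("curve") or "").strip()
        if curve:
            curves.setdefault(curve, []).append(idx)
        side = (rec.get("side") or "").strip().lower()
        if side == "mid":
            mids.append(idx)
        elif side == "left":
            left.append(idx)
        elif side == "right":
            right.append(idx)
    if len(left) != len(right):
        raise ValueError(f"unbalanced sides: {len(left)} left vs {len(right)} right points")
    return {
        "roles": roles,
        "curves": curves,
        "midline_ids": mids,
        "pair_map": list(zip(left, right)),
    }


def apply_role_table(cfg: LandmarkConfiguration, table: dict) -> LandmarkConfiguration:
    """Return a copy of *cfg* with roles/midline/pair structure from a role table."""
    if len(table["roles"]) != cfg.n_points:
        raise ValueError("role table length does not match configuration")
    out = cfg.copy()
    out.roles = list(table["roles"])
    out.midline_ids = list(table["midline_ids"])
    out.pair_map = list(table["pair_map"])
    return out


def read_metadata(path: str | Path) -> dict[str, SpecimenMeta]:
    """Read specimen metadata CSV keyed by specimen_id."""
    out: dict[str, SpecimenMeta] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            bsl = rec.get("basal_skull_length_mm", "")
            out[rec["specimen_id"]] = SpecimenMeta(
                specimen_id=rec["specimen_id"],
                species=rec.get("species", ""),
                group=rec.get("group", "other"),
                stage=rec.get("stage", "unknown"),
                basal_skull_length=float(bsl) if bsl not in ("", None) else None,
            )
    return out


def resample_curve(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline into *n* points evenly spaced by arc length.

    The first and last output points coincide with the polyline endpoints.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 polyline points")
    if n < 2:
        raise ValueError("n must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate polyline of zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, total, n)
    out = np.empty((n, pts.shape[1]))
    # interpolate each coordinate along cumulative arc length
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(target, cum, pts[:, d])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def _fit_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: returns (point on line, unit direction)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    if np.allclose(centered, 0.0):
        raise ValueError("coincident midline points: sagittal axis undefined")
    # principal direction of the midline scatter
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[0]


def _reflect(points: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = points - origin
    along = rel @ direction
    proj = np.outer(along, direction)
    return origin + 2 * proj - rel


def mirror_fill(cfg: LandmarkConfiguration, use_side: str) -> LandmarkConfiguration:
    """Replace one bilateral side by the mirror of the other across the sagittal axis.

    The axis is the total-least-squares line through the midline points; those
    points are snapped onto it so the output is exactly symmetric.  *use_side*
    names the preserved (better-preserved) side: ``"left"`` or ``"right"``.
    """
    if use_side not in ("left", "right"):
        raise ValueError("use_side must be 'left' or 'right'")
    if len(cfg.midline_ids) < 2:
        raise ValueError("need >=2 midline points to define the sagittal axis")
    if not cfg.pair_map:
        raise ValueError("pair_map is empty; nothing to mirror")
    origin, direction = _fit_axis(cfg.coords[cfg.midline_ids])
    out = cfg.copy()
    # snap midline points onto the axis
    mid = cfg.coords[cfg.midline_ids]
    along = (mid - origin) @ direction
    out.coords[cfg.midline_ids] = origin + np.outer(along, direction)
    for left_i, right_i in cfg.pair_map:
        keep, fill = (left_i, right_i) if use_side == "left" else (right_i, left_i)
        out.coords[fill] = _reflect(cfg.coords[keep][None, :], origin, direction)[0]
    return out


def subset_landmarks(cfg: LandmarkConfiguration, keep_ids: Sequence[int]) -> LandmarkConfiguration:
    """Restrict a configuration to *keep_ids* (0-based), reindexing in place order.

    Bilateral pairs split by the subset are dropped from ``pair_map`` with a
    warning.
    """
    keep = sorted(set(int(i) for i in keep_ids))
    if not keep:
        raise ValueError("keep_ids must be nonempty")
    for i in keep:
        if not 0 <= i < cfg.n_points:
            raise ValueError(f"keep id {i} out of range")
    remap = {old: new for new, old in enumerate(keep)}
    pairs = []
    for a, b in cfg.pair_map:
        if a in remap and b in remap:
            pairs.append((remap[a], remap[b]))
        elif a in remap or b in remap:
            warnings.warn(f"bilateral pair ({a}, {b}) split by subset; dropped")
    return LandmarkConfiguration(
        specimen_id=cfg.specimen_id,
        species=cfg.species,
        group=cfg.group,
        coords=cfg.coords[keep],
        roles=[cfg.roles[i] for i in keep],
        midline_ids=[remap[i] for i in cfg.midline_ids if i in remap],
        pair_map=pairs,
        scale=cfg.scale,
    )
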