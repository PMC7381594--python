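"""Generalized Procrustes superimposition of 2D landmark configurations.

Partial Procrustes: configurations are centered, scaled to unit centroid size
and rotated (proper rotations only — mirroring is a deliberate preprocessing
step, never part of alignment) to a consensus re-estimated each iteration.
Centroid size is carried separately as the size variable for allometry.
Semilandmarks are treated as fixed points during superimposition; a sliding
strategy can be hooked in later without changing the interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landmark_io import LandmarkConfiguration

__all__ = ["AlignedSample", "centroid_size", "opa_align", "gpa", "mean_shape"]


@dataclass
class AlignedSample:
    """A Procrustes-superimposed sample.

    ``shapes`` holds one row per specimen, coordinates flattened as
    (x1, y1, x2, y2, ...).  ``centroid_sizes`` are the original sizes removed
    during scaling.
    """

    shapes: np.ndarray  # (n, 2k)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2)
    specimen_ids: list[str]
    converged: bool
    iterations: int
    tangent_projected: bool

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1] // 2

    def shape_of(self, specimen_id: str) -> np.ndarray:
        """Aligned (k, 2) coordinates of one specimen."""
        idx = self.specimen_ids.index(specimen_id)
        return self.shapes[idx].reshape(-1, 2)


def _as_matrix(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return np.asarray(config.coords, dtype=float)
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Root summed squared distances of the points from their centroid."""
    coords = _as_matrix(config)
    if len(coords) < 2:
        raise ValueError("need at least 2 points")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValueError("all points coincident: centroid size undefined")
    return cs


def _preshape(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs == 0.0:
        raise ValueError("degenerate configuration")
    return centered / cs


def _optimal_rotation(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R minimizing ||target @ R - reference||."""
    u, _, vt = np.linalg.svd(target.T @ reference)
    d = np.sign(np.linalg.det(u @ vt))
    # force det(R) = +1: reflections are never allowed in alignment
    correction = np.diag([1.0, d])
    return u @ correction @ vt


def opa_align(target, reference) -> tuple[np.ndarray, float, float]:
    """Ordinary Procrustes alignment of *target* onto *reference*.

    Both are centered and scaled to unit centroid size; the target is then
    rotated (no reflection) to minimize the summed squared distance to the
    reference.  Returns ``(aligned_target, rotation_angle_rad, residual)``.
    """
    t = _as_matrix(target)
    r = _as_matrix(reference)
    if t.shape != r.shape:
        raise ValueError(f"point-count mismatch: {t.shape} vs {r.shape}")
    t = _preshape(t)
    r = _preshape(r)
    rot = _optimal_rotation(t, r)
    aligned = t @ rot
    angle = float(np.arctan2(rot[0, 1], rot[0, 0]))
    residual = float(np.sum((aligned - r) ** 2))
    return aligned, angle, residual


def gpa(
    configs: Sequence,
    tol: float = 1e-8,
    max_iter: int = 100,
    tangent: bool = True,
) -> AlignedSample:
    """Generalized Procrustes analysis.

    Iterates ordinary alignment of every configuration to a provisional
    consensus until the consensus stabilises (root-mean-square coordinate
    change < *tol*).  With ``tangent=True`` (default) the unit-size aligned
    shapes are orthogonally projected onto the tangent space at the consensus,
    the standard linearisation for downstream PCA and regression.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    mats = [_as_matrix(c) for c in configs]
    k = mats[0].shape[0]
    for m in mats:
        if m.shape != (k, 2):
            raise ValueError("mixed point counts across configurations")
    ids = [
        c.specimen_id if isinstance(c, LandmarkConfiguration) else f"specimen_{i}"
        for i, c in enumerate(configs)
    ]
    sizes = np.array([centroid_size(m) for m in mats])
    shapes = np.stack([_preshape(m) for m in mats])  # (n, k, 2)

    consensus = shapes[0].copy()
    converged = False
    prev_obj = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(shapes)):
            rot = _optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ rot
        new_consensus = _preshape(shapes.mean(axis=0))
        obj = float(np.sum((shapes - new_consensus[None]) ** 2))
        if obj > prev_obj + 1e-12:
            raise RuntimeError("GPA objective increased; alignment is diverging")
        prev_obj = obj
        delta = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last RMS change {delta:.3e})"
        )

    flat = shapes.reshape(len(shapes), -1)
    if tangent:
        m = consensus.reshape(-1)
        m = m / np.linalg.norm(m)
        # orthogonal projection onto the tangent space at the consensus
        flat = flat - np.outer(flat @ m, m) + m[None, :]
    return AlignedSample(
        shapes=flat,
        centroid_sizes=sizes,
        consensus=flat.mean(axis=0).reshape(-1, 2),
        specimen_ids=ids,
        converged=converged,
        iterations=iterations,
        tangent_projected=tangent,
    )


def mean_shape(sample: AlignedSample, subset: Sequence[str] | None = None) -> np.ndarray:
    """Coordinate-wise mean (k, 2) of the selected aligned shapes."""
    if subset is None:
        rows = sample.shapes
    else:
        subset = list(subset)
        if not subset:
            raise ValueError("subset must be nonempty")
        try:
            idx = [sample.specimen_ids.index(s) for s in subset]
        except ValueError as exc:
            raise KeyError(f"unknown specimen id in subset: {exc}") from exc
        rows = sample.shapes[idx]
    return rows.mean(axis=0).reshape(-1, 2)
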