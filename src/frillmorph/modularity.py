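"""Covariance-ratio (CR) test of landmark modularity.

The CR coefficient compares between-module landmark covariation with
within-module covariation.  With S the coordinate covariance matrix
partitioned into within-module blocks S11, S22 and the between block S12:

    CR = sqrt( tr(S12 S21) / sqrt( tr(S11* S11*) * tr(S22* S22*) ) )

where * zeroes the block diagonals.  CR < 1 indicates stronger covariation
within modules than between them (modularity); the null distribution comes
from reassigning whole landmarks (x and y together) to modules of the same
sizes at random.  The test is left-tailed: low CR is evidence of modularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Partition", "CRResult", "cr", "cr_test", "semilandmark_sensitivity"]


@dataclass
class Partition:
    """Per-landmark module labels (two or more modules, >=2 landmarks each)."""

    module_of: list[str]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for m in self.module_of:
            counts[m] = counts.get(m, 0) + 1
        if len(counts) < 2:
            raise ValueError("partition needs at least 2 modules")
        small = [m for m, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"modules {small} have fewer than 2 landmarks")
        self.modules = sorted(counts)

    def indices(self, module: str) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.module_of) if m == module])

    @property
    def n_landmarks(self) -> int:
        return len(self.module_of)


@dataclass
class CRResult:
    cr_observed: float
    null_distribution: np.ndarray
    n_permutations: int
    p_value: float
    seed: int


def _coord_cols(landmark_idx: np.ndarray) -> np.ndarray:
    """Column indices in the flattened (x1,y1,x2,y2,...) matrix for landmarks."""
    return np.stack([2 * landmark_idx, 2 * landmark_idx + 1], axis=1).ravel()


def _pairwise_cr(S: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray) -> float:
    S12 = S[np.ix_(cols_a, cols_b)]
    S11 = S[np.ix_(cols_a, cols_a)].copy()
    S22 = S[np.ix_(cols_b, cols_b)].copy()
    np.fill_diagonal(S11, 0.0)
    np.fill_diagonal(S22, 0.0)
    between = np.sum(S12 * S12)  # tr(S12 S21)
    within = np.sqrt(np.sum(S11 * S11) * np.sum(S22 * S22))
    if within <= 0:
        raise ValueError("a module has zero off-diagonal covariance mass; CR undefined")
    return float(np.sqrt(between / within))


def cr(aligned_shapes: np.ndarray, partition: Partition) -> float:
    """Covariance ratio of a landmark partition.

    *aligned_shapes* is a specimens x 2k matrix of superimposed coordinates.
    Both coordinates of a landmark go to that landmark's module.  For more
    than two modules, the average pairwise CR is returned.
    """
    X = np.asarray(aligned_shapes, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    if X.shape[1] != 2 * partition.n_landmarks:
        raise ValueError("partition size does not match coordinate count")
    S = np.cov(X, rowvar=False)
    values = []
    for a, b in combinations(partition.modules, 2):
        cols_a = _coord_cols(partition.indices(a))
        cols_b = _coord_cols(partition.indices(b))
        values.append(_pairwise_cr(S, cols_a, cols_b))
    return float(np.mean(values))


def cr_test(
    aligned_shapes: np.ndarray,
    partition: Partition,
    n_permutations: int = 10000,
    seed: int = 0,
) -> CRResult:
    """Left-tailed permutation test of the CR coefficient.

    The null reassigns whole landmarks to modules of the same sizes uniformly
    at random; p = (1 + #{null <= observed}) / (1 + n_permutations), so a low
    observed CR (strong modularity) gives a small p.
    """
    X = np.asarray(aligned_shapes, dtype=float)
    observed = cr(X, partition)
    rng = np.random.default_rng(seed)
    labels = np.asarray(partition.module_of)
    null = np.empty(n_permutations)
    kept = 0
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        try:
            null[kept] = cr(X, Partition(list(perm)))
            kept += 1
        except ValueError:
            continue  # degenerate random partition; draw again implicitly
    null = null[:kept]
    p = (1 + int(np.sum(null <= observed))) / (1 + kept)
    return CRResult(
        cr_observed=observed,
        null_distribution=null,
        n_permutations=kept,
        p_value=float(p),
        seed=seed,
    )


def semilandmark_sensitivity(
    aligned_shapes: np.ndarray,
    partition: Partition,
    roles: Sequence[str],
    remove_counts: Sequence[int] = (10, 20, 28),
    replicates: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the CR test with random semilandmark subsets removed.

    Guards against the possibility that a modularity signal is an artifact of
    densely sampled curve semilandmarks.  For each removal count and
    replicate, semilandmarks are dropped at random (stratified proportionally
    across modules) and the CR test re-run on the reduced configuration.
    Returns rows ``(remove_count, replicate, cr, p)``.
    """
    X = np.asarray(aligned_shapes, dtype=float)
    roles = list(roles)
    if len(roles) != partition.n_landmarks:
        raise ValueError("roles length does not match partition")
    semis_by_module = {
        m: [i for i in partition.indices(m) if roles[i] != "fixed"] for m in partition.modules
    }
    n_semi = sum(len(v) for v in semis_by_module.values())
    rng = np.random.default_rng(seed)
    rows = []
    for count in remove_counts:
        if count >= n_semi:
            raise ValueError(f"cannot remove {count} of {n_semi} semilandmarks")
        for rep in range(replicates if count > 0 else 1):
            if count == 0:
                res = cr_test(X, partition, n_permutations, seed)
            else:
                # proportional stratification over modules, remainder at random
                quota = {
                    m: int(round(count * len(v) / n_semi)) for m, v in semis_by_module.items()
                }
                # fix rounding drift
                drift = count - sum(quota.values())
                mods = sorted(semis_by_module, key=lambda m: -len(semis_by_module[m]))
                i = 0
                while drift != 0:
                    m = mods[i % len(mods)]
                    step = 1 if drift > 0 else -1
                    if 0 <= quota[m] + step <= len(semis_by_module[m]):
                        quota[m] += step
                        drift -= step
                    i += 1
                drop: set[int] = set()
                for m, pool in semis_by_module.items():
                    take = min(quota[m], len(pool))
                    drop.update(rng.choice(pool, size=take, replace=False))
                keep = [i for i in range(partition.n_landmarks) if i not in drop]
                sub = Partition([partition.module_of[i] for i in keep])
                cols = _coord_cols(np.asarray(keep))
                res = cr_test(X[:, cols], sub, n_permutations, int(rng.integers(2**31)))
            rows.append(
                {
                    "remove_count": count,
                    "replicate": rep,
                    "cr": res.cr_observed,
                    "p": res.p_value,
                }
            )
    return pd.DataFrame(rows)
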