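"""Pairwise permutational ANOVA of group differences along ordination axes.

Each comparison is a two-group one-way ANOVA of per-species scores on one
pPC axis, with the p-value computed by permuting group labels within the
pair.  The raw permutation proportion (#{F_perm >= F_obs} / n_permutations)
is reported alongside the (+1)-corrected estimator, which can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PermAnovaResult", "pairwise_perm_anova"]


@dataclass
class PermAnovaResult:
    axis: int
    group1: str
    group2: str
    F: float
    df1: int
    df2: int
    p: float  # raw permutation proportion (can be 0)
    p_corrected: float  # (1+b)/(1+m) estimator
    n_permutations: int
    seed: int


def _anova_f(values: np.ndarray, mask1: np.ndarray) -> float:
    """Closed-form one-way F for two groups given a boolean membership mask."""
    g1 = values[mask1]
    g2 = values[~mask1]
    n1, n2 = len(g1), len(g2)
    grand = values.mean()
    ss_between = n1 * (g1.mean() - grand) ** 2 + n2 * (g2.mean() - grand) ** 2
    ss_within = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    df2 = n1 + n2 - 2
    if ss_within <= 0:
        return np.inf
    return float(ss_between / (ss_within / df2))


def pairwise_perm_anova(
    scores: Mapping[str, float],
    groups: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    n_permutations: int = 1000,
    seed: int = 0,
    axis: int = 1,
) -> list[PermAnovaResult]:
    """Permutational ANOVA for each requested pair of groups.

    *scores* maps species to their score on one axis; *groups* maps species
    to a group label.  Each group in a pair must have at least 2 members.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[float]] = {}
    for sp, score in scores.items():
        by_group.setdefault(groups[sp], []).append(float(score))
    results = []
    for g1, g2 in pairs:
        for g in (g1, g2):
            if len(by_group.get(g, [])) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 members")
        v1 = np.asarray(by_group[g1])
        v2 = np.asarray(by_group[g2])
        values = np.concatenate([v1, v2])
        mask1 = np.zeros(len(values), dtype=bool)
        mask1[: len(v1)] = True
        f_obs = _anova_f(values, mask1)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(values))
            if _anova_f(values[perm], mask1) >= f_obs:
                count += 1
        results.append(
            PermAnovaResult(
                axis=axis,
                group1=g1,
                group2=g2,
                F=f_obs,
                df1=1,
                df2=len(values) - 2,
                p=count / n_permutations,
                p_corrected=(1 + count) / (1 + n_permutations),
                n_permutations=n_permutations,
                seed=seed,
            )
        )
    return results


def results_table(results: Sequence[PermAnovaResult]) -> pd.DataFrame:
    """Tabulate permutational ANOVA results (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "axis": f"PC{r.axis}",
                "group1": r.group1,
                "group2": r.group2,
                "F": r.F,
                "df1": r.df1,
                "df2": r.df2,
                "p": r.p,
                "p_corrected": r.p_corrected,
            }
            for r in results
        ]
    )
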