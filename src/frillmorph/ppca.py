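"""Phylogenetic principal components analysis of aligned shape coordinates.

PCA of the evolutionary (rate) covariance matrix estimated by generalized
least squares under Brownian motion: with C the shared-path matrix of the
time tree and X the species-by-coordinate shape matrix, the phylogenetic mean
is a = (1'C^-1 1)^-1 1'C^-1 X and the evolutionary covariance
R = (X - 1a)' C^-1 (X - 1a) / (n - 1).  Scores are projections of the
(non-whitened) centered data on the eigenvectors of R, so that on a star tree
with equal branch lengths the analysis reduces to ordinary PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .phylo_core import TimeTree, vcv

__all__ = ["PPCAResult", "phylo_pca", "axis_extremes"]


@dataclass
class PPCAResult:
    eigenvalues: np.ndarray  # descending, >= 0
    percent_variance: np.ndarray  # sums to 100
    loadings: np.ndarray  # (2k, n_axes), orthonormal columns
    scores: pd.DataFrame  # species x axes, columns PC1..
    phylo_mean: np.ndarray  # (2k,)
    mode: str  # covariance | correlation


def phylo_pca(shapes: pd.DataFrame, ttree: TimeTree, mode: str = "covariance") -> PPCAResult:
    """Phylogenetic PCA of a species-by-coordinate matrix on a time tree.

    *shapes* must be indexed by species names matching the tree's tips exactly
    (one row per species).  ``mode="correlation"`` rescales the evolutionary
    covariance to a correlation matrix before the eigen-decomposition.
    """
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    tips = set(ttree.tip_labels)
    species = set(shapes.index)
    if tips != species:
        missing = sorted(tips - species)
        extra = sorted(species - tips)
        raise ValueError(f"species/tip mismatch: missing from data {missing}, not in tree {extra}")
    order = [l for l in ttree.tip_labels]
    X = shapes.loc[order].to_numpy(dtype=float)
    C = vcv(ttree).loc[order, order].to_numpy()
    n = len(order)

    cf = cho_factor(C)
    ones = np.ones((n, 1))
    Ci1 = cho_solve(cf, ones)
    a = (Ci1.T @ X) / float((ones.T @ Ci1).item())  # (1, 2k) phylogenetic (GLS) mean
    Xc = X - a
    R = Xc.T @ cho_solve(cf, Xc) / (n - 1)
    if mode == "correlation":
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)

    evals, evecs = np.linalg.eigh(R)
    idx = np.argsort(evals)[::-1]
    evals = np.clip(evals[idx], 0.0, None)
    evecs = evecs[:, idx]
    n_axes = min(n - 1, X.shape[1])
    evals = evals[:n_axes]
    evecs = evecs[:, :n_axes]
    # fix axis sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        peak = np.argmax(np.abs(evecs[:, j]))
        if evecs[peak, j] < 0:
            evecs[:, j] *= -1.0
    scores = Xc @ evecs
    total = evals.sum()
    percent = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return PPCAResult(
        eigenvalues=evals,
        percent_variance=percent,
        loadings=evecs,
        scores=pd.DataFrame(
            scores, index=order, columns=[f"PC{j + 1}" for j in range(n_axes)]
        ),
        phylo_mean=a.ravel(),
        mode=mode,
    )


def axis_extremes(result: PPCAResult, axis: int) -> tuple[dict, dict]:
    """Species at the negative and positive extremes of a pPC axis.

    Returns two dicts with keys ``species``, ``score`` and ``deformation``
    (the species' difference from the phylogenetic mean, as a (k, 2) array).
    Ties are broken by species-name order with a warning.
    """
    col = result.scores.iloc[:, axis]
    lo_val, hi_val = col.min(), col.max()
    lo_ties = sorted(col.index[col == lo_val])
    hi_ties = sorted(col.index[col == hi_val])
    if len(lo_ties) > 1 or len(hi_ties) > 1:
        warnings.warn("tie for axis extreme; first species by name order used")
    out = []
    for name, val in ((lo_ties[0], lo_val), (hi_ties[0], hi_val)):
        # deformation reconstructed from the retained axes
        row_scores = result.scores.loc[name].to_numpy()
        deform = (result.loadings @ row_scores).reshape(-1, 2)
        out.append({"species": name, "score": float(val), "deformation": deform})
    return out[0], out[1]
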