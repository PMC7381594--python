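"""Allometric regression and phylogenetic heterochrony inference.

The procedure: (1) pool specimens across species and regress Procrustes shape
coordinates on log centroid size; (2) collapse each shape to its regression
score, the projection onto the normalized multivariate allometric vector;
(3) summarise each ontogenetically sampled species by an ontogenetic vector
connecting its smallest and largest specimens in the (log CS, score) plane;
(4) reconstruct ancestral vectors by squared-change parsimony of the four
endpoint coordinates on the time tree; (5) classify each ancestor-descendant
branch: an adult-score increase beyond 1.5x the CI half-width of the mean
branch difference is peramorphosis, a symmetric decrease paedomorphosis;
(6) estimate per-branch rates (score change per Ma) and test vector-angle
changes against a bounded-uniform randomization null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_core import TimeTree, sqcp_ancestral

__all__ = [
    "AllometricModel",
    "OntogeneticVector",
    "ShiftRecord",
    "pooled_regression",
    "regression_score",
    "ontogenetic_vector",
    "ancestral_vectors",
    "shift_table",
    "vector_angle",
    "angle_randomization_test",
    "classify_modes",
]


@dataclass
class AllometricModel:
    """Multivariate regression of shape on log centroid size."""

    b: np.ndarray  # (2k,) per-coordinate slopes
    intercept: np.ndarray  # (2k,)
    mean_shape: np.ndarray  # (2k,) pooled mean, the centering reference
    slope_scalar: float  # slope of regression score on log CS
    F: float
    p: float
    n: int


@dataclass
class OntogeneticVector:
    """A species' (or ancestor's) growth trajectory endpoints.

    Both endpoints live in the (log centroid size, regression score) plane.
    """

    label: str
    juvenile: tuple[float, float]
    adult: tuple[float, float]
    reconstructed: bool = False

    @property
    def displacement(self) -> np.ndarray:
        return np.array(
            [self.adult[0] - self.juvenile[0], self.adult[1] - self.juvenile[1]]
        )


@dataclass
class ShiftRecord:
    """One ancestor->descendant branch's allometric shift."""

    ancestor: str
    descendant: str
    delta_score: float  # descendant adult score - ancestor adult score
    threshold: float  # 1.5 x CI half-width of the mean branch difference
    classification: str  # peramorphosis | paedomorphosis | none
    branch_length: float  # Ma
    rate: float  # delta_score per Ma
    rate_quartile: int | None = None  # 1 (slowest) .. 4 (fastest) by |rate|
    angle_deg: float | None = None
    angle_percentile: float | None = None


def pooled_regression(
    aligned_shapes: np.ndarray,
    log_cs: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> AllometricModel:
    """Pooled multivariate least-squares regression of shape on log centroid size.

    Every coordinate is regressed on log CS; the stacked slopes form the
    allometric vector b, and the scalar slope is that of the regression score
    on log CS (identical to ||b|| scaled by the score normalisation).  The
    significance of allometry is assessed with Goodall's F — total shape sum
    of squares explained by size over residual — and a permutation p-value
    (sizes shuffled across specimens).  A naive parametric F-test of score on
    size would be circular, since the score is the projection onto the fitted
    direction, and rejects almost surely under the null.
    """
    X = np.asarray(aligned_shapes, dtype=float)
    s = np.asarray(log_cs, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    if np.ptp(s) == 0:
        raise ValueError("log centroid size is constant")
    Xm = X.mean(axis=0)
    Xc = X - Xm
    df2 = len(s) - 2

    def goodall_f(size: np.ndarray) -> tuple[np.ndarray, float]:
        sc = size - size.mean()
        slopes = (sc @ Xc) / float(sc @ sc)
        fitted = np.outer(sc, slopes)
        ss_model = float(np.sum(fitted**2))
        ss_res = float(np.sum((Xc - fitted) ** 2))
        if ss_res <= 0:
            return slopes, np.inf
        return slopes, ss_model / (ss_res / df2)

    b, F_obs = goodall_f(s)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        _, F_perm = goodall_f(s[rng.permutation(len(s))])
        if F_perm >= F_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    intercept = Xm - b * s.mean()
    model = AllometricModel(
        b=b, intercept=intercept, mean_shape=Xm, slope_scalar=np.nan, F=float(F_obs),
        p=float(p), n=len(s),
    )
    scores = np.array([regression_score(model, x) for x in X])
    res = stats.linregress(s, scores)
    model.slope_scalar = float(res.slope)
    return model


def regression_score(model: AllometricModel, shape: np.ndarray) -> float:
    """Projection of a centered shape onto the unit allometric vector b/||b||."""
    norm = np.linalg.norm(model.b)
    if norm == 0:
        raise ValueError("allometric vector has zero norm")
    return float((np.asarray(shape, dtype=float) - model.mean_shape) @ (model.b / norm))


def ontogenetic_vector(
    label: str,
    log_cs: Sequence[float],
    scores: Sequence[float],
    specimen_ids: Sequence[str] | None = None,
) -> OntogeneticVector:
    """Growth vector connecting the smallest and largest sampled specimens.

    Endpoints are chosen by centroid size; ties are broken by specimen id
    order with a warning.
    """
    s = np.asarray(log_cs, dtype=float)
    sc = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 specimens to form an ontogenetic vector")
    ids = list(specimen_ids) if specimen_ids is not None else [str(i) for i in range(len(s))]
    order = sorted(range(len(s)), key=lambda i: (s[i], ids[i]))
    i_min, i_max = order[0], order[-1]
    if np.sum(s == s[i_min]) > 1 or np.sum(s == s[i_max]) > 1:
        warnings.warn("centroid-size tie at an endpoint; broken by specimen id order")
    return OntogeneticVector(
        label=label,
        juvenile=(float(s[i_min]), float(sc[i_min])),
        adult=(float(s[i_max]), float(sc[i_max])),
    )


def ancestral_vectors(
    ttree: TimeTree, tip_vectors: Mapping[str, OntogeneticVector]
) -> dict[str, OntogeneticVector]:
    """Squared-change-parsimony reconstruction of ancestral growth vectors.

    Each of the four endpoint coordinates (juvenile log CS, juvenile score,
    adult log CS, adult score) is reconstructed independently at every
    internal node of the time tree.
    """
    tips = ttree.tip_labels
    missing = [t for t in tips if t not in tip_vectors]
    if missing:
        raise KeyError(f"missing tip vectors for {missing}")
    components = {
        "jx": {t: tip_vectors[t].juvenile[0] for t in tips},
        "jy": {t: tip_vectors[t].juvenile[1] for t in tips},
        "ax": {t: tip_vectors[t].adult[0] for t in tips},
        "ay": {t: tip_vectors[t].adult[1] for t in tips},
    }
    recon = {key: sqcp_ancestral(ttree, trait) for key, trait in components.items()}
    out = {}
    for node_label in recon["jx"]:
        out[node_label] = OntogeneticVector(
            label=node_label,
            juvenile=(recon["jx"][node_label], recon["jy"][node_label]),
            adult=(recon["ax"][node_label], recon["ay"][node_label]),
            reconstructed=True,
        )
    return out


def _branches(ttree: TimeTree) -> list[tuple[str, str, float]]:
    """(ancestor_label, descendant_label, branch_length) for every branch."""
    out = []
    for node in ttree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = node.taxon.label if node.is_leaf() else node.label
        parent = node.parent_node.label
        out.append((parent, child, float(node.edge.length)))
    return out


def shift_table(
    ttree: TimeTree,
    adult_scores: Mapping[str, float],
    ci_level: float = 0.95,
    ci_multiplier: float = 1.5,
) -> list[ShiftRecord]:
    """Classify every ancestor->descendant branch's allometric shift.

    *adult_scores* must cover every tip and internal node label (the latter
    usually from :func:`ancestral_vectors`).  The significance threshold is
    ``ci_multiplier`` times the t-based CI half-width of the mean of all
    branch score differences; positive exceedances are peramorphosis, negative
    ones paedomorphosis.  Rates are score change per Ma; records are sorted by
    |rate| and tagged with rate quartiles (4 = fastest).
    """
    branches = _branches(ttree)
    deltas = []
    for anc, desc, _bl in branches:
        if anc not in adult_scores or desc not in adult_scores:
            raise KeyError(f"missing adult score for branch {anc}->{desc}")
        deltas.append(adult_scores[desc] - adult_scores[anc])
    deltas = np.asarray(deltas)
    n = len(deltas)
    sem = deltas.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    half_width = stats.t.ppf(0.5 + ci_level / 2, df=n - 1) * sem if n > 1 else 0.0
    threshold = ci_multiplier * float(half_width)
    records = []
    for (anc, desc, bl), d in zip(branches, deltas):
        if d > threshold:
            cls = "peramorphosis"
        elif d < -threshold:
            cls = "paedomorphosis"
        else:
            cls = "none"
        rate = d / bl if bl > 0 else np.nan
        records.append(
            ShiftRecord(
                ancestor=anc,
                descendant=desc,
                delta_score=float(d),
                threshold=threshold,
                classification=cls,
                branch_length=bl,
                rate=float(rate),
            )
        )
    records.sort(key=lambda r: abs(r.rate) if np.isfinite(r.rate) else -1.0)
    finite = [r for r in records if np.isfinite(r.rate)]
    for i, rec in enumerate(finite):
        rec.rate_quartile = min(4, 1 + (4 * i) // len(finite))
    records.sort(key=lambda r: -abs(r.rate) if np.isfinite(r.rate) else 1.0)
    return records


def vector_angle(u: OntogeneticVector | np.ndarray, v: OntogeneticVector | np.ndarray) -> float:
    """Angle in degrees ([0, 180]) between two growth displacement vectors."""
    du = u.displacement if isinstance(u, OntogeneticVector) else np.asarray(u, dtype=float)
    dv = v.displacement if isinstance(v, OntogeneticVector) else np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length ontogenetic vector; angle undefined")
    cosang = np.clip(float(du @ dv) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_randomization_test(
    observed_vectors: Sequence[OntogeneticVector],
    observed_angles: Mapping[str, float] | None = None,
    n_vectors: int = 200,
    seed: int = 0,
) -> dict:
    """Randomization null for growth-vector angles.

    Random displacement vectors are drawn component-wise uniformly within the
    min/max bounds of the observed displacements; angles are measured between
    disjoint successive pairs (1-2, 3-4, ...), giving ``n_vectors/2`` null
    angles.  Each observed angle is reported with its percentile in the null
    (the fraction of null angles it exceeds).
    """
    if len(observed_vectors) < 2:
        raise ValueError("need at least 2 observed vectors")
    disp = np.stack([v.displacement for v in observed_vectors])
    lo = disp.min(axis=0)
    hi = disp.max(axis=0)
    if np.all(hi - lo <= 0):
        raise ValueError("degenerate bounds: all observed displacements identical")
    rng = np.random.default_rng(seed)
    rand = rng.uniform(lo, hi, size=(n_vectors, 2))
    null = np.array(
        [vector_angle(rand[i], rand[i + 1]) for i in range(0, n_vectors - 1, 2)]
    )
    out = {"null_angles": null, "seed": seed, "percentiles": {}}
    if observed_angles:
        for name, ang in observed_angles.items():
            out["percentiles"][name] = float(np.mean(null < ang))
    return out


def classify_modes(
    vectors: Mapping[str, OntogeneticVector],
    shifts: Sequence[ShiftRecord],
    angle_percentiles: Mapping[str, float] | None = None,
    angle_cutoff: float = 0.85,
) -> pd.DataFrame:
    """Narrative heterochrony labels per ancestor-descendant branch.

    Rules: a branch whose vector-angle percentile exceeds *angle_cutoff* is
    acceleration (descendant slope steeper) or deceleration (shallower);
    effectively parallel vectors shifted toward smaller size and score are
    predisplacement, away postdisplacement, and an extended adult endpoint
    (larger adult size and score along the same line) is hypermorphosis.  A
    significant positive/negative adult-score shift carries the umbrella
    label peramorphosis/paedomorphosis.
    """
    rows = []
    for rec in shifts:
        anc = vectors.get(rec.ancestor)
        desc = vectors.get(rec.descendant)
        if anc is None or desc is None:
            continue
        try:
            ang = vector_angle(anc, desc)
        except ValueError:
            rows.append(
                {"ancestor": rec.ancestor, "descendant": rec.descendant,
                 "angle_deg": np.nan, "mode": "indeterminate",
                 "umbrella": rec.classification, "rule": "zero-length vector"}
            )
            continue
        pct = (angle_percentiles or {}).get(rec.descendant)
        slope = lambda v: v.displacement[1] / v.displacement[0] if v.displacement[0] != 0 else np.inf
        mode, rule = "none", ""
        if ang < 1e-9 and np.allclose(anc.displacement, desc.displacement) and np.allclose(
            anc.juvenile, desc.juvenile
        ):
            mode, rule = "none", "identical vectors"
        elif pct is not None and pct > angle_cutoff:
            if abs(slope(desc)) > abs(slope(anc)):
                mode, rule = "acceleration", f"angle percentile {pct:.2f} > {angle_cutoff}, steeper"
            else:
                mode, rule = "deceleration", f"angle percentile {pct:.2f} > {angle_cutoff}, shallower"
        else:
            # effectively parallel: compare endpoint placement
            d_juv = np.array(desc.juvenile) - np.array(anc.juvenile)
            d_adult = np.array(desc.adult) - np.array(anc.adult)
            scale = max(np.linalg.norm(d_juv), np.linalg.norm(d_adult), 1e-12)
            if np.all(np.abs(d_juv) < 1e-9) and np.all(np.abs(d_adult) < 1e-9):
                mode, rule = "none", "identical vectors"
            elif (
                d_adult[0] > 0
                and d_adult[1] > 0
                and np.linalg.norm(d_juv) < 0.5 * np.linalg.norm(d_adult)
            ):
                # juvenile endpoint (nearly) fixed, adult extended to larger
                # size and score along the shared trajectory
                mode, rule = "hypermorphosis", "parallel, adult endpoint extended"
            elif np.all(d_juv < 0.1 * scale) and np.all(d_adult < 0.1 * scale):
                mode, rule = "predisplacement", "parallel, shifted toward origin"
            elif np.all(d_juv > -0.1 * scale) and np.all(d_adult > -0.1 * scale):
                mode, rule = "postdisplacement", "parallel, shifted away from origin"
            else:
                mode, rule = "indeterminate", "parallel, mixed endpoint shifts"
        rows.append(
            {
                "ancestor": rec.ancestor,
                "descendant": rec.descendant,
                "angle_deg": ang,
                "mode": mode,
                "umbrella": rec.classification,
                "rule": rule,
            }
        )
    return pd.DataFrame(rows)
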