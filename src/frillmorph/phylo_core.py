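"""Phylogeny handling for comparative analyses of fossil taxa.

Covers Newick I/O (via dendropy), time-calibration of a cladogram against
first/last appearance dates, the Brownian-motion shared-path covariance
matrix, Felsenstein's independent contrasts, squared-change-parsimony
ancestral states, and maximum-likelihood Brownian model fits with the Pagel
lambda/kappa/delta tree transformations and a directional-trend variant.

Time-calibration follows the palaeontological convention that a tip's age is
its first appearance datum (FAD); a cladogram dated this way has many
zero-length branches (every oldest tip in a clade, and internal nodes tied to
it), which are made positive either by equal redistribution of time from the
first ancestral branch of positive length ("equal") or by inserting 1 Ma
ghost-lineage segments ("punctuated").
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "TimeTree",
    "EvoModelFit",
    "read_newick",
    "resolve_polytomies",
    "timescale",
    "vcv",
    "pic",
    "pic_regression",
    "sqcp_ancestral",
    "fit_bm_model",
    "model_table",
]

_AGE_EPS = 1e-9


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a literal Newick string."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(text), schema="newick", suppress_internal_node_taxa=False
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip names in tree: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip names in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _min_tip_label(node) -> str:
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve polytomies deterministically with zero-length branches.

    Children of a polytomy are combined pairwise in alphabetical order of the
    smallest tip name they subtend, so repeated runs give the same topology.
    Zero-length branches introduced here are later made positive by
    :func:`timescale`.
    """
    tree = tree.clone(depth=1)
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            children.sort(key=_min_tip_label)
            a, b = children[0], children[1]
            node.remove_child(a)
            node.remove_child(b)
            merged = dendropy.Node(edge_length=0.0)
            merged.add_child(a)
            merged.add_child(b)
            node.add_child(merged)
            children = node.child_nodes()
    return tree


@dataclass
class TimeTree:
    """A calibrated phylogeny with branch lengths in Ma and node ages.

    Node ages (Ma before present) are stored on each node as ``node.age``;
    tip ages equal the species' FAD.
    """

    tree: dendropy.Tree
    tip_ages: dict[str, tuple[float, float]]  # species -> (FAD, LAD)
    root_age: float

    @property
    def tip_labels(self) -> list[str]:
        return tip_labels(self.tree)

    def branch_lengths(self) -> dict:
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                out[node] = node.edge.length
        return out

    def validate(self, tol: float = 1e-6) -> None:
        """Check positive branch lengths and age/path-length consistency."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None or node.edge.length <= 0:
                raise ValueError(f"non-positive branch length at {node}")
        for leaf in self.tree.leaf_node_iter():
            path = 0.0
            node = leaf
            while node.parent_node is not None:
                path += node.edge.length
                node = node.parent_node
            if abs((self.root_age - path) - leaf.age) > tol:
                raise ValueError(
                    f"tip {leaf.taxon.label}: age {leaf.age} inconsistent with "
                    f"root-to-tip path {path}"
                )


def _initial_node_ages(tree: dendropy.Tree, fad: Mapping[str, float]) -> None:
    """Basic dating: every node as old as its oldest descendant tip's FAD."""
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in fad:
                raise KeyError(f"tip {label!r} missing from age table")
            node.age = float(fad[label])
        else:
            node.age = max(c.age for c in node.child_nodes())


def _set_lengths_from_ages(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age


def timescale(
    tree: dendropy.Tree,
    tip_ages: Mapping[str, tuple[float, float]],
    method: str = "equal",
    root_extension: float = 1.0,
) -> TimeTree:
    """Time-calibrate a cladogram from per-tip (FAD, LAD) ages in Ma.

    ``method="equal"``: basic FAD dating, root pushed back by
    *root_extension*, then every zero-length branch absorbs an equal share of
    the first ancestral branch of positive length.

    ``method="punctuated"``: basic FAD dating, then exactly 1.0 Ma is added to
    every zero-length branch (each oldest tip in its clade and the internal
    chain above it), shifting ancestral nodes older so descendant ages stay
    fixed.

    Either way all output branch lengths are strictly positive and tip ages
    equal the FADs.
    """
    fad = {}
    for label, (f, l) in tip_ages.items():
        if f < l:
            raise ValueError(f"{label}: FAD {f} < LAD {l}")
        if f <= 0:
            raise ValueError(f"{label}: FAD must be positive (Ma before present)")
        fad[label] = float(f)
    tree = resolve_polytomies(tree)

    if method == "equal":
        _initial_node_ages(tree, fad)
        root = tree.seed_node
        root.age += float(root_extension)
        if root.age <= max(fad.values()):
            raise ValueError("root_extension too small: root branch still zero")
        # preorder pass: re-space every zero-length branch by borrowing time,
        # equally, from the first ancestral branch of positive length
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            if parent.age - node.age > _AGE_EPS:
                continue
            # walk up to the first ancestor whose incoming branch is positive
            chain = [node, parent]
            top = parent
            while top.parent_node is not None and top.parent_node.age - top.age <= _AGE_EPS:
                top = top.parent_node
                chain.append(top)
            anchor = top.parent_node
            if anchor is None:
                raise ValueError("zero-length branch at the root after extension")
            chain.append(anchor)
            # chain runs node -> ... -> anchor; re-space intermediate ages evenly
            ages = np.linspace(anchor.age, node.age, len(chain))[::-1]
            for n, age in zip(chain, ages):
                n.age = float(age)
    elif method == "punctuated":
        _initial_node_ages(tree, fad)
        # bottom-up: any branch of zero implied duration gets 1 Ma; ancestors
        # shift older, descendant ages stay fixed
        basic_age = {n: n.age for n in tree.preorder_node_iter()}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            new_age = 0.0
            for child in node.child_nodes():
                implied = basic_age[node] - basic_age[child]
                length = 1.0 if implied <= _AGE_EPS else implied
                new_age = max(new_age, child.age + length)
            node.age = new_age
    else:
        raise ValueError(f"unknown method {method!r}")

    _set_lengths_from_ages(tree)
    out = TimeTree(tree=tree, tip_ages=dict(tip_ages), root_age=tree.seed_node.age)
    out.validate()
    return out


def label_internal_nodes(ttree: TimeTree, clades: Mapping[str, Sequence[str]] | None = None) -> None:
    """Label internal nodes, optionally naming clade MRCAs.

    *clades* maps a name (e.g. "Neoceratopsia") to the tips whose MRCA should
    carry it; remaining unlabeled nodes get stable preorder names ``N1, N2...``.
    """
    tree = ttree.tree
    if clades:
        for name, tips in clades.items():
            mrca = tree.mrca(taxon_labels=list(tips))
            mrca.label = name
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            i += 1
            node.label = f"N{i}"


def _node_depths(ttree: TimeTree) -> dict:
    depths = {ttree.tree.seed_node: 0.0}
    for node in ttree.tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def vcv(ttree: TimeTree) -> pd.DataFrame:
    """Shared-path (Brownian motion) covariance matrix among tips.

    ``C[i, j]`` is the path length from the root to the MRCA of tips i and j;
    the diagonal holds root-to-tip path lengths.
    """
    depths = _node_depths(ttree)
    leaves = list(ttree.tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    index = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for leaf in leaves:
        C[index[leaf], index[leaf]] = depths[leaf]
    for node in ttree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        tipsets = [[index[l] for l in c.leaf_iter()] for c in children]
        for a in range(len(tipsets)):
            for b in range(a + 1, len(tipsets)):
                for i in tipsets[a]:
                    for j in tipsets[b]:
                        C[i, j] = C[j, i] = depths[node]
    return pd.DataFrame(C, index=labels, columns=labels)


def _require_binary(ttree: TimeTree) -> None:
    for node in ttree.tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            raise ValueError("tree must be strictly bifurcating (run resolve_polytomies/timescale)")


def pic(ttree: TimeTree, trait: Mapping[str, float]) -> np.ndarray:
    """Felsenstein's standardized independent contrasts (n-1 values for n tips)."""
    _require_binary(ttree)
    values = {}
    adj_length = {}
    for leaf in ttree.tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in trait:
            raise KeyError(f"missing trait value for tip {label!r}")
        values[leaf] = float(trait[label])
        adj_length[leaf] = leaf.edge.length
    contrasts = []
    for node in ttree.tree.postorder_internal_node_iter():
        a, b = node.child_nodes()
        va, vb = values[a], values[b]
        la, lb = adj_length[a], adj_length[b]
        contrasts.append((va - vb) / np.sqrt(la + lb))
        values[node] = (va / la + vb / lb) / (1 / la + 1 / lb)
        extra = la * lb / (la + lb)
        adj_length[node] = (node.edge.length if node.parent_node is not None else 0.0) + extra
    return np.asarray(contrasts)


def pic_regression(
    ttree: TimeTree, x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[float, float, float]:
    """Through-origin regression of y-contrasts on x-contrasts.

    Returns ``(slope, F, p)`` with the F-test on (1, n-2) degrees of freedom.
    """
    cx = pic(ttree, x)
    cy = pic(ttree, y)
    sxx = float(cx @ cx)
    if sxx <= 0:
        raise ValueError("zero variance in x contrasts")
    slope = float(cx @ cy) / sxx
    resid = cy - slope * cx
    df2 = len(cx) - 1  # = n_tips - 2
    if df2 < 1:
        raise ValueError("too few contrasts for an F test")
    ss_reg = slope**2 * sxx
    ss_res = float(resid @ resid)
    if ss_res <= 0:
        return slope, np.inf, 0.0
    F = ss_reg / (ss_res / df2)
    p = float(stats.f.sf(F, 1, df2))
    return slope, float(F), p


def sqcp_ancestral(ttree: TimeTree, trait: Mapping[str, float]) -> dict[str, float]:
    """Branch-length-weighted squared-change parsimony ancestral states.

    Minimizes the sum over branches of (change)^2 / branch length, the same
    objective whose minimizer is the maximum-likelihood Brownian-motion state
    at each internal node.  Returns values keyed by internal node label
    (labels are assigned if missing).
    """
    label_internal_nodes(ttree)
    internals = [n for n in ttree.tree.preorder_node_iter() if not n.is_leaf()]
    idx = {n: i for i, n in enumerate(internals)}
    m = len(internals)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in ttree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        w = 1.0 / node.edge.length
        p = idx[parent]
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise KeyError(f"missing trait value for tip {label!r}")
            A[p, p] += w
            b[p] += w * float(trait[label])
        else:
            c = idx[node]
            A[p, p] += w
            A[c, c] += w
            A[p, c] -= w
            A[c, p] -= w
    values = np.linalg.solve(A, b)
    return {n.label: float(values[idx[n]]) for n in internals}


# ---------------------------------------------------------------------------
# Brownian-motion model fitting with tree transformations


@dataclass
class EvoModelFit:
    """One maximum-likelihood fit of a trait evolution model."""

    model: str  # BM | directional | lambda | kappa | delta
    parameter: float | None  # lambda/kappa/delta estimate; None for BM/directional
    sigma2: float
    root_state: float
    beta: float | None  # directional trend per Ma (directional only)
    loglik: float
    aicc: float
    n: int
    k_params: int


def _transform_C(ttree: TimeTree, C: np.ndarray, model: str, theta: float) -> np.ndarray:
    if model == "lambda":
        out = C * theta
        np.fill_diagonal(out, np.diag(C))
        return out
    if model == "delta":
        return np.power(C, theta)
    if model == "kappa":
        # raise each branch length to power kappa, then rebuild shared paths
        kdepth = {ttree.tree.seed_node: 0.0}
        for node in ttree.tree.preorder_node_iter():
            if node.parent_node is not None:
                kdepth[node] = kdepth[node.parent_node] + node.edge.length**theta
        leaves = list(ttree.tree.leaf_node_iter())
        index = {l: i for i, l in enumerate(leaves)}
        n = len(leaves)
        out = np.zeros((n, n))
        for leaf in leaves:
            out[index[leaf], index[leaf]] = kdepth[leaf]
        for node in ttree.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            tipsets = [[index[l] for l in c.leaf_iter()] for c in node.child_nodes()]
            for a in range(len(tipsets)):
                for bb in range(a + 1, len(tipsets)):
                    for i in tipsets[a]:
                        for j in tipsets[bb]:
                            out[i, j] = out[j, i] = kdepth[node]
        return out
    raise ValueError(f"no transformation for model {model!r}")


def _profile_loglik(
    x: np.ndarray, C: np.ndarray, W: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """GLS-profiled Gaussian log-likelihood; returns (loglik, coef, sigma2)."""
    n = len(x)
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("transformed covariance matrix is not positive definite") from exc
    Ci_W = cho_solve(cf, W)
    Ci_x = cho_solve(cf, x)
    coef = np.linalg.solve(W.T @ Ci_W, W.T @ Ci_x)
    resid = x - W @ coef
    sigma2 = float(resid @ cho_solve(cf, resid)) / n
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("covariance matrix has non-positive determinant")
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(loglik), coef, sigma2


_BOUNDS = {"lambda": (0.0, 1.0), "kappa": (0.0, 3.0), "delta": (1e-5, 3.0)}


def fit_bm_model(
    ttree: TimeTree,
    trait: Mapping[str, float],
    model: str = "BM",
    fixed_value: float | None = None,
) -> EvoModelFit:
    """Maximum-likelihood fit of a Brownian-motion trait model.

    Models: plain random walk (``BM``), a directional trend whose mean drifts
    linearly with root-to-tip path length (``directional``; identifiable only
    on non-ultrametric trees), and the three Pagel transformations ``lambda``
    (off-diagonal shrinkage of the covariance), ``kappa`` (branch lengths
    raised to a power) and ``delta`` (element-wise power of shared depths).
    The rate sigma^2 and the root state (plus trend slope) are profiled
    analytically; the transformation parameter is optimized numerically unless
    *fixed_value* pins it.
    """
    labels = ttree.tip_labels
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 tips")
    x = np.array([float(trait[l]) for l in labels])
    Cdf = vcv(ttree)
    C = Cdf.loc[labels, labels].to_numpy()

    if model in ("BM", "directional"):
        if model == "directional":
            W = np.column_stack([np.ones(n), np.diag(C)])
            if np.ptp(np.diag(C)) < 1e-9:
                raise ValueError("directional model unidentifiable on an ultrametric tree")
        else:
            W = np.ones((n, 1))
        loglik, coef, sigma2 = _profile_loglik(x, C, W)
        theta_hat = None
        beta = float(coef[1]) if model == "directional" else None
        k = 2 if model == "BM" else 3
        root = float(coef[0])
    elif model in _BOUNDS:
        W = np.ones((n, 1))
        lo, hi = _BOUNDS[model]

        def nll(theta: float) -> float:
            try:
                Ct = _transform_C(ttree, C, model, theta)
                ll, _, _ = _profile_loglik(x, Ct, W)
            except (ValueError, np.linalg.LinAlgError):
                return 1e10
            return -ll

        if fixed_value is not None:
            theta_hat = float(fixed_value)
        else:
            res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-8})
            if not res.success:
                raise RuntimeError(f"optimizer failed for {model}: {res.message}")
            theta_hat = float(res.x)
            # the bounded optimizer can miss boundary optima; check them
            for cand in (lo, hi):
                if nll(cand) < nll(theta_hat):
                    theta_hat = cand
        Ct = _transform_C(ttree, C, model, theta_hat)
        loglik, coef, sigma2 = _profile_loglik(x, Ct, W)
        beta = None
        root = float(coef[0])
        k = 2 if fixed_value is not None else 3
    else:
        raise ValueError(f"unknown model {model!r}")

    if n - k - 1 <= 0:
        raise ValueError("too few tips for AICc with this many parameters")
    aicc = -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return EvoModelFit(
        model=model,
        parameter=theta_hat,
        sigma2=sigma2,
        root_state=root,
        beta=beta,
        loglik=loglik,
        aicc=float(aicc),
        n=n,
        k_params=k,
    )


def model_table(fits: Sequence[EvoModelFit]) -> pd.DataFrame:
    """AICc comparison table of model fits on the same data, sorted by AICc."""
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits are not on identical data (tip counts differ)")
    bm = next((f for f in fits if f.model == "BM"), None)
    rows = []
    for f in fits:
        lr = 2 * (f.loglik - bm.loglik) if bm is not None else np.nan
        rows.append(
            {
                "model": f.model,
                "parameter": f.parameter,
                "loglik": f.loglik,
                "aicc": f.aicc,
                "lr_vs_bm": lr,
            }
        )
    df = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    return df
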