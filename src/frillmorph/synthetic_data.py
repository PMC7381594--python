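"""Synthetic landmark data with known phylogenetic, modular and allometric structure.

The generator emulates the statistical structure the analysis pipeline
assumes: per-species mean configurations evolve on a time tree under Brownian
motion with a block-structured (modular) trait covariance; within each
species, specimens follow a linear ontogenetic allometry (shape displacement
proportional to log centroid size along a fixed allometric direction) plus
isotropic digitization noise.  Because every true parameter is recorded, each
pipeline stage has a recovery test that needs no fossil data.

All randomness flows from one seed through named per-stage generators
(``tree``, ``shapes``, ``growth``, ``noise``) so stages are reproducible in
isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .landmark_io import (
    ROLE_FIXED,
    ROLE_SEMI,
    LandmarkConfiguration,
    write_tps,
)
from .phylo_core import TimeTree, read_newick, timescale, vcv
from .superimposition import centroid_size

__all__ = [
    "SimulationConfig",
    "default_timetree",
    "base_shape",
    "trait_covariance",
    "allometric_direction",
    "simulate_specimens",
    "random_timetree",
    "simulate_bm_trait",
    "simulate_tip_shapes",
    "simulate_growth_series",
    "make_fixture_set",
]

# an 8-tip non-ultrametric toy tree with staggered first/last appearance
# dates (Ma), shaped like a fossil supertree with ghost lineages
DEFAULT_NEWICK = "(((A,B),(C,D)),((E,F),(G,H)));"
DEFAULT_TIP_AGES: dict[str, tuple[float, float]] = {
    "A": (90.0, 85.0),
    "B": (80.0, 76.0),
    "C": (84.0, 80.0),
    "D": (72.0, 70.0),
    "E": (78.0, 74.0),
    "F": (69.0, 66.0),
    "G": (75.0, 72.0),
    "H": (66.0, 65.0),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults are the baseline study conditions used throughout the test
    suite: a modular trait covariance (within-module correlation 0.7,
    between-module 0.1), Brownian rate 1e-4 squared shape units per Ma on an
    8-tip fossil tree, species allometric slope 0.15 over a 30-1000 size
    range, and digitization noise of 0.005 shape units.
    """

    seed: int = 0
    n_landmarks_module1: int = 8  # the hypothesized module (frill)
    n_landmarks_module2: int = 8  # rest of the structure
    newick: str = DEFAULT_NEWICK
    tip_ages: dict = field(default_factory=lambda: dict(DEFAULT_TIP_AGES))
    root_extension: float = 5.0
    bm_rate: float = 1e-4  # shape variance per Ma
    within_module_corr: float = 0.7
    between_module_corr: float = 0.1
    slope_by_species: dict = field(default_factory=dict)  # species -> slope
    default_slope: float = 0.15
    size_range: tuple[float, float] = (30.0, 1000.0)
    n_specimens_per_species: int = 8
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if not (0 <= self.between_module_corr <= self.within_module_corr <= 1):
            raise ValueError("require 0 <= rho_between <= rho_within <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_landmarks(self) -> int:
        return self.n_landmarks_module1 + self.n_landmarks_module2

    def module_labels(self) -> list[str]:
        return ["frill"] * self.n_landmarks_module1 + ["rest"] * self.n_landmarks_module2

    def roles(self) -> list[str]:
        # first two points of each module are treated as fixed landmarks,
        # the remainder as curve semilandmarks
        out = []
        for size in (self.n_landmarks_module1, self.n_landmarks_module2):
            out.extend([ROLE_FIXED] * min(2, size) + [ROLE_SEMI] * max(0, size - 2))
        return out

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])


def default_timetree(config: SimulationConfig | None = None) -> TimeTree:
    """The toy fossil time tree implied by the configuration."""
    config = config or SimulationConfig()
    tree = read_newick(config.newick)
    return timescale(tree, config.tip_ages, method="equal", root_extension=config.root_extension)


def base_shape(config: SimulationConfig) -> np.ndarray:
    """Deterministic (k, 2) base configuration: module 1 along an upper arc
    (the frill margin), module 2 along a lower arc (rest of the skull)."""
    k1, k2 = config.n_landmarks_module1, config.n_landmarks_module2
    t1 = np.linspace(0.15 * np.pi, 0.85 * np.pi, k1)
    t2 = np.linspace(1.15 * np.pi, 1.85 * np.pi, k2)
    upper = np.column_stack([np.cos(t1), 0.6 * np.sin(t1) + 0.15])
    lower = np.column_stack([0.8 * np.cos(t2), 0.5 * np.sin(t2) - 0.1])
    pts = np.vstack([upper, lower])
    # centered, unit centroid size: all simulated deviations and allometric
    # slopes are then in Procrustes shape units, commensurate with GPA output
    pts = pts - pts.mean(axis=0)
    return pts / np.sqrt(np.sum(pts**2))


def trait_covariance(config: SimulationConfig) -> np.ndarray:
    """Block-structured 2k x 2k trait covariance (per Ma of evolution)."""
    labels = np.repeat(config.module_labels(), 2)
    same = labels[:, None] == labels[None, :]
    R = np.where(same, config.within_module_corr, config.between_module_corr)
    np.fill_diagonal(R, 1.0)
    return config.bm_rate * R


def allometric_direction(config: SimulationConfig) -> np.ndarray:
    """Unit allometric vector: outward expansion of the module-1 (frill) arc.

    The raw outward field is projected orthogonal to the similarity
    directions (translations, rotation, uniform scaling) at the base shape,
    so the signal survives Procrustes superimposition instead of being
    absorbed into size and alignment.
    """
    shape = base_shape(config)
    v = np.zeros_like(shape)
    m1 = slice(0, config.n_landmarks_module1)
    pts = shape[m1]
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    v[m1] = pts / np.where(norms == 0, 1.0, norms)
    v = v.ravel()

    k = len(shape)
    centered = shape - shape.mean(axis=0)
    m = centered / np.sqrt(np.sum(centered**2))
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-m[:, 1], m[:, 0]]).ravel()  # infinitesimal rotation
    basis = [tx / np.linalg.norm(tx), ty / np.linalg.norm(ty), m.ravel()]
    for q in basis:
        rot = rot - (rot @ q) * q
    basis.append(rot / np.linalg.norm(rot))
    for q in basis:
        v = v - (v @ q) * q
    return v / np.linalg.norm(v)


def random_timetree(
    n_tips: int,
    seed: int | np.random.Generator = 0,
    min_bl: float = 0.5,
    max_bl: float = 5.0,
) -> TimeTree:
    """A random binary non-ultrametric time tree with positive branch lengths.

    Topology by random sequential joins; branch lengths uniform on
    [min_bl, max_bl] Ma.  Tips are labeled T1..Tn.
    """
    import dendropy

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n_tips)])
    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node()
        leaf.taxon = taxon
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.uniform(min_bl, max_bl))
        b.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    # consistent node ages: root age = deepest tip depth
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + node.edge.length
    root_age = max(depths[l] for l in tree.leaf_node_iter())
    for node, d in depths.items():
        node.age = root_age - d
    tip_ages = {l.taxon.label: (l.age, l.age) for l in tree.leaf_node_iter()}
    return TimeTree(tree=tree, tip_ages=tip_ages, root_age=root_age)


def simulate_bm_trait(
    ttree: TimeTree,
    sigma2: float = 1.0,
    root_state: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """One Brownian-motion trait realization at the tips of a time tree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = ttree.tip_labels
    C = vcv(ttree).loc[labels, labels].to_numpy()
    L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(len(labels)))
    x = root_state + L @ rng.standard_normal(len(labels))
    return dict(zip(labels, x.tolist()))


def simulate_specimens(
    config: SimulationConfig, n_specimens: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Independent specimen shapes drawn from the block trait covariance.

    Returns an (n, 2k) matrix of flattened coordinates around the base shape,
    with no phylogenetic structure — the sampling model behind the
    within-sample modularity test.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else (config.rng("specimens") if seed is None else np.random.default_rng(seed))
    )
    Sigma = trait_covariance(config)
    L = np.linalg.cholesky(Sigma)
    Z = rng.standard_normal((n_specimens, Sigma.shape[0]))
    return base_shape(config).ravel()[None, :] + Z @ L.T


def simulate_tip_shapes(
    config: SimulationConfig, ttree: TimeTree | None = None
) -> dict[str, LandmarkConfiguration]:
    """Species mean shapes under Brownian motion with modular trait covariance.

    The joint covariance of the stacked species-by-coordinate deviations is
    the Kronecker product of the tree's shared-path matrix C and the block
    trait covariance.
    """
    ttree = ttree or default_timetree(config)
    labels = ttree.tip_labels
    C = vcv(ttree).loc[labels, labels].to_numpy()
    Sigma = trait_covariance(config)
    for name, M in (("tree", C), ("trait", Sigma)):
        w = np.linalg.eigvalsh(M)
        if w.min() <= 0:
            raise ValueError(f"{name} covariance not positive definite (min eigenvalue {w.min()})")
    rng = config.rng("shapes")
    Lc = np.linalg.cholesky(C)
    Ls = np.linalg.cholesky(Sigma)
    Z = rng.standard_normal((len(labels), Sigma.shape[0]))
    deviations = Lc @ Z @ Ls.T
    base = base_shape(config).ravel()
    out = {}
    for i, label in enumerate(labels):
        coords = (base + deviations[i]).reshape(-1, 2)
        out[label] = LandmarkConfiguration(
            specimen_id=f"{label}_mean",
            species=label,
            coords=coords,
            roles=config.roles(),
        )
    return out


def simulate_growth_series(
    mean_shape: np.ndarray,
    slope: float,
    size_range: tuple[float, float],
    n: int,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    allometric_vector: np.ndarray | None = None,
) -> dict:
    """A linear ontogenetic growth series for one species.

    Log centroid sizes are evenly spaced over the log size range; the i-th
    shape is ``mean + slope * (log cs_i - mean log cs) * v`` plus isotropic
    noise, with v the unit allometric vector.  Returned ``coords`` are the
    shapes rescaled so each configuration's realized centroid size equals the
    prescribed one; ``shapes`` are the exact tangent-space shape vectors the
    allometric model sees.
    """
    if n < 2:
        raise ValueError("need n >= 2 specimens")
    lo, hi = size_range
    if not (0 < lo < hi):
        raise ValueError("invalid size_range")
    mean_pts = np.asarray(mean_shape, dtype=float).reshape(-1, 2)
    mean_pts = mean_pts - mean_pts.mean(axis=0)
    mean_flat = (mean_pts / centroid_size(mean_pts)).ravel()  # unit-CS shape units
    if allometric_vector is None:
        raise ValueError("allometric_vector is required")
    v = np.asarray(allometric_vector, dtype=float).ravel()
    if slope != 0 and np.linalg.norm(v) == 0:
        raise ValueError("zero allometric vector with nonzero slope")
    v = v / np.linalg.norm(v) if np.linalg.norm(v) > 0 else v
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_cs = np.linspace(np.log(lo), np.log(hi), n)
    centered = log_cs - log_cs.mean()
    shapes = mean_flat[None, :] + slope * centered[:, None] * v[None, :]
    if noise_sd > 0:
        shapes = shapes + rng.normal(0.0, noise_sd, size=shapes.shape)
    cs = np.exp(log_cs)
    coords = []
    for i in range(n):
        pts = shapes[i].reshape(-1, 2)
        coords.append(pts / centroid_size(pts) * cs[i])
    return {
        "shapes": shapes,
        "coords": coords,
        "log_cs": log_cs,
        "centroid_sizes": cs,
    }


def make_fixture_set(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic study to *out_dir* and return its manifest.

    Emits one TPS file of per-species growth series, the sidecar role table,
    specimen metadata, the tip age table, the Newick tree, and a manifest
    JSON recording the seed and all true generating parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ttree = default_timetree(config)
    tips = simulate_tip_shapes(config, ttree)
    v = allometric_direction(config)
    rng = config.rng("growth")
    configs = []
    meta_rows = []
    slopes = {}
    for species, mean_cfg in sorted(tips.items()):
        slope = config.slope_by_species.get(species, config.default_slope)
        slopes[species] = slope
        series = simulate_growth_series(
            mean_cfg.coords,
            slope,
            config.size_range,
            config.n_specimens_per_species,
            config.noise_sd,
            seed=rng,
            allometric_vector=v,
        )
        for i, coords in enumerate(series["coords"]):
            sid = f"{species}_{i:02d}"
            configs.append(
                LandmarkConfiguration(
                    specimen_id=sid, species=species, coords=coords, roles=config.roles()
                )
            )
            stage = ("juvenile", "subadult", "adult")[
                min(2, 3 * i // config.n_specimens_per_species)
            ]
            meta_rows.append(
                f"{sid},{species},other,{stage},{series['centroid_sizes'][i]:.6g}"
            )
    write_tps(configs, out_dir / "specimens.tps")
    roles = config.roles()
    modules = config.module_labels()
    with open(out_dir / "roles.csv", "w") as fh:
        fh.write("index,role,curve,side\n")
        for i, (role, module) in enumerate(zip(roles, modules), start=1):
            curve = "frill_margin" if (role == ROLE_SEMI and module == "frill") else (
                "skull_margin" if role == ROLE_SEMI else ""
            )
            fh.write(f"{i},{role},{curve},\n")
    with open(out_dir / "partition.csv", "w") as fh:
        fh.write("index,module\n")
        for i, module in enumerate(modules, start=1):
            fh.write(f"{i},{module}\n")
    with open(out_dir / "metadata.csv", "w") as fh:
        fh.write("specimen_id,species,group,stage,basal_skull_length_mm\n")
        fh.write("\n".join(meta_rows) + "\n")
    with open(out_dir / "ages.csv", "w") as fh:
        fh.write("species,FAD_Ma,LAD_Ma\n")
        for sp, (fad, lad) in sorted(config.tip_ages.items()):
            fh.write(f"{sp},{fad},{lad}\n")
    (out_dir / "tree.nwk").write_text(config.newick + "\n")
    manifest = {
        "seed": config.seed,
        "n_landmarks_module1": config.n_landmarks_module1,
        "n_landmarks_module2": config.n_landmarks_module2,
        "bm_rate": config.bm_rate,
        "within_module_corr": config.within_module_corr,
        "between_module_corr": config.between_module_corr,
        "true_slopes": slopes,
        "size_range": list(config.size_range),
        "n_specimens_per_species": config.n_specimens_per_species,
        "noise_sd": config.noise_sd,
        "newick": config.newick,
        "tip_ages": {k: list(v) for k, v in sorted(config.tip_ages.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
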