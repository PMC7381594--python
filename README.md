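# frillmorph

Geometric morphometrics and phylogenetic heterochrony analysis for 2D
landmark data on fossil time trees.

The package was built around a concrete macroevolutionary question — how the
parieto-squamosal frill of ceratopsian dinosaurs changed shape across the
clade's phylogeny and within the growth series of individual species — but
every component is a general tool for landmark-based shape analysis of
fossil samples:

- **Landmark I/O** (`landmark_io`): TPS files with sidecar role tables
  (fixed landmarks vs. curve semilandmarks, midline and bilateral-pair
  structure), arc-length resampling of curves into evenly spaced
  semilandmarks, mirroring of the better-preserved skull side across the
  sagittal axis, and landmark subsetting (e.g. excluding the parietal
  fenestra so unfenestrated taxa fit the same configuration).
- **Superimposition** (`superimposition`): generalized Procrustes analysis
  (partial Procrustes: translation, unit-centroid-size scaling, proper
  rotations only), centroid sizes, tangent-space projection.
- **Phylogenetics** (`phylo_core`): time-calibration of a cladogram from
  first/last appearance dates with "equal" branch-sharing or a punctuated
  +1 Ma ghost-lineage correction; the Brownian shared-path covariance;
  Felsenstein's independent contrasts; squared-change-parsimony ancestral
  states; ML Brownian model fits with Pagel's λ/κ/δ transformations and a
  directional trend, compared by AICc.
- **Ordination** (`ppca`): phylogenetic PCA of the GLS evolutionary
  covariance matrix, with per-axis variance shares and axis-extreme shape
  deformations.
- **Modularity** (`modularity`): the covariance-ratio (CR) statistic for a
  landmark partition, its random-partition permutation null, and a
  semilandmark-removal sensitivity analysis.
- **Group comparisons** (`group_stats`): pairwise permutational ANOVA of
  group scores along ordination axes.
- **Heterochrony** (`heterochrony`): pooled multivariate regression of shape
  on log centroid size, regression scores, ontogenetic vectors connecting
  the smallest and largest specimens of each species, squared-change
  parsimony reconstruction of ancestral vectors, classification of
  allometric shifts (peramorphosis / paedomorphosis via a 1.5 × CI
  criterion), per-branch rates, and a randomization test for growth-vector
  angle changes (acceleration / deceleration / hypermorphosis / pre- and
  postdisplacement).
- **Synthetic data** (`synthetic_data`): a generator producing landmark
  datasets with *known* phylogenetic, modular, and allometric structure, so
  every stage of the pipeline has an exact recovery test.

## The statistics in brief

With aligned shapes `X` (specimens × 2k) the CR coefficient for a two-module
partition is

    CR = sqrt( tr(S12 S21) / sqrt( tr(S11* S11*) tr(S22* S22*) ) )

where `S` is the coordinate covariance matrix, `S12` its between-module
block, and `*` zeroes block diagonals; CR < 1 means stronger covariation
within modules than between them. Significance is the left tail of CR over
random same-size reassignments of whole landmarks.

Phylogenetic PCA eigen-decomposes the evolutionary covariance
`R = (X − 1a)' C⁻¹ (X − 1a) / (n − 1)` with `C` the shared-path matrix of
the time tree and `a` the GLS phylogenetic mean.

Allometry is summarised by the regression score: the projection of each
centered shape onto the unit multivariate allometric vector `b/‖b‖` from the
pooled regression of shape on log centroid size. Heterochrony inference
compares ancestor and descendant ontogenetic vectors in the
(log CS, regression score) plane.

## Worked example

```python
import numpy as np, pandas as pd
from frillmorph.synthetic_data import (
    SimulationConfig, default_timetree, simulate_tip_shapes, simulate_specimens)
from frillmorph.superimposition import gpa
from frillmorph.ppca import phylo_pca
from frillmorph.modularity import Partition, cr_test

cfg = SimulationConfig(seed=1)              # modular, allometric study conditions
tree = default_timetree(cfg)                # 8-tip fossil time tree
species_means = simulate_tip_shapes(cfg, tree)

aligned = gpa(list(species_means.values()))
print(f"GPA converged in {aligned.iterations} iterations")

shapes = pd.DataFrame(aligned.shapes, index=[c.species for c in species_means.values()])
res = phylo_pca(shapes, tree)
print("pPC1-3 % variance:", np.round(res.percent_variance[:3], 1))

X = simulate_specimens(cfg, 50)             # 50 specimens, rho_w=0.7, rho_b=0.1
out = cr_test(X, Partition(cfg.module_labels()), n_permutations=9999, seed=0)
print(f"CR = {out.cr_observed:.3f}, p = {out.p_value:.4f}")
```

Output:

```
GPA converged in 4 iterations
pPC1-3 % variance: [43.3 19.  11.1]
CR = 0.178, p = 0.0002
```

The first three phylogenetic PC axes capture ~73% of interspecific shape
variance in this run; the CR well below 1 with p ≈ 2 × 10⁻⁴ correctly
detects the modular covariance structure the generator built in
(within-module correlation 0.7 vs. 0.1 between).

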