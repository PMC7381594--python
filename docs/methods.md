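# Methods

This note documents the statistical models implemented in `frillmorph`, the
choices made where the methodology was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Superimposition

Generalized Procrustes analysis is implemented as *partial* Procrustes:
configurations are centered, scaled to unit centroid size, and rotated to a
provisional consensus that is re-estimated each iteration; there is no
additional cos(ρ) rescaling. Centroid size — the root summed squared
distance of points from their centroid — is carried separately as the size
variable for allometry. Convergence is declared when the root-mean-square
coordinate change of the consensus falls below `tol` (default 1e-8); the
Procrustes objective is asserted non-increasing on every run.

Two deliberate restrictions:

- **No reflections.** The optimal rotation is constrained to determinant +1.
  Skulls are digitized in a consistent view; any mirroring of a damaged side
  is an explicit preprocessing step (`landmark_io.mirror_fill`), which also
  snaps midline points onto the fitted total-least-squares sagittal axis so
  the output is exactly bilaterally symmetric.
- **Semilandmarks are not slid.** Curve points are treated as fixed during
  superimposition. Sliding would require a curve specification as input; the
  interface accepts role/curve sidecar tables so a sliding strategy can be
  added without changing call signatures.

Tangent projection (orthogonal projection onto the tangent space at the
consensus) is on by default, the standard linearisation before PCA and
regression on shape coordinates.

## Time-calibration of fossil trees

Tip ages are first appearance dates (FAD, Ma). Basic dating makes each node
as old as its oldest descendant tip, which necessarily produces zero-length
branches (the oldest tip in each clade, and internal chains tied to it).
Two correction methods are provided:

- **equal** — the root is pushed back by `root_extension` (default 1 Ma;
  5 Ma in the synthetic default), then each zero-length branch takes an
  equal share of the first ancestral branch of positive length, by evenly
  re-spacing the node ages along the chain. Tip ages are never moved.
- **punctuated** — exactly 1 Ma is inserted into every zero-length branch,
  shifting ancestral nodes older while descendant ages stay fixed. This
  emulates a punctuated reading in which change is concentrated at
  speciation, and avoids the very deep smoothed branches the equal method
  can produce when sampling is sparse.

Polytomies are resolved to zero-length bifurcations before dating,
deterministically (children combined in alphabetical order of their smallest
subtended tip name) so repeated runs give identical topologies.

## Comparative machinery

The shared-path matrix `C` (tips × tips) contains root-to-MRCA path lengths;
it is validated against a brute-force double-loop MRCA computation in the
tests. Independent contrasts follow Felsenstein's pruning algorithm, with
the through-origin contrast regression tested for exact agreement with the
GLS slope. Squared-change parsimony minimises Σ (change)²/branch over
internal states by solving the weighted tree Laplacian system; with
branch-length weighting this is identical to the ML Brownian ancestral
states, and the tests assert equality with an explicit GLS conditional-mean
oracle to 1e-8.

Model fitting maximises the Gaussian likelihood with mean `a·1` (plus
`β · depth` for the directional trend, identifiable only on non-ultrametric
trees) and covariance `σ²·C(θ)`. `σ²` and the mean coefficients are profiled
analytically; θ is optimized by bounded scalar search with the bounds
λ ∈ [0, 1], κ ∈ [0, 3], δ ∈ (0, 3], plus explicit endpoint checks because
boundary optima (λ̂ = 1 in particular) are common. AICc uses k = 2 free
parameters for plain Brownian motion and k = 3 otherwise. The λ transform
scales off-diagonal entries of C; κ raises each branch length to a power
before rebuilding C; δ raises the shared depths element-wise. Model
selection is by AICc with likelihood ratios against Brownian motion also
reported; no MCMC machinery is involved, so posterior rate-shift
localisation is out of scope.

## Phylogenetic PCA

The evolutionary covariance `R = (X − 1a)' C⁻¹ (X − 1a)/(n − 1)` is
eigen-decomposed, where `a` is the GLS phylogenetic mean. Scores are
projections of the (GLS-)centered but *non-whitened* data on the
eigenvectors, so on a star tree with equal branch lengths the analysis is
ordinary PCA. Covariance mode is the default; correlation mode (rescaling R
to unit diagonal) is available. Axis signs are fixed by making the
largest-magnitude loading positive. Axis extremes return the species with
minimum and maximum score together with their deformation from the
phylogenetic mean; ties break by species name with a warning.

## Covariance-ratio modularity test

CR compares between-module covariation to within-module covariation with
block diagonals zeroed (see README for the formula); both coordinates of a
landmark always travel together. The null reassigns whole landmarks to
modules of the same sizes uniformly at random; the test is left-tailed (low
CR = modularity) and the p-value uses the (1 + b)/(1 + m) estimator, which
cannot be zero. For more than two modules the statistic is the mean of the
pairwise CRs (tested for m = 2). The semilandmark sensitivity analysis
removes a given number of semilandmarks at random — stratified
proportionally across modules, with replicates (default 100), since no
single removal set is canonical — and re-runs the test on the reduced
configuration.

## Allometry and heterochrony

The pooled regression fits every Procrustes coordinate on log centroid size;
the stacked slopes form the allometric vector `b`, and the regression score
of a shape is its centered projection onto `b/‖b‖`. The reported scalar
slope is that of score on log size. Significance of allometry is Goodall's
F (total shape SS explained by size over residual) with a permutation
p-value from shuffling sizes across specimens. A parametric F-test of the
*score* on size would be circular — the score is the projection onto the
fitted direction, and such a test rejects almost surely when there is no
allometry at all; the permutation test is calibrated (type-I error at the
nominal rate) and is what the test suite asserts.

Ontogenetic vectors connect the smallest and largest specimen of a species
(by centroid size, the analysis's size variable; ties break by specimen id
with a warning) in the (log CS, regression score) plane. Ancestral vectors
reconstruct all four endpoint coordinates independently by squared-change
parsimony on the time tree. For every ancestor→descendant branch the
adult-score difference is compared against a global threshold of 1.5 × the
95% t-based CI half-width of the mean branch difference (the CI level is
configurable; 95% is the conventional default): exceedances are
peramorphosis, negative exceedances paedomorphosis. Rates divide the score
difference by branch duration in Ma and are tagged by quartile.

Angle changes between ancestor and descendant vectors are tested against a
null of 200 random displacement vectors drawn component-wise uniformly
within the min/max bounds of the observed displacements, paired disjointly
(1–2, 3–4, …) into 100 null angles; each observed angle is reported as the
fraction of null angles it exceeds. Narrative labels follow the standard
decision rules: large angle change → acceleration (steeper descendant) or
deceleration; effectively parallel vectors with the adult endpoint extended
to larger size and score → hypermorphosis; parallel vectors shifted bodily
toward/away from the origin → pre-/postdisplacement; anything ambiguous is
labeled indeterminate together with the rule that fired.

## Permutational ANOVA

Group comparisons along an ordination axis are two-group one-way ANOVAs with
the label-permutation p-value. The raw proportion (which can be exactly 0,
the convention used in published tables of this kind) and the +1-corrected
estimator are both reported.

## Synthetic data: what it emulates and what it does not

The generator produces exactly the structure the analysis assumes:

- species mean shapes evolving by Brownian motion on a fossil time tree,
  with a block trait covariance (within-module correlation ρ_w = 0.7,
  between-module ρ_b = 0.1, rate 1e-4 shape-variance per Ma by default);
- linear ontogenetic allometry, shape displaced along a fixed unit
  allometric direction in proportion to log centroid size (default slope
  0.15 over a 30–1000 centroid-size range, 8 specimens per species);
- isotropic digitization noise (default 0.005 shape units).

The base configuration is centered and scaled to unit centroid size, so all
simulated deviations are in Procrustes shape units and survive
superimposition; the allometric direction is likewise projected orthogonal
to the similarity transformations (translations, rotation, scaling) at the
base shape — otherwise most of a radial "expansion" signal would be absorbed
into centroid size during alignment.

The default tree has 8 tips with staggered appearance dates spanning
90–66 Ma and a 5 Ma root extension, exercising time-scaling and the
identifiability of the directional model. All randomness flows from one seed
through named per-stage generators, so individual stages are reproducible in
isolation and the fixture manifest is byte-identical across runs.

What the generator does *not* emulate: taphonomic distortion beyond
isotropic noise, missing landmarks, ornament (epiossification) shape,
curve-sliding artifacts, or unequal specimen sampling per species. Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness of conclusions drawn from
real, distorted fossil material.

## Problem sizes in the test suite

The suite's simulation-based checks use: 200 replicates for the CR type-I
calibration and 20 for its power condition (50 specimens each, 199
permutations); 200 Brownian replicates on a 25-tip tree for λ recovery; 100
replicates for peramorphic-branch recovery on the 8-tip tree; 500
replicates for the permutational-ANOVA calibration. These sizes keep the
whole suite in the tens of seconds while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

- Semilandmark sliding is not implemented (hook only).
- The punctuated correction adds 1 Ma uniformly; it does not model
  lineage-specific ghost durations.
- λ/κ/δ are ML point estimates with AICc comparison; Bayes-factor
  thresholds from MCMC marginal likelihoods are not comparable and are not
  produced.
- The CR generalisation to m > 2 modules (mean pairwise CR) is implemented
  but only exercised for m = 2.
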