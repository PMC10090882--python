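# Methods

This note documents the models, numerical choices and known limitations
behind `nasallom`, in the spirit of the methods documentation of other
comparative/statistical packages.

## Statistical model

### Brownian-motion covariance

For a rooted tree with branch lengths in Ma, the BM trait covariance of
tips *i*, *j* is the root-to-MRCA path length; the diagonal is the
root-to-tip depth. `bm_covariance` computes it by assigning every
internal node's depth to the tip pairs split across its children —
O(n²) and exact. On an ultrametric tree the diagonal is constant; the
implementation does not require ultrametricity, only a rooted tree with
non-negative branch lengths.

### Line fitting

All fits operate on base-10 logarithms, the conventional axes for
allometry. Base choice only shifts intercepts; no test statistic depends
on it.

- **OLS**: closed-form normal equations; coefficient covariance
  `σ̂²(XᵀX)⁻¹` with `σ̂² = RSS/(n−2)`.
- **SMA**: slope `sign(r)·s_y/s_x` through the bivariate mean; slope
  variance by Warton's large-sample formula `b²(1−r²)/n`.
- **PGLS**: `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` via Cholesky solves; residual scale
  `RSS_GLS/(n−2)`; R² measured against the GLS-weighted mean; reported
  log-likelihood is the profile-ML value. The covariance structure is
  pure Brownian motion — no Pagel's λ optimisation; λ-style rescaling can
  be applied by the caller transforming C before fitting.

### Conditional group tests

Slopes first, intercepts only under slope homogeneity:

- OLS/PGLS slope test: Wald *t* on the group×x interaction in the pooled
  (G)LS model `y = b0 + b1·x + b2·g + b3·g·x`, df = n−4. Intercept test:
  Wald on the group dummy at common slope, df = n−3 (classical ANCOVA F
  = t² for OLS; "phylogenetic ANCOVA" when C comes from the tree).
- SMA slope test: Warton-style likelihood ratio. For a candidate common
  slope *b*, each group's residual axis `y − b·x` and fitted axis
  `y + b·x` have correlation `r_i(b)`; the statistic
  `−Σ (n_i−2)·log(1−r_i²)` is minimised over *b* and referred to
  χ²(groups−1). The group SMA slopes are always evaluated as candidate
  minima, because with noise-free collinear data the objective is a
  needle a smooth search cannot hit. A seeded permutation p-value
  (`n_perm`) is available for small samples.
- SMA elevation test: difference of mean residuals at the common slope,
  variance including the common-slope uncertainty estimated from the
  curvature of the LR surface, referred to χ²(1).

Raw p-values are reported per comparison; no multiple-testing correction
is applied.

Degenerate inputs: a perfect fit (zero residual) yields statistic 0 and
p = 1 when the tested coefficient is itself zero, and p = 0 otherwise.
Near-singular covariance matrices (zero-length terminal branches,
i.e. effectively identical tips) are detected both when the factorization
fails *and* when it "succeeds" with a near-zero pivot, and a diagonal
jitter of 1e-8 × tree depth is applied with a warning.

### Calibration nulls

`null_rejection_rate` estimates each test's type-I error under its own
null model: OLS and SMA assume independent residuals, so they are
calibrated with BM on a *star* phylogeny (exactly i.i.d. tips); PGLS is
calibrated with BM on a structured pure-birth tree. Running OLS/SMA on
tree-structured data inflates their type-I error — that phylogenetic
pseudo-replication is the reason the pipeline carries PGLS at all, not a
calibration failure of those tests.

## Synthetic data

### Trees

Pure-birth (Yule) trees conditioned on the tip count, then rescaled to a
target depth (default 100 Ma), emulating a time-calibrated phylogeny.
The simulator stops at the n-th birth, which would leave the newest
cherry with zero-length terminal branches (and a singular BM covariance);
all terminal branches are therefore extended by the Exp(n·λ) waiting time
to the next, uncounted event before rescaling — the standard conditioned
pure-birth construction.

### Traits

`simulate_allometric_traits` draws the predictor and an independent
residual as Brownian motion on the tree (i.i.d. residuals available via
`residual_structure="iid"` for robustness checks; which structure real
measurements follow is unknowable from a single data set, so both are
provided) and forms `y = intercept_g + slope_g·x + e` per tip.
`simulate_dataset` produces the full measurement schema with a two-layer
design: log body mass is BM; log nasal volume follows body mass with *no*
group term; log skull volume follows body mass with an endotherm offset
(default −0.3 log10 units). Relative to head size, endotherms then carry
a ~0.3 log10-unit larger nasal cavity while the body-mass relation is
identical across groups — the central contrast the pipeline is designed
to detect. Hull volume is a fixed multiple (1.6×) of skull volume, the
respiratory region a fixed fraction (0.6) of the nasal cavity, and
surface areas follow exact 2/3-power scaling of the volumes; these
deterministic links keep every response column present without inventing
extra noise processes.

Default rates: `sigma_x2 = 0.01`/Ma (≈1 log10 unit of body-size spread at
the tips over 100 Ma, a few orders of magnitude across the clade) and
`sigma_e2 = 5e-5`/Ma (≈0.07 log10 units of scatter about a line,
r² ≈ 0.99). The residual rate is set by power-matching: the emulated
comparisons live in the regime where a clade-level 0.3 log10 intercept
offset is decisively significant, and under BM the standard error of a
clade contrast is governed by the two root-to-clade stem paths rather
than by the number of tips, so looser scatter would contradict the
emulated system. Group assignment defaults to `by_clade` (the subclade
closest to half the tips is endothermic) — phylogenetically clustered
endothermy, the hard case for comparative tests.

Multiple conspecific specimens are simulated by expanding species tips
into 1-Ma pendant polytomies (the stem is shortened by 1 Ma so the tree
stays ultrametric) and running BM on the expanded tree, which gives
specimens realistic within-species correlation.

What the generator does **not** emulate: measurement error in the voxel
pipeline feeding the table, non-Brownian evolution (OU, rate shifts),
body-mass estimation error, and ecology-driven outliers (e.g. reduced
olfaction lineages). Passing tests therefore demonstrate correctness of
the inferential machinery under its stated model, not robustness to
violations of it.

### Skull phantoms

A phantom is a hollow box "skull" (bone shell) enclosing an ellipsoidal
cavity split by a plane into main-airway and olfactory labels. Analytic
truths: ellipsoid volume `(4/3)πabc`; plane partitions by mapping the
ellipsoid to the unit ball (a plane stays a plane) and using the
spherical-cap formula; surface area by Thomsen's approximation
(p = 1.6075, ≤1.1% error — tests therefore use ≥2% tolerances for areas).
Voxelization uses the voxel-centre convention
`world = origin + (index + 0.5)·spacing`; default geometry places cut
planes midway between voxel-centre coordinates so a half-cut is not
biased by a voxel layer lying exactly on the plane.

## Morphometry

- Volumes are voxel counts × voxel volume (exact for label maps).
- Surface areas are marching-cubes isosurfaces of the label's indicator
  field after Gaussian smoothing with σ = 1 voxel. Raw binary marching
  cubes overestimates curved surfaces by ~9% (staircase artefact);
  smoothing reduces the sphere-area error to ≈0.2%. If smoothing erases a
  structure entirely (thin, ≲2-voxel features) the raw binary isosurface
  is used instead; the method constant for a single 1-mm voxel is the
  octahedron through the half-level crossings, area √3 mm². Whether the
  areas include the artificial cut face between respiratory and olfactory
  regions follows the closed-region convention: each label's full
  boundary, cut face included.
- The convex-hull head model is the hull of the bone isosurface vertices
  (not voxel centres), matching the idea of a hull spanned by the skull's
  surface points; volumes via Qhull.
- Mesh volumes use the signed-tetrahedron sum (via trimesh) and require
  watertight input.

## Airway reconstruction

The four constraints are implemented as oriented planes whose normals
point toward the retained airway side: rostral nostril cut, dorsal
antrum boundary, caudal choana cut; cavity voxels caudal of the choana up
to a cap plane through the mesethmoid point (normal to the rostrocaudal
x-axis) are relabelled olfactory. The output labels partition the input
cavity exactly. A curved antrum wall supplied as a triangulated surface
is reduced to its least-squares plane, oriented toward a user-supplied
interior seed point; full curved-surface sidedness is out of scope. The
nasal vestibule is considered part of the main airway. The soft-tissue
correction is the scalar 40–60% bracket only; mucosal constriction and
turbinate geometry are deliberately not modelled.

The placement index ρ is computed in log10 space, the space the
regression lines live in. Estimate standard errors at the fossil's x are
attached when the fits carry coefficient covariances.

## Pipeline conventions

Five comparisons (whole cavity vs body mass / skull volume / hull
volume; respiratory region vs skull / hull volume) × two responses
(surface area, volume) × up to three methods. Mammalian records never
enter respiratory-region cells: mammalian turbinates offer no landmark
separating the respiratory from the olfactory region, so that label does
not exist for them. Rows with missing body mass are excluded from
body-mass cells only. Crocodylian body masses can be estimated from
length via a configured power law; the coefficients are configuration
values (published equations differ in length measure and units), and the
provenance hierarchy is direct measurement > species mean > allometric
estimate. Reports are deterministic given config and seed (sorted JSON
keys, fixed row order); untested intercepts are exported as an em dash.

## Problem sizes used in the checks

Calibration uses 1000 null simulations per test (40 tips, 20 per group);
contrast recovery uses 200 simulated data sets of 50 tips; oracle
equivalence uses 100 random trees of 4–12 tips; phantoms are 96×64×64
voxels at 0.5 mm. These sizes give Monte-Carlo standard errors of
~0.7 percentage points on a 5% rejection rate and ~2 points on a 90%
rate, small relative to the asserted tolerance bands.

## Known limitations

- PGLS assumes the BM covariance is known up to scale; λ/OU structures
  are not fitted.
- The SMA elevation test's common-slope variance comes from the LR
  curvature (numerical second difference), adequate at the sample sizes
  used here but not a small-sample-exact procedure.
- Conditioning the intercept test on a non-significant slope test makes
  the joint null-retention probability of a comparison ≈0.95² ≈ 0.90, not
  0.95 — an inherent property of sequential testing worth remembering
  when reading simulation summaries.
- Voxel tolerances assume structures ≳10 voxels across the smallest
  axis; sub-voxel features are not resolved.
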