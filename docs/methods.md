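# Methods

This note documents the models, numerical choices and known limitations of
`uavheight`, stage by stage.

## Synthetic study design

The generator emulates a multi-site wheat DH trial: `n_lines = 198` doubled
haploid lines plus the two parents, randomized complete blocks with
`n_reps = 3` at each of `n_sites = 2` sites, plots of 1.3 m × 3 m, rasters
at 2.5 cm ground sampling distance. These defaults are the study conditions
every recovery test runs under; smaller configurations used in unit tests
keep every design feature (two sites, replicate blocks, parents) and only
shrink counts.

### Genetics

* **Map.** Six chromosomes (named 1A, 2B, 3A, 4B, 4D, 6D) of 150 cM with
  markers every 5 cM (186 markers). A regular grid keeps expected-genotype
  computations transparent; real maps are denser and irregular, which the
  scan handles but the defaults do not exercise.
* **Meiosis.** One recombinant gamete per line, doubled to homozygosity.
  Recombination between adjacent markers follows the Haldane map function
  r = (1 − e^(−2d/100))/2 with no interference — chosen over Kosambi because
  no interference model is being fitted, only simulated, and the interval
  scan uses the same map function, keeping simulator and analysis
  consistent.
* **Architecture.** Two major dwarfing loci — 4B @ 60 cM, effect −10 cm and
  4D @ 75 cM, effect −9 cm on the ±1 parental contrast — emulate the
  Green-Revolution Rht-B1b/Rht-D1b alleles; a minor locus 6D @ 40 cM
  (+4 cm) emulates a small growth QTL. QTL positions snap to the nearest
  marker. The polygenic background (default variance 60 cm²) is
  *marker-borne*: i.i.d. N(0, σ²g/p) effects on every marker, so genomic
  prediction and the marker-exclusion experiment see a background that is in
  principle capturable from the genotypes, as for a real genotyped
  population. The expected across-line background variance equals σ²g; the
  realized variance fluctuates between seeds (effects and linkage), which is
  why component-recovery tests quote tolerances per seed and medians across
  seeds.
* **Phenotype model.** Plot value = 85 cm + genetic value + site effect
  (N(0, 25)) + G×E deviate (N(0, 24)) + plot residual (N(0, 120)), all in
  cm. With the QTL variance (≈197 cm²) this puts the plot-level SD near
  20 cm, entry-mean heritability near 0.89, and the combined variance
  explained by the two major loci near 60% — the regime the method is meant
  to operate in. Distributions for the site and G×E terms are a design
  choice (normals), as is treating the simulated plot values as the
  ground-measured heights.

### Raster rendering

The true DTM is a tilted plane plus three low-frequency sinusoids with a
total amplitude of ~0.5 m across the field — gentle farmland relief; there
is no accepted terrain model for trial fields, so smoothness and amplitude
are the only commitments. The DSM equals the terrain except inside plots:

* the **canopy-top level** is the true (ruler) height times
  (1 − `canopy_deficit_frac`), default 0.10: photogrammetric surface
  reconstruction undersamples thin spike tips, so the DSM sits
  systematically below ruler height, and proportionally more for taller
  plots. This single parameter reproduces both the systematic
  underestimation and the larger absolute error on tall plots that motivate
  bias correction in practice;
* a fraction `spike_fraction = 0.35` of plot pixels are spike tops at the
  canopy-top level minus a half-normal offset (sd 3 cm) — tips at or below
  the tallest spike; the remaining pixels image lower leaves and gaps,
  uniform between 35% and 90% of the top level, which makes a naive
  mean-of-canopy estimator underestimate badly and motivates the
  upper-boundary rule;
* i.i.d. sensor noise (sd 2 cm) is added everywhere; the true DTM is
  noise-free.

Within-canopy texture statistics are free knobs, not calibrated to wheat;
what passing tests show is that the *extraction rule* recovers heights from
a texture with the right qualitative pathologies (sparse tops, deep gaps,
sensor noise, terrain), not that the texture is photometrically realistic.
No photogrammetric artifacts (doming, blur, bundle-adjustment error) are
modelled, and rasters are rendered directly rather than reconstructed from
virtual images.

## Terrain model

Three control points per bare-ground polygon: the centroid paired with the
median pixel elevation (robust to stray vegetation pixels inside the
polygon), plus the locations of the lowest and highest pixel elevations,
which capture the local relief of the zone. TIN-linear interpolation over
the Delaunay triangulation was chosen over kriging or splines because it is
exact on affine surfaces, has zero tuning parameters, and minimizes surface
oscillation; it is the documented extension point if smoother models are
wanted. Outside the convex hull the DTM takes the nearest control point's
elevation (plots at field edges must still get a value); every extrapolated
pixel is flagged in a companion quality mask. Duplicate control-point
locations are collapsed before triangulation. Fewer than three distinct,
non-collinear points is an error.

## Height extraction

* PHM = DSM − DTM with nodata propagation; grid mismatch is an error (no
  silent resampling). Negative heights are kept, counted and logged —
  clipping would hide DTM bias.
* Plot polygons are trimmed inward by `trim_fraction × shorter side`
  (default 0.10) before sampling, against edge-row effects.
* Defaults: `n = 10` windows per plot (mirroring the ten plants a ground
  crew measures per plot), window edge 7.5 cm (3×3 pixels at 2.5 cm GSD —
  single-spike scale), boundary tolerance 10 cm. Windows are placed by
  rejection sampling (centers uniform in the trimmed plot, pairwise
  non-overlap, retry cap 200); if fewer than requested fit, the count is
  reduced with a warning, and fewer than two is an error.
* The per-window **maximum** operationalizes "the upper boundary of the
  canopy"; the 10 cm rule is applied *across* windows: any reading more
  than the tolerance below the plot-wide best cannot be a spike top and is
  rejected. U and L are the extremes of the accepted readings and
  H = (U + L)/2 exactly. If rejection leaves one survivor, U = L = H with a
  low-confidence flag. This across-window reading (rather than within one
  window) is the central interpretive decision of the extraction stage.
* Pixel membership is by pixel-center containment; coordinates are CRS
  units (meters).

## Validation statistics

RMSE and bias are computed on raw paired differences (ground − UAV), so a
constant underestimate appears fully in both. The elevation split
(tall vs short at the median ground height, ties to short) quantifies
height-dependent error. The bias–variance identity
RMSE² = bias² + var(error) holds to float tolerance and is asserted in the
tests.

Variance components come from the balanced two-way ANOVA by
expected-mean-squares equating (σ²ε = MSE, σ²ge = (MS_GE − MSE)/r,
σ²g = (MS_G − MS_GE)/(re)), with F-ratios F_G = MS_G/MS_GE,
F_E = MS_E/MS_GE, F_GE = MS_GE/MSE. EMS was chosen over REML because the
designs this package produces are exactly balanced by construction (REML is
the noted extension for unbalanced real data); an independent OLS-ANOVA
cross-check backs the implementation in the tests. Negative solutions are
truncated to zero and flagged. A single environment makes σ²ge inestimable
and is refused rather than silently absorbed.

Heritability uses the entry-mean form with the G×E term divided by the
replicate count r by default — the convention this package standardizes
on — with the more common alternative (divide by the number of environments
e) behind `ge_divisor="environments"`. Both are kept because published
formulas disagree and silent substitution would make reported h² values
incomparable; the two differ here by under 0.01 at the default design.

## QTL interval mapping

The two-stage ICIM scheme in regression (Haley–Knott) form:

1. forward–backward stepwise marker selection (entry/exit p-values
   0.001/0.002) picks background cofactors;
2. at each 1 cM grid position the phenotype, adjusted by the fitted
   cofactor effects — excluding cofactors within 10 cM of the position on
   the same chromosome, so a cofactor cannot absorb the locus under test —
   is regressed on the expected signed QTL genotype given the flanking DH
   marker genotypes under Haldane probabilities (collapsing to the observed
   genotype at a marker). LOD = (n/2)·log10(RSS₀/RSS₁); the additive effect
   is the coefficient on the ±1 expected genotype; PVE is expressed against
   the total variance of the unadjusted entry means.

A full mixture-model EM (as in dedicated interval-mapping software) is not
used: for a DH population the genotype distribution at a putative locus is
a two-component mixture and the regression approximation is accurate at
these sample sizes. Peaks are local maxima above LOD 2.5 with 1-LOD support
intervals; peaks on one chromosome whose supports overlap or that lie
closer than 20 cM are treated as one QTL (leftmost wins exact LOD ties);
per-peak PVE is recomputed from the joint regression on peak-nearest
markers. Cofactor-free scans show the classic "ghost peak" between two
linked QTL; the cofactor stage removes it, which the tests demonstrate.

## Genomic prediction

`RidgeBLUP` fits y = μ + Zu + ε with u ~ N(0, σ²u·I) on the centered signed
marker coding — ridge regression with λ = σ²ε/σ²u. REML estimates λ through
the eigendecomposition of ZZᵀ (the all-ones null direction, guaranteed by
column centering, is dropped together with the intercept): a 61-point grid
on log₁₀λ ∈ [−6, 9] followed by Brent refinement between the bracketing
grid points. A boundary optimum (e.g. a pure-noise phenotype drives
λ → ∞) triggers a loud fallback to λ = p. The intercept equals the training
mean exactly (the ones vector is in the null space of ZZᵀ). Fixed-λ fits
use the p×p normal equations when p ≤ n (required for λ = 0, which demands
full rank and n > p) and the n×n dual otherwise.

Cross-validation refits everything (including REML) inside each training
fold. Accuracy is the correlation between observed and predicted values
pooled over a repeat's folds **after centering both within each test
fold**: the per-fold prediction intercept is the training mean, which is
anti-correlated with the held-out fold mean, and uncentered pooling would
bias the null accuracy visibly below zero (≈ −0.04 at n = 80, k = 5).
Folds too small to center (leave-one-out) are pooled as-is. The
marker-exclusion experiment runs both arms on identical fold partitions per
repeat, so the accuracy difference is paired and partition noise cancels.

## Problem sizes and expected behavior

The default field (600 plots/site, ~6.8 Mpixel rasters) simulates, builds
terrain, and extracts in roughly ten seconds; the test suite exercises the
full default design for the recovery properties (terrain RMSE regime
1–5 cm; height R² ≥ 0.9 with nonpositive bias; h² agreement between
UAV-derived and true phenotypes within 0.05; major-QTL concordance within
5 cM; paired CV-accuracy drop under marker exclusion) and scaled copies for
everything else. Two behaviors are expected and by design, not defects:
the minor 6D locus sits near the LOD threshold (its realized marginal
effect varies with the polygenic draw), so it can cross 2.5 in one
phenotype source and not the other — minor-QTL instability across data
sources is a real phenomenon this generator reproduces; and absolute CV
accuracies run higher (~0.85) than typical field studies report, because
the simulated background is fully marker-borne on a compact map — the
directional and paired properties, not the absolute r, are the meaningful
checks.

## Limitations

* Elevation only: no spectral bands, no vegetation/soil classification —
  bare-ground polygons are inputs.
* No spatial field-trend models (row/column, AR1) in the ANOVA.
* Additive genetics only: no epistasis, no dominance (DH lines have none),
  single-trait.
* The GeoTIFF reader/writer handles the single-band, north-up, square-pixel,
  EPSG-coded case this pipeline produces; it is not a general GeoTIFF
  implementation.
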