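# Methods

## Scope and design

`radsem` quantifies how radiologist-style semantic scores relate to computed
radiomic features on 3D CT tumor volumes. The package has four analysis
stages (extract → prune → associate, plus a synthetic cohort generator that
stands in for patient scans) exposed both as scikit-learn-style estimators
and as a staged CLI pipeline. All conventions that affect numbers are fixed
here.

Axis convention: arrays are indexed `(x, y, z)`, 0-based, voxel centers at
`origin + index * spacing` (mm). Masks treat any nonzero voxel as
foreground. CSVs are UTF-8, comma-separated, `.` decimal, header mandatory;
undefined feature values serialize as empty cells.

## Radiomic features

**Discretization.** Texture matrices use fixed-width binning,
`level = floor((HU − min_in_mask)/w) + 1` with default `w = 25` HU anchored
at the in-mask minimum. This makes all texture features invariant to global
HU shifts. A constant region is a valid single-level case, not an error.
Filtered images are re-discretized with the same bin width on their own
dynamic range; for low-amplitude sub-bands this yields few levels, which is
accepted rather than hidden behind per-image adaptive binning (adaptive
binning would silently change the meaning of the bin-width parameter).

**Shape (13).** Volume = voxel count × voxel volume. Surface area comes
from a marching-cubes triangle mesh of the 0.5 level-set of the mask after
Gaussian smoothing at 0.6 mm; a raw binary mesh overestimates the area of
smooth bodies by a staircase factor, and the smoothed level-set removes that
bias (a radius-20 mm digital ball at 1 mm spacing measures sphericity
≈ 0.978; the package tests pin the window [0.95, 1.005]). Two guards handle
degenerate masks: if smoothing pushes the field below the level set (tiny
structures) the raw mask is meshed instead, and the area is floored at the
isoperimetric minimum (36πV²)^⅓ so sphericity can never exceed 1 through
measurement error. Sphericity ψ = π^⅓(6V)^⅔/A; compactness1 = V/(√π A^{3/2});
compactness2 = 36πV²/A³; spherical disproportion = A/(4πR²) with
R = (3V/4π)^⅓; surface-to-volume ratio; maximum 3D diameter (largest
pairwise distance between boundary-voxel centers, via the convex hull);
major/minor/least axis lengths 4√λᵢ from the PCA of voxel coordinates;
elongation √(λ₂/λ₁); flatness √(λ₃/λ₁). Voxel-count and PCA features are
exactly invariant under 90° grid rotations; mesh-derived features vary at
the triangulation level (≈1%) because marching cubes resolves ambiguous
cells orientation-dependently — a documented trade for the unbiased area.

**First-order statistics (12).** energy Σv², entropy on the 25-HU histogram
(log₂), excess kurtosis and skewness (population moments; NaN on constant
regions, logged), max/mean/median/min/range, mean absolute deviation, RMS,
population standard deviation.

**GLCM (17).** Distance-1 co-occurrence over the 13 unique 3D directions,
symmetric accumulation, per-direction normalization; features
(autocorrelation, cluster prominence/shade/tendency, contrast, correlation,
difference entropy, dissimilarity, energy, entropy, homogeneity, inverse
difference moment, inverse variance, maximum probability, sum average, sum
entropy, sum variance) averaged over directions that contain at least one
in-mask voxel pair. Correlation is NaN where the directional gray-level
variance is zero and is averaged over its defined directions.

**GLSZM (1).** Zones are 26-connected components of equal gray level.
Size-zone variability = (1/N_z) Σ_s (number of zones of size s)², large for
fragmented, heterogeneous regions.

**RLGL (5).** Maximal same-level runs inside the mask along each of the 13
directions (a gap in the mask breaks a run); short/long-run emphasis,
gray-level and run-length non-uniformity, run percentage = runs/voxels;
averaged over directions. Runs are extracted by a vectorized
line-decomposition (sort by line id and position, break on line change,
mask gap, or level change) validated against a walk-every-line oracle.

All three matrix families are validated to 1e-10 against exhaustive
brute-force enumeration (pair counting, BFS flood fill, line walking) on
small random regions.

## Filter bank

LoG responses are computed by FFT convolution with the sampled closed-form
3D kernel ((r² − 3σ²)/σ⁴)·G(x)G(y)G(z), σ in millimetres converted per axis
by the voxel spacing, truncated at 5σ, Riemann-weighted by the voxel
volume, and mean-corrected so constants map exactly to zero. Wavelet
sub-bands use a single-level undecimated (à trous) separable transform with
the coiflet-1 decomposition filters (taps from PyWavelets); sub-band letter
i is the filter on axis i, first letter = x. Undecimated analysis keeps all
sub-bands on the source grid so the original mask applies unchanged; the
transform is redundant (×8 for three axes; with periodic wrapping and an
orthonormal kernel the sub-band energies sum to exactly 8× the input
energy, which the tests check). Boundary handling everywhere is symmetric
(mirror) padding as part of the bit-exact contract. Defaults — LoG σ ∈
{1,…,5} mm and all 8 sub-bands — are conventional choices, overridable in
config; the filtered inventory is therefore explicit (13 images × 35
features by default) rather than an opaque count.

## Redundancy pruning

Midrank Spearman correlation of every feature pair (pairwise-complete over
NaNs; via pandas). Pruning is greedy largest-pair-first: among retained
features find the pair with the largest |ρ| ≥ threshold (default 0.85),
drop the member with the larger mean |ρ| against retained features, repeat.
Ties — in the pair choice and in the mean comparison (tolerance 1e-12 so
float summation order cannot decide) — break lexicographically on feature
name, making the procedure deterministic and column-order invariant. The
mean is taken over *currently retained* features, the natural reading of
"highest average correlation" during iterative removal. Constant columns
(undefined ρ) are force-dropped with their own reason code; NaN
correlations count as 0 in means. A post-condition audit asserts on every
run that no kept pair reaches the threshold.

## Association engine

Binary semantic features: raw AUC from midrank Mann–Whitney,
(R₁ − n₁(n₁+1)/2)/(n₀n₁), class 1 = presence, ties half-credit. AUC ≥ 0.5
is "proportional", otherwise "inverse" with folded AUC 1 − AUC (exact 0.5
folds proportional by convention). Significance by Noether's asymptotic
normal test with null variance (n₀+n₁+1)/(12n₀n₁) — the test is named in
the literature without a formula; the null-variance normal approximation is
the standard realization and is frozen here (a tie-corrected variance would
change p-values only marginally at these sample sizes). Ordinal semantic
features: midrank Spearman ρ for strength/direction and tie-corrected
Kruskal–Wallis (χ², groups − 1 df) for significance.

Multiple testing: Benjamini–Hochberg step-up within each semantic feature's
family (all radiomic tests against that column), matching per-column
starring of association matrices; q ≤ 0.05 flags significance (the
boundary-inclusive convention). NaN feature values are excluded pairwise
per test; cells with fewer than 10 usable observations are reported
"not-evaluated". Binary columns with a single class are skipped with a
warning. Under permuted labels with independent features, the fraction of
replicates with any significant cell per column stays at the nominal level
(tested at 100 replicates × 57 features).

## Synthetic phantom cohort

Each phantom is a star-convex radial body on a default 64³ grid at 1 mm
isotropic spacing: surface radius r(u) = R_ell(u)·(1 + L(u) + S(u)), where
R_ell is an ellipsoid whose eccentricity grows 0.09 per contour score step,
L is a smooth random angular field (plane-wave sum, wavenumber 2–4) with
amplitude 0.09·(lobulation − 1), and S a high-frequency field (wavenumber
9–14) with amplitude 0.03·(spiculation − 1); the perturbation is clipped at
a 2-RMS envelope so the promised grid-fit bound is exact. Concavity
subtracts (score − 1) spherical bites of radius 0.5R placed at depth
0.22R·(score − 1), breaking star-convexity only locally. Base radius is
drawn uniformly from 8–11 mm per subject (≈16–22 mm nodules, sized so the
largest perturbed tumor fits the default grid with margin).

Interior: texture score sets the tissue density (GGO −600 HU, part-solid
−350 HU with a solid 30 HU core, solid 30 HU); sub-solid tumors keep three
vessel-like bright strands (0.8 mm, −100 HU). Cavitation carves one main
air cavity (25% volume fraction) plus 2–4 satellite pockets at −1000 HU,
adds 0.12 extra boundary-irregularity amplitude (cavitating tumors are
more aggressive and irregular), and overlays a fine necrotic density
mottle (0.8 mm correlation length, 60 HU sd) on the tumor after border
blurring — necrosis is a tissue property, not an interface one, so it must
survive the border blur; without it interior heterogeneity was erased for
poorly-defined borders. Air bronchogram carves a 1.2 mm tube at −950 HU;
calcification stamps 1–3 spots of 1–1.5 mm at +300…+800 HU, small enough
not to distort the overall shape. Background is lung parenchyma at
−800 HU; the border is blurred with a Gaussian of 0.3/0.8/1.5 mm for
border-definition scores 1/2/3, then white noise (sd 30 HU) is added. The
mask is the rendered support *before* blurring.

Score marginals default to an observed lung-adenocarcinoma cohort
distribution (e.g. cavitation 59%, solid texture 71%, calcification 11%).
Subject seeds derive from the master seed by the counter scheme
`SeedSequence([master_seed, index])`, so cohorts are reproducible and
subjects independent. All score-to-knob constants were calibrated once so
that the intended phenotype directions are recoverable by the association
engine on an 80-phantom check cohort — sphericity falls with lobulation,
spiculation, concavity and cavitation; size-zone variability rises with
cavitation (folded AUC > 0.6); median HU rises with texture — and then
frozen; they are not fitted to any external data. The air-bronchogram tube
geometry has no quantitative anchor in the literature we follow; it is a
documented free choice.

**What the generator does and does not emulate.** It reproduces the
*direction* structure linking scores to geometry and density, realistic HU
ranges, anisotropy support, and cohort score marginals. It does not model
scanner physics (reconstruction kernels, beam hardening), anatomy (vessel
trees, pleura, ribs), inter-reader score noise, or correlations *between*
semantic scores (sampled independently, unlike real cohorts where e.g.
spiculation and lobulation co-occur). Passing direction-recovery tests
therefore shows the pipeline recovers encoded phenotypes at realistic
noise, not that real-cohort effect sizes are reproduced — those depend on
patient data that no synthetic stand-in can supply.

## Problem sizes and runtime choices

Statistical tests run on a 200-phantom cohort at 64³ (the package's
reference cohort size, large enough that every encoded direction reaches
q ≤ 0.05 with margin); the FDR null uses 100 permutation replicates of 57
independent features × 258 subjects; oracle equivalence uses regions up to
4×4×4 with ≤4 gray levels where exhaustive enumeration is exact and cheap.
The acceptance script regenerates everything from scratch in about two
minutes on one CPU.

## Known limitations

- Mesh-surface features are only ≈1%-stable under grid rotations
  (triangulation of ambiguous marching-cubes cells); voxel-count and PCA
  features are exact.
- Fixed-width discretization on filtered images can collapse to very few
  gray levels for low-amplitude sub-bands; features remain well-defined but
  carry little information there.
- The greedy pruning order (largest pair first) is one deterministic
  realization of the "drop the highest-average-|ρ| member" rule; other
  orders can keep a different, equally valid feature subset.
- Noether's test uses the null-variance normal approximation; exact
  permutation p-values would differ for very small groups (the engine
  refuses cells with n < 10 instead).
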