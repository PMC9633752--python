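# Methods

## Problem setting

MR-guided SBRT delivers 3–5 high-dose fractions to liver lesions (primary
hepatocellular carcinoma, intrahepatic cholangiocarcinoma, or metastases),
with a volumetric 0.35 T setup image acquired before every fraction
(typical voxels 1.5 × 1.5 × 3.0 mm).  The analysis asks whether the
*change* in second-order texture features of the gross tumor volume
between the pre-treatment image and images acquired after fixed quanta of
biologically effective dose (BED 20 and 40 Gy) predicts local control.
The package implements that analysis end to end; response labels
(poor response = progressive disease of the treated lesion) are inputs,
not something the package assesses.

## ROI preparation

**Collewet dynamic-range constraint.**  ROI intensities are clipped into
`[μ − kσ, μ + kσ]` with `k = 3` and μ, σ computed over ROI voxels only —
background must not influence the dynamic range.  σ defaults to the
population (divide-by-n) estimator; `sigma_divisor="n-1"` is available
because the divisor is a convention, not a substantive choice: it moves
only values at the clip boundary.

**Histogram-equalization quantizer.**  Voxels map to integer levels
`1..Ng` (`Ng = 64`) by `level(x) = floor(Ng · F⁻(x)) + 1`, where `F⁻(x)`
is the fraction of ROI voxels strictly below `x`.  Properties that drove
this choice of transfer function (equalization is a named method but its
exact transfer function is a design decision):

- monotone in the input; ties share a level; levels always in `1..Ng`;
- `n` i.i.d. continuous draws occupy each level equally (exactly `n/Ng`
  when `Ng | n`), which is the point of equalization;
- a constant ROI maps to level 1 with no special casing, so zero-variance
  lesions flow through the pipeline (single-level matrices are defined);
- idempotent: re-quantizing the produced levels is a no-op.  The
  right-continuous variant `ceil(Ng · F(x))` fails idempotency whenever a
  pass merges all values into one level and also sends constant input to
  level `Ng`, which is why it was rejected.

A 1e-9 guard inside the floor absorbs float rounding of `Ng · k / n`
products; attainable products are spaced ≥ `Ng/n` apart, orders of
magnitude wider than the guard.

Order is fixed: normalize, then quantize.  Computation is restricted to
the mask bounding box purely for speed; tests assert bit-identical
features against full-grid computation.

## Texture matrices and the 39 features

All matrices are 3D, built on the voxel lattice: offsets are in voxels
(not mm), using the 13 unique direction vectors (half of the
26-neighborhood); anisotropic spacing is carried on the data structures
but does not reweight offsets.

- **GLCM**: symmetric co-occurrence counts at Chebyshev distance 1
  (configurable), merged over the 13 directions into a single matrix
  before normalization (per-direction feature averaging is available via
  `TextureConfig(glcm_aggregation="averaged")`).  Pairs with either voxel
  outside the ROI are excluded.
- **GLRLM**: maximal equal-level runs per direction, merged; a run breaks
  at the ROI boundary or a level change.  Every ROI voxel lies in exactly
  one run per direction, so the matrix's voxel mass is `13 · N_voxels`.
- **GLSZM**: maximal 26-connected equal-level components; zone mass
  `Σ s·P(i,s)` equals the ROI voxel count.
- **NGTDM**: for each ROI voxel with at least one ROI neighbor, the
  absolute difference between its level and the mean level of its valid
  26-neighborhood, summed per level.

The canonical 39-feature vector is 8 GLCM (energy, contrast, correlation,
homogeneity, variance, sum average, entropy, dissimilarity), 13 GLRLM and
13 GLSZM (the classic run/zone formula family: short/long emphasis,
gray-level and length/size non-uniformity, run/zone percentage, low/high
gray-level emphases and their four combinations, gray-level and
length/size variance), and 5 NGTDM (coarseness, contrast, busyness,
complexity, strength).  The registry is an ordered, data-driven mapping
(`texture.FEATURE_NAMES`), so the set can be re-mapped if a different
enumeration is ever required; only energy and large zone emphasis are
pinned as headline features.

Degenerate conventions, chosen so longitudinal series never crash
mid-cohort: a ROI with no co-occurring pair (isolated voxels) uses the
diagonal level-histogram distribution for the GLCM (a lone voxel is
maximally homogeneous, energy 1); GLCM correlation of a single-level ROI
is 1; NGTDM features are 0 when no voxel has a valid neighbor, with
coarseness capped at 1e6 (the conventional value for perfectly smooth
input — an uncapped value would be infinite).  Every feature is finite
for every non-empty ROI, and the test suite enforces it.

All four builders are verified against independent brute-force oracles
(pair enumeration, scan-line runs, BFS flood fill, per-voxel neighborhood
loops) on dozens of random small ROIs.

## BED checkpoints and delta features

`BED = n·d·(1 + d/(α/β))`, α/β = 10 Gy, equal dose per fraction in
prescription order.  Setup image k precedes fraction k, so its cumulative
BED is `(k−1)·d·(1 + d/(α/β))`.  A checkpoint (20/40 Gy) is realized by
the **first image at or after** the target (ceiling rule): exact hits are
rare across heterogeneous schedules (BED per fraction in the packaged
cohort ranges 9.6–50.4 Gy), and the realized BED is stored with every row
so the approximation is auditable.  A course that never accumulates the
target before its last image is *unreachable* for that checkpoint —
reported in a per-checkpoint exclusion table, never silently dropped and
never excluded from the other library.  A single high-dose fraction can
realize both checkpoints with the same image, in which case the two delta
rows coincide.

Delta sign convention: `f(checkpoint) − f(baseline)`; downstream AUCs are
invariant to a global sign flip.

## Modeling

- **Baseline screen**: Welch t-test per feature by default (pooled
  variance via `equal_var=True`), Bonferroni `p_adj = min(1, 39·p)` at
  α = 0.05.  Features constant in both classes report p = 1.
- **Gini ranking**: 500 trees, mtry = 6 (≈ √39) candidate features per
  split, bootstrap resampling with replacement; importance is mean
  decrease in Gini impurity.  Ties break by canonical feature order
  (stable sort); the seed is an explicit argument, so rankings are
  bit-reproducible.
- **Internal validation**: 1,000 Monte-Carlo iterations; each trains on
  `floor(2n/3)` patients drawn **without** replacement and tests on the
  disjoint remainder — with-replacement sampling could not leave a
  disjoint held-out third, so subsampling is the only consistent reading.
  Iterations with a single-class train or test partition have no defined
  AUC; they are redrawn and the redraw count is reported (at 15/7 class
  balance this affects a few percent of draws).  The logistic model
  carries a weak L2 penalty (C = 1e4) so complete separation at n = 22
  still converges; penalized scores are monotone in the unpenalized ones,
  so AUCs are unchanged.
- **AUC** is the Mann–Whitney probability of correct ranking with half
  credit for ties (cross-checked in tests against explicit pair
  counting).
- **Clinical / combined forests**: 500 trees, mtry = 6 over the clinical
  covariates and mtry = 8 when the top-2 delta features are added.  Two
  covariate presets ship — the declared protocol list (BED/fraction,
  tumor size, sex, ethnicity, KPS, cirrhosis) and the list exercised on
  the packaged table (age, total BED, BED/fraction, tumor size), which
  lacks the unrecorded covariates; requesting an absent covariate is an
  error, not an imputation.  The training-phase AUC is out-of-bag and
  labeled as such (resubstitution AUC of a random forest is ~1 by
  construction and carries no information).

## Synthetic cohorts

The generator emulates the *statistical shape* of the study data, not MR
physics.  Defaults copy the cohort conditions: 22 patients, 7 poor
responders, 48×48×16 grids at 1.5×1.5×3.0 mm, fractionation schedules
drawn from the packaged cohort's menu (30–60 Gy in 3–5 fractions), ages
49–94, sizes 1.3–8 cm.

Each lesion is an ellipsoid (semi-axes 11–15 mm in-plane, 8–11 mm axial —
several hundred voxels, so zone statistics are non-degenerate) filled
with a Gaussian random field: a per-patient white-noise field smoothed to
correlation length ℓ and unit variance, plus fresh per-timepoint white
observation noise (SD 0.15 of the field SD).  The white field is fixed
per patient so consecutive images share anatomy; with zero noise and a
unit trajectory multiplier, later timepoints reproduce the baseline image
exactly.

ℓ is the texture-homogeneity knob: larger ℓ → larger uniform regions
after quantization → higher GLCM energy and GLSZM large zone emphasis.
Class trajectories multiply the baseline ℓ₀ = 2.5 mm by a
piecewise-linear function of cumulative BED through (0 Gy, 1),
(20 Gy, m20), (40 Gy, m40): responders (2.0, 1.15) — homogeneity rises
sharply by the 20 Gy checkpoint and mostly relaxes back by 40 Gy; poor
responders (0.5, 0.85) — the mirrored opposite.  ℓ₀ = 2.5 mm keeps many
independent texture blobs inside a lesion; substantially longer baseline
correlation lengths leave so few blobs (~tens) that feature-estimator
variance swamps the class effect and the planted signal is not reliably
recoverable — an instructive failure mode for real small-ROI radiomics,
but not the regime the default generator is meant to produce.

What passing tests on these cohorts shows: the pipeline's plumbing,
ranking and validation machinery recover a planted longitudinal texture
effect of realistic geometry under realistic fractionation heterogeneity,
and the null regime (no effect) yields chance-level AUC.  What it does
not show: anything about real MR contrast, lesion heterogeneity across
histologies, contouring variability, or the clinical effect size — the
study's patient images are unpublished, so its reported AUCs are treated
as regime descriptions, not reproduction targets.

The table-level generator bypasses images entirely: 39 standard-normal
delta columns with planted columns shifted ±effect/2 by class (class
means `effect` SDs apart, responders up / progressors down).  A
single fixed null cohort of n = 22 has a held-out AUC that varies widely
around 0.5 (the dataset's idiosyncratic spurious association dominates),
so null-behavior checks average over many generated cohorts.

## Numerical and degenerate-input choices

- Quantizer float guard 1e-9 (see above); BED checkpoint comparison uses
  a 1e-9 Gy tolerance so exact-hit schedules are not missed to rounding.
- Empty ROIs, empty cohorts, and missing baselines are errors; an
  unreachable checkpoint is a reported state, not an error.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / scikit-learn `random_state`); generators
  derive per-patient, per-timepoint streams from `SeedSequence` spawns so
  cohorts are reproducible element-wise.

## Problem sizes used in the shipped checks

The test suite and example runs use desk-scale sizes chosen to exercise
every code path: oracle comparisons on ROIs up to 8×8×4 at Ng ≤ 8 (the
brute-force oracles are quadratic); image cohorts of 22 patients on
48×48×16 grids; 300–1,000 Monte-Carlo iterations; 10–50 seeded
repetitions for recovery-rate checks.

## Known limitations

- The 39-feature enumeration matches the classic texture-toolbox family
  counts, but the study's exact feature list is not published; only
  energy and large zone emphasis are certain.  The registry is data-driven
  to allow re-mapping.
- GLCM/GLRLM offsets ignore voxel anisotropy (no mm-space reweighting),
  matching the voxel-lattice convention of the classic toolboxes.
- Fractions are assumed equal-dose and delivered in order; adapted plans
  with per-fraction dose variation are out of scope.
- The synthetic generator is a surrogate; its trajectory multipliers are
  engineered, and conclusions about real tissue require real data.
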