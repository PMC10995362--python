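# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of each analysis stage, and what the synthetic generators do and
do not emulate.

## Ocular magnification

Lateral retinal dimensions are corrected with the axial-length (AL)
approximation q = a·(AL − b), a = 0.01306 mm/deg/mm, b = 1.82 mm: the
retinal size per pixel of an instrument calibrated for a reference eye
(default AL_ref = 24.00 mm, configurable) is multiplied by
(AL − b)/(AL_ref − b). Both constants are exposed in configuration so
alternative schematic-eye variants can be substituted. Only *lateral*
(transverse) dimensions are corrected; axial OCT distances depend on the
group refractive index of the tissue, not on ocular magnification, and are
taken as instrument-calibrated. Valid biometry is enforced as
AL ∈ (15, 40) mm and SE ∈ (−30, +15) D.

## Cone mosaic morphometry

**Detection.** Commercial AO software is proprietary, so the detector is a
standard spot-detection chain: difference-of-Gaussians band-pass with
σ₁ = 0.2 × expected spacing (σ₂ = 2σ₁), local maxima with minimum
separation 0.5 × expected spacing, relative peak threshold 10 % of the
band-passed maximum, and center-of-mass refinement of the positive
band-passed signal in a 5 × 5 px window. All parameters live in
`DetectionParams`. A zero-variance ROI returns zero cones with a warning.
Vessel avoidance is the caller's responsibility: `ROISpec` accepts a
perpendicular offset for manual ROI displacement, and no vessel detector is
included.

**Metrics.** Density is the raw count over the ROI area. "Adjacent cones"
are Delaunay neighbors; edges longer than 3 × the median edge length are
discarded before averaging, which suppresses convex-hull artifacts at ROI
borders while matching the nearest-neighbor notion of spacing. (Mean
nearest-neighbor distance is also computed and reported as `nn_spacing`;
the Delaunay-edge mean is the default spacing.) Regularity counts Voronoi
cells with 5–7 sides; cells whose polygon is unbounded or touches outside
the ROI square are excluded from numerator *and* denominator, because
border cells have undercounted neighbors. With fewer than three cones,
spacing and regularity are NaN and flagged. ROIs default to 100 × 100 μm at
0.6 mm (inner) and 1.2 mm (outer) eccentricity along the four meridians;
per-region summaries are unweighted means over the ROIs of a region.

## Choroid quantification

**Linearization.** Each column is shifted by an integer number of pixels so
the RPE–Bruch boundary lands on its median row; all boundaries shift
consistently, and shifted-in pixels carry a fill value with a validity
mask. Integer shifts leave a sub-pixel residual (< 0.5 px by construction)
and avoid interpolating speckle.

**Binarization.** Niblack's local threshold T = m + k·σ over a square
window, applied to the linearized scan; pixels strictly below T inside the
choroid mask are lumen, the rest stroma. Defaults k = −0.2 (the classic
dark-object weight) and window = 51 px (near the scale of medium choroidal
vessels at ~6 μm/px) — neither is dictated by the protocol we follow, both
are configurable. Because the threshold is affine-equivariant, CVI is
invariant to any positive affine intensity rescaling of the scan, which the
tests assert.

**Areas.** TCA and LA are pixel counts × (lateral × axial pixel area),
reported in mm²; SA = TCA − LA so LA + SA = TCA holds exactly by
construction. CVI = LA/TCA; a zero-area subfield flags CVI undefined.
CT is the mean per-column boundary separation × axial scale. Subfields are
column strips at 0.5–1.0 mm (inner) and 1.0–1.5 mm (outer) eccentricity,
pooled over both sides of the fovea; with only horizontal and vertical
scan lines available, strips — not annuli — are the natural region shape.
Lateral scales should be magnification-corrected per eye via the
magnification module; raw pixel counts are preserved in the areas
(divide by the scale factor squared to undo).

**Sublayers.** Thicknesses are mean per-column separations of named
boundary pairs (OPL, HFL+ONL, IS, OS, IZ+RPE) × axial scale. Boundaries
arrive as annotation files (JSON or CSV, one depth per column); the
segmentation algorithm itself is out of scope, and the `BoundarySet`
container rejects crossing boundaries.

**Agreement.** The coefficient of repeatability is 1.96 × SD (ddof = 1) of
the paired differences; ICC is the two-way random-effects,
absolute-agreement, single-measurement form (ICC(2,1), via pingouin). Two
constant series make ICC undefined and are flagged.

## Psi-method CSF estimation

**Psychometric model.** Weibull for 2AFC:
P(correct | c) = γ + (1 − γ − λ)(1 − exp(−(c/τ)^β)), γ = 0.5, λ = 0.02.
Defining τ at the 1 − 1/e point puts threshold performance at
0.5 + 0.48 × (1 − e⁻¹) = 0.80337…, i.e. the 80.3 %-correct criterion the
adaptive procedure targets. This back-derivation anchors all simulated
observers.

**Grid and prior.** Discrete posterior over log₁₀ τ ∈ [−3, 0] step 0.02
(151 points) × 10 log-spaced slopes, uniform prior; candidate contrasts are
the τ grid. The slope grid spans **β ∈ [1.5, 8]**: empirical 2AFC contrast
psychometric slopes fall in roughly 2–5, and admitting hypotheses much
shallower than 1.5 measurably biases the marginal posterior-mean threshold
low at 45 trials (≈ −0.017 log₁₀ units with a [0.5, 8] grid, enough to pull
performance at the estimate to 78.5 %). With the default grid the estimator
is unbiased to < 0.01 log units with RMSE ≈ 0.06 at 45 trials. All grid
limits are configurable.

**Selection and update.** Each trial presents the candidate minimizing the
expected posterior entropy over the two possible responses
(Kontsevich–Tyler rule); ties within 1e−12 break toward the lower
contrast, and a degenerate point-mass posterior returns the candidate
nearest the posterior-mean threshold. The update is exact Bayes on the
grid with renormalization; a zero total likelihood (numerical underflow)
raises rather than silently renormalizing. Expected entropies are computed
from precomputed likelihood tables as matrix–vector products, so a
45-trial staircase costs ~25 ms.

**Estimator.** Posterior mean of marginal log₁₀ τ — smoother at small n
than the MAP.

**Summaries.** AULCSF integrates max(log₁₀ S, 0) against log₁₀ f
trapezoidally over the measured band [1.5, 24] cpd; negative
log-sensitivities are clipped at zero so unmeasurable frequencies cannot
subtract area. The cut-off SF solves the descending limb of the log-CSF
for log₁₀ S = 0 in (log₁₀ f, log₁₀ S) coordinates: an interior descending
zero crossing is interpolated; otherwise the last segment is extrapolated;
a non-descending tail is flagged and floored at log₁₀ f_max. Cut-off is
reported in log₁₀ cpd, consistent with observed clinical values of
1.29–1.42 (≈ 19–26 cpd). Sessions run one independent staircase per
frequency (45 trials each, 270 total) and can be refit offline from a
recorded trial log.

## Cohort statistics

Group comparisons use one-way ANOVA (overall P0) plus pairwise two-sample
Student t-tests labelled P1 = EM vs LM/MM, P2 = EM vs SHM,
P3 = LM/MM vs SHM (Welch available by flag; no multiplicity correction, and
the pair labelling is configurable since naming conventions vary). The sex ×
group table is tested with Pearson's chi-square without continuity
correction; empty margins are rejected. The regression screen fits one OLS
per candidate predictor, admits those with p < 0.05 to a multivariable
model, then backward-eliminates the largest-p predictor until all retained
predictors have p < 0.05; both raw and standardized (β·SDx/SDy) coefficients
are reported, complete cases per model, and a standardized-design condition
number above 10³ flags collinearity. Mixed/random-effects models are
deliberately out of scope (one eye per subject; no repeated-measures
structure).

## Synthetic generators

All generators are deterministic under a fixed seed.

**Cone mosaics.** Hexagonal lattice with constant s = √(2/(√3·density)),
i.i.d. Gaussian positional jitter (SD as a fraction of s), Bernoulli
dropout, rendered as unit-amplitude Gaussian spots (σ = 1 μm at 0.5 μm/px)
plus additive Gaussian noise; default density 20,000/mm² is typical of the
healthy parafovea at 0.6–1.2 mm eccentricity. Not emulated: vessel
shadows, rods, frame-averaging artifacts, or eccentricity gradients within
one ROI — so detector tests certify the measurement chain on clean
quasi-regular mosaics, not robustness to clinical image quality.

**Choroid phantoms.** A band of target thickness between smooth sinusoidal
boundaries; dark elliptical lumens (intensity 60) in bright stroma (180)
with Gaussian speckle (SD 15), vessel radii 15–60 μm. Ellipses are added by
rejection sampling until the labelled lumen fraction lies within ±0.01 of
target (a candidate overshooting the window is rejected). The rendered
intensities are exactly two-level plus noise — no optical blur — so the
per-pixel labels are an exact ground truth for binarization accuracy;
recovery error at default contrast is ≈ 0.02 and shrinks as contrast
grows. Real speckle is multiplicative and spatially correlated; this
phantom does not claim to model it.

**Observers.** Truncated log-parabola CSF:
log₁₀ S(f) = log₁₀ G − 4 log₁₀ 2 ((log₁₀ f − log₁₀ f₀)/w)², floored at
log₁₀ G − δ below the peak. Defaults G = 100, f₀ = 3 cpd, w = 0.65,
δ = 0.5, Weibull slope 3, lapse 0.02 give an AULCSF within the observed
adult range 1.5–1.9 and a cut-off near 21 cpd. Responses are Bernoulli
draws from the package's own psychometric function.

**Cohorts.** Three groups of 20/26/35 eyes with SE and AL drawn from
truncated normals matching the study-population means ± SD and printed
ranges; draws are resampled until the re-derived refractive-group rule
(SHM iff SE ≤ −6.00 D or AL ≥ 26.5 mm) agrees with the intended label, so
emitted tables respect the rule exactly. Every downstream outcome is
linear-Gaussian in AL: value = intercept(24 mm) + slope·(AL − 24) + noise,
clipped to physiological bounds. Default slopes are negative for cone
density, regularity, CT, CVI, TCA, AULCSF, and cut-off, positive for cone
spacing and OS thickness, with magnitudes and noise SDs chosen to put
group means and correlation strengths near clinically reported values
(e.g. AULCSF slope −0.066 per mm). Couplings are free parameters of
`CohortSpec` — the defaults are plausible, not estimates. Device-reported
flow metrics (vessel densities, FAZ area) are generated as weakly coupled
columns and only ever consumed as given.

## Pipeline and reproducibility

Stages (simulate → cones → choroid → csf → stats) run in dependency order
under a validated configuration; unknown or invalid fields are rejected by
name. Outputs are plain CSV/JSON/TIFF with fixed float formatting and
sorted JSON keys, no timestamps; a manifest records seed, config hash
(scientific parameters only, not output paths), and package version.
Reruns with the same seed are byte-identical, which the tests assert
file by file.

## Problem sizes used in validation

Closed-form cone checks use a 1 × 1 mm lattice (~46k points); detector
recall/precision uses a 120 × 120 μm field at 20,000/mm². Staircase
calibration uses 500 simulated 45-trial runs (performance criterion) and
200 runs × {15, 45, 90} trials (bias/RMSE and convergence). Statistical
calibration uses 1000 null ANOVA simulations at n = 30 × 3 and a 200-case
regression recovery. These sizes make the checks stable to simulation
error at the stated tolerances.

## Known limitations

- The cone detector is tuned for quasi-regular mosaics near 20,000/mm²;
  heavily blurred or low-SNR clinical frames may need retuned band-pass
  scales.
- CVI depends on the binarization parameters; values are comparable only
  within a fixed (window, k) protocol. The defaults here are one such
  protocol, not a calibration against any device.
- Cut-off SF extrapolates the last measured segment; observers whose CSF
  has not begun to descend by 24 cpd are floored and flagged rather than
  extrapolated.
- The statistics stage implements fixed-effects OLS only; correlated eyes
  within subject would require mixed models that are out of scope.
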