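# Methods

`ccfd` quantifies flow deficits (FDs) of the choriocapillaris — the
capillary layer directly beneath the retinal pigment epithelium — from
pairs of co-registered en face OCTA slabs of a 3 × 3 mm macular scan, and
provides the cohort statistics layer used to relate those deficits to
clinical covariates. This note describes the model and procedure, the
parameters that matter, the synthetic material used to validate the
pipeline, and the numerical choices and limitations.

## Image model and pipeline

An *en face slab* is a 2-D grayscale projection of the OCTA volume over a
thin depth interval. Two slabs enter per eye: a **flow** slab (the
decorrelation/flow signal of the choriocapillaris) and a **structure**
slab (reflectivity over the same depth interval). Intensities are
normalized to [0, 1] at load (`raw / (2^bits − 1)`), because the
thresholding formula below contains an exponential term that assumes a
bounded intensity scale. The default raster is 512 × 512 over 3 × 3 mm
(pixel pitch 3000/512 ≈ 5.859 µm); this is the unique pitch under which
the four standard window-radius conversions (26.37 / 49.80 / 61.52 /
90.82 µm for 4 / 8 / 10 / 15 px, using the center-pixel-inclusive
convention `(r + 0.5)·pitch`) all reproduce to two decimals. It is
configurable, never assumed.

### 1. Shadow compensation

Drusen and drusenoid pigment-epithelial detachments attenuate the OCT
beam, darkening both slabs below them; uncorrected, the shadow is
misread as a flow deficit. The compensation is the standard
invert–blur–multiply scheme:

    compensated = rescale( flow × G_σ(1 − structure) )

where `G_σ` is a 2-D Gaussian with reflective boundary handling and
`rescale` is a min–max map onto [0, 1] (a constant product maps to all
zeros). Where the beam was attenuated, the inverted structure slab is
bright and boosts the flow signal. This multiplicative correction is not
a division: it removes the shadow exactly only when the structural
background sits near `1/(1 + a)` for attenuation `a`, and approximately
otherwise; the local threshold below absorbs most of the smooth residual
gain. The blur standard deviation is **not** standardized anywhere;
`blur_sigma_px = 2.0` is the default here — enough to suppress speckle in
the structural signal without smearing individual drusen shadows
(drusen radii of interest are ≥ 10 px) — and is exposed in the
configuration so its sensitivity can be probed.

### 2. Phansalkar local thresholding

Each compensated pixel is classified by the Phansalkar local threshold,
designed for low-contrast images. Over the circular window of radius
`r` pixels (center distance ≤ r; boundary by reflection with edge
duplication), with local mean µ and *population* standard deviation σ:

    T = µ · (1 + p·e^(−q·µ) + k·(σ/r_norm − 1)),
    k = 0.25, r_norm = 0.5, p = 2, q = 10

A pixel is flow iff intensity > T; ties are deficits. The shape
constants are the original publication defaults; only the radius is a
study-level choice (15 px ≈ 90.82 µm for the primary analysis, with
4/8/10 px sweeps for sensitivity). The implementation computes µ and σ
by normalized correlation with the disc footprint (two passes: mean and
mean of squares) and is validated against a brute-force per-pixel window
loop to < 1e−9 on 64 × 64 images; classification is done at full float
precision (an 8-bit quantization step before thresholding, as some
legacy toolchains apply, could shift a small number of borderline
pixels).

### 3. Flow-deficit morphometry

Deficit pixels are grouped into **8-connected** components (diagonal
contact joins; this is the particle-analysis default and changes the
count materially, so it is fixed and documented). No size or
circularity filtering is applied, and components touching the frame are
kept. Per eye:

* `fd_percent` = 100 × deficit pixels / total pixels,
* `n_fd` = number of components,
* `mean_fd_size_um2` = mean component area (pitch² per pixel),
* `total_fd_area_mm2` = summed deficit area.

`n_fd × mean_fd_size_um2` equals the total area in µm² exactly, by
construction. Cohort-level "FD size" is the mean across eyes of the
per-eye mean component area (the across-eyes convention); pooling all
components of all eyes before averaging is available via the per-eye
component size vectors but is not the reported default.

### 4. Radius sensitivity

`sensitivity_analysis` re-binarizes each compensated image at each
radius and reports the cohort mean and sample SD of FD%, FD count and
mean FD size per radius. On synthetic cohorts the qualitative behavior
reported for patient cohorts reproduces: FD count falls and FD% and
mean size rise as the radius grows from 4 to 15 px.

## Cohort statistics

* **Group summaries**: arithmetic mean and sample (n−1) SD.
* **Fisher exact, two-sided** (binary flags): minimum-likelihood rule —
  the p-value sums the hypergeometric point probabilities of every table
  with the observed margins whose probability does not exceed the
  observed table's. Computed in exact integer arithmetic (all
  probabilities share the denominator C(N, row₁), so comparisons and the
  sum are exact); a zero margin returns p = 1 with a warning.
* **Mann–Whitney U, two-sided** (quantitative variables): exact null
  distribution when the pooled sample has ≤ 20 observations and no ties,
  otherwise normal approximation with tie and continuity corrections.
* **Regression screen**: stage 1 fits one OLS model per covariate;
  stage 2 fits a single OLS model on all covariates with univariate
  p < 0.20 (threshold configurable). Published protocols often add "or
  clinically significant" to the screen; that subjective clause is
  replaced by an explicit `forced` covariate list (default empty) for
  reproducibility. By the usual table convention the three FD outcomes
  and age/CMT/CT are modelled in log10; both transforms are explicit
  arguments so any variant (including raw-scale recovery tests) is
  expressible. A rank-deficient stage-2 design raises an error naming
  the dependent columns.
* **Log–log size–number fit**: OLS of log10(FD count) on log10(mean FD
  size) across eyes, returning slope, intercept (on the log10 scale) and
  R². Reported intercepts of such fits are sometimes quoted as the
  back-transformed count at unit size (e.g. +2267 ⇒ log10 intercept
  ≈ 3.356); this package always reports the log10-scale intercept.
* No multiple-testing correction is applied (matching standard practice
  in these cohort tables); p < 0.05 is the conventional significance
  level.

## Synthetic data: what it emulates and what it does not

No per-eye scans are publicly deposited for this kind of study, so all
pipeline validation runs on synthetic scenes with known ground truth.

**Scene generator.** The deficit mask is made by thresholding a
Gaussian-smoothed noise field at the quantile matching the target FD
fraction — this yields the irregular, scale-controllable morphology of
real deficit maps and *exact* control of the planted fraction (realized
fraction deviates from target only through ties, far inside the ±0.02
guarantee). The flow slab takes `flow_level` on flow pixels and
`deficit_level` on deficit pixels plus Gaussian noise; the structure slab
is a uniform bright field plus independent noise. Drusen are soft-edged
discs (edges smoothed with a 3-px Gaussian, emulating the penumbra of
real shadows) that multiply *both* channels by the same attenuation
factor — precisely the artifact the compensation removes.

**Defaults are the study conditions.** `target_fd_fraction = 0.45`
matches the ≈46% FD operating point of elderly AMD-fellow-eye cohorts;
`attenuation = 0.6` is a representative drusen shadow depth;
`flow_level/deficit_level = 0.30/0.12` put the slab in the dark regime
of real choriocapillaris flow slabs, where the threshold's `e^(−qµ)`
term makes shadowing consequential (in a bright scene a local threshold
is nearly scale-invariant and shadows would be cosmetic); `noise_sd =
0.05`; 24 drusen of radius 18–48 px (≈105–280 µm, the large-drusen/PED
scale) cover roughly a quarter of the field. Drusen parameters are drawn
*last* from the seeded generator, so paired scenes with and without
drusen share the same deficit mask and noise realization.

**Cohort simulator.** Covariates follow the profile of an elderly
AMD fellow-eye cohort (age ~ N(79, 7.7²); CT ~ N(209, 83²) µm; drusen
flag prevalences ≈ 0.2–0.7). FD% follows its own linear model
(default: age effect 0.62 %/year plus N(0, 10²) residual); FD size is
log-normal; FD count follows the planted log–log law
(slope −0.0604). FD% and count × size are deliberately *not* tied
through the per-image area identity: published cohort marginals for
these three quantities are themselves mutually inconsistent (mean count
× mean size ≠ mean total area, as means of skewed ratios), so the
simulator plants the statistical relations the tests must recover, not
an image-level identity. Per-eye simulated metrics keep count, size and
total area consistent pairwise.

**What passing tests do and do not show.** Ground-truth recovery,
shadow robustness and parameter recovery on this material validate the
*algorithmic* chain. Real SS-OCTA slabs additionally contain speckle
with non-Gaussian statistics, projection artifacts, segmentation errors
of the manually adjusted slab, and motion artifacts — none of which are
emulated. Passing here therefore demonstrates correctness of the
computation, not clinical validity of FD estimates on any device.

## Numerical choices

* Boundary handling is reflection (edge-duplicating, "symmetric") for
  blur and windowed statistics — avoiding the frame darkening that
  zero-padding would cause, which would inflate FD% at the image border.
* σ in the threshold is the population SD of the window (reference
  implementation behavior); cohort summaries use the sample (n−1) SD.
* Intensity exactly equal to its threshold classifies as deficit.
* Min–max rescale after compensation; a constant product yields zeros.
* Component labelling and metrics are integer/boolean computations and
  bit-reproducible across platforms; the whole quantification chain is
  deterministic, randomness exists only in the synthetic generators and
  is fully seed-driven.
* Degenerate inputs: empty masks give zero metrics (no NaNs); a
  Phansalkar radius above half the image extent warns and computes; a
  zero-margin 2 × 2 table returns p = 1 with a warning.

## Problem sizes used in the test and acceptance suites

Validation runs use full 512-px scenes where the property under test
concerns the default geometry (shadow robustness) and 96–256-px scenes
for recovery, sweep-trend and orchestration tests; simulation recovery
uses 100 replicate cohorts of 89 eyes. These sizes were chosen so the
statistical properties under test are comfortably resolved.

## Known limitations

* The compensation is the multiplicative invert–blur–multiply scheme
  only; no model-based or inverse-variance attenuation correction.
* Only the Phansalkar threshold is provided (no Niblack/Sauvola/global
  alternatives), since the radius semantics and micron conversions are
  tied to it.
* No topographic/ETDRS-subfield analysis; metrics are whole-image.
* The synthetic non-neovascular comparison arm reproduces only the
  reported *marginal* flag counts; its quantitative covariates are
  placeholders, so only flag (Fisher) comparisons are meaningful on it.
* Blur σ and the post-multiplication rescale convention are not
  standardized in the field; both are explicit configuration here, and
  absolute FD% values shift by a few points across reasonable choices
  (the radius sweep shows the same sensitivity).
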