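# Methods

This note documents the models and procedures implemented in `facestat`,
the conventions and defaults chosen where several reasonable options exist,
and what the synthetic-data generator does and does not emulate.

## Spectral slope estimation

An image is resampled to 512×512 by bicubic interpolation, transformed with
an unwindowed 2-D FFT, and its power `|F|²` is averaged over integer-radius
annuli (`f = round(√(u²+v²))` in cycles/image; DC excluded).  A line is
fitted by ordinary least squares to the binned log-log spectrum over 10–255
cycles/image: 33 bins of equal width in log10 frequency; within each bin the
fitted point is (mean log10 f, mean log10 P) over its integer frequencies,
and empty bins are dropped.  Frequencies are cycles per image, not cycles
per face width, so the measure is comparable across image content.

Conventions worth making explicit:

* **No tapering.**  Boundary leakage is part of the measured statistic; a
  windowed variant would measure something slightly different.
* **Bin ordinate.**  Averaging log-power within a bin (default) and taking
  the log of the mean power are both defensible readings of "binning in the
  log-log plane"; both are implemented (`SpectralConfig.bin_statistic`), and
  both recover an exact power law exactly.  The default is mean-of-logs,
  with the bin abscissa the mean of member log-frequencies rather than the
  bin center.
* **Amplitude vs power.**  The amplitude-domain fit uses the ordinate
  `0.5·log10 P` and is therefore *exactly* half the power-domain slope
  (halving a float is exact), reproducing the ≈−2 (power) ↔ −1 (amplitude)
  correspondence for natural-scene statistics.
* **Affine invariance.**  `a·I + b` rescales every off-DC power by `a²`,
  a constant shift in log power, so the measured slope is unchanged.
* Log base 10 throughout; the intercept is log10 power at log10 f = 0.

On pure power-law random-phase textures the estimator is accurate to within
about 0.005 slope units (the residual bias comes from annulus rounding);
the acceptance band used in round-trip tests is ±0.05.

## Random-phase synthesis

The Fourier amplitude at radius `f` is set to `f^(s/2)` — half the
exponent, because `s` parameterizes the *power* spectrum and power is
amplitude squared; this is the classic off-by-two pitfall and the reason
the exponent appears halved in both the generator and the slope shifter.
Phases are i.i.d. uniform with Hermitian symmetry enforced by
antisymmetrizing a uniform draw (`θ(−k) = −θ(k)`; self-conjugate bins get
phase 0), so the inverse FFT is real to machine precision and, because the
amplitude at every bin is deterministic, the measured slope is essentially
seed-independent.  DC is zeroed before the final linear rescale to
[0, 255], which sets the mean and, being affine, leaves the slope intact.

Stimulus assembly fixes: mid-grey = 128 (midpoint of the display range);
overlay opacity 0.15 with the blend applied first and the black oval window
second (the surround stays strictly black); the default oval has semi-axes
(0.45·H, 0.35·W), centered — the geometry is configurable since no single
standard exists.  Whether the original overlay stimuli were windowed before
or after blending is not documented anywhere authoritative; the two orders
differ only in a boundary ring, and blend-first was chosen to match the
published stimulus figures.  Background stimuli paste the oval interior of
the face onto a random-phase canvas scaled so the oval covers 1/3 of the
canvas width and 8.4/17.1 ≈ 0.49 of its height (the visual-angle layout of
the background study); masks and backgrounds are generated at the stated
stimulus resolution rather than resized from another raster.

## Slope manipulation

To move an image from measured slope `m` to target `t`, every off-DC
coefficient at radius `f` is multiplied by `f^((t−m)/2)`; a single global
positive factor then restores the original total off-DC power, and DC is
untouched.  Phases are never modified (positive real multipliers), so the
change is purely a redistribution of power across frequencies.  `m` is
measured with the package's own estimator, making the procedure
self-consistent with it; for pure power-law textures a nominal reference
slope can be supplied instead.  Results are returned as unclipped floats:
clipping to [0, 255] on export perturbs the spectrum slightly, so exactness
claims (phase to 1e−6 rad, power to 1e−6 relative) refer to the pre-clip
image, and measured-slope accuracy after export is held to 0.05 units.
Slope ladders generate every rung from the original image, never by
chaining, so clip artifacts cannot compound; a 100-step ladder from −4 to
−1 on a 512² power-law texture tracks its targets to within ~0.002.

## PHOG measures

The image is resampled to ~100,000 pixels (isotropic, aspect preserved to
±1 px).  Gradients are central differences (`[−1, 0, 1]/2`), with the
1-pixel border excluded; orientation is signed over the full 360° circle
and magnitudes are hard-assigned to 16 equal 22.5° bins.  Level `ℓ` of the
pyramid divides the gradient field into `4^ℓ` rectangles (borders at
multiples of `⌊dim/2^ℓ⌋`, remainders joining the last section), so child
histograms partition their parent exactly.

* Self-similarity: mean histogram intersection between each sum-normalized
  section histogram at levels 1–3 and the normalized level-0 histogram,
  averaged over sections then levels; in [0, 1].
* Complexity: total level-0 gradient magnitude divided by the number of
  gradient pixels — per-pixel normalization makes the value independent of
  image size and exactly linear in contrast.
* Anisotropy: population variance of the 16 normalized bin strengths,
  averaged over the 64 level-3 sections (empty sections skipped).

Degenerate inputs are handled by convention: a constant image yields
self-similarity 0 and anisotropy 0 with a warning (and no spectral slope at
all, since there is no off-DC power).  The gradient operator, bin
interpolation and normalization are not standardized across published PHOG
implementations; the absolute values produced here are internally
consistent but not directly comparable to numbers computed with other
low-level choices.  The correlation structure across images — not the
absolute level — is the intended analysis surface.

## Inference

* **Second-level residual regression.**  The image property is residualized
  on chronological face age once (image level); per participant, ratings
  are residualized on age and regressed on the property residuals; the
  per-participant coefficients are tested against zero with a one-sample
  t-test (df = n−1).  By Frisch–Waugh–Lovell this coefficient equals the
  property's partial coefficient in a joint regression on (age, property) —
  the package tests this equivalence at 1e−10.  Gender enters effect-coded
  (female +1, male −1) together with a property×gender interaction when
  requested.  Participants missing more than 40% of stimuli are dropped;
  remaining missing rows are dropped listwise per participant, with
  warnings.
* **Trend analysis.**  One-way within-subject ANOVA on participant ×
  condition means (`F = MS_cond / MS_cond×subj`), Greenhouse–Geisser ε from
  the doubly centered covariance of condition scores applied to both df
  (ε = 1 exactly at k = 2), and a quadratic orthogonal-polynomial contrast
  — weights (2, −1, −2, −1, 2) for five levels — tested per participant
  with a one-sample t (contrast F = t², df (1, n−1)).  Higher-order factor
  interactions are out of scope; stratified one-way runs cover those
  questions.
* **Choice tallies.**  Category percentages are selections over all trials
  (summing to 100 across the three categories); conditional percentages
  within a pairing sum to 100; paired t-tests compare each category's
  per-participant selection rates between its two pairing contexts.
* **Rank tests.**  Friedman on within-participant ranks (χ² = 0 by
  convention when every participant's scores are fully tied), pairwise
  Wilcoxon signed-rank with the tie-corrected normal approximation, and
  sign tests (exact binomial to n = 25, continuity-corrected normal
  beyond).  Post-hoc tests are reported uncorrected by default, matching
  common practice for these designs; a Bonferroni adjustment is a
  one-liner on the returned p-value matrices.

Standard distributional machinery (t, F, binomial, rank statistics) comes
from scipy.stats; the procedures themselves are implemented here.

## Synthetic data

The generator emulates the *structure* of face-rating studies, not their
appearance:

* face-like images are power-law skin textures with nominal slope
  `−3.1 + 0.006·age ± N(0, 0.05)` (ages 19–80 span −2.99 to −2.62), an
  age-linked number of small dark blemishes (≈4 + 0.9/year), fixed dark
  feature ellipses, and the black oval window.  Measured slopes land in a
  −2.9…−2.8 band: the window edge and features compress the nominal range,
  as framing does in real photographs, while preserving the age ordering.
  Blemishes add orientation-balanced high-frequency gradients, which is
  what drives complexity and self-similarity up and anisotropy down with
  age — reproducing the directions of the published age correlations
  without modelling skin.
* table-only cohorts draw the four property values from linear-in-age
  models with observation scatter (slope scatter 0.12 total, giving an
  age-slope sample correlation near .6 at n = 110, the magnitude seen in
  real sets) — convenient for fast inference simulations that never touch
  pixels.
* ratings follow a linear model: intercept 2.5 on the 1–4 scale, an age
  coefficient of −0.015/year (ages span ~0.9 rating units), optional
  centered property coefficients and per-condition offsets, participant
  random intercepts (sd 0.3, a calibration choice — published reports do
  not include variance components), and residual noise (sd 0.3), clamped
  to the scale and rounded to the 1–4 grid for keystroke designs.  The
  overlay design keeps ratings continuous (its original response scale was
  a quasi-continuous slider); condition-profile offsets are expressed in
  the same rating units.  Forced-choice trials compare the latent values
  of two different faces plus category offsets and choice noise.

Passing tests on this material demonstrates that the pipeline recovers
known ground truth under realistic noise and design sizes; it does not
certify absolute PHOG values or rating effect sizes for any real face
database, which depend on photographic conditions the generator does not
model (lighting, hair, optics, demographics).

## Problem sizes and numerical notes

Round-trip and ladder checks run at 512² with 20 seeds per condition;
inference calibration uses 500 null experiments (20 participants × 110
faces) and 100-replicate power/recovery runs — sizes at which Monte-Carlo
error is comfortably below the tested tolerances while the whole suite
stays fast.  All randomness flows through `numpy.random.default_rng`
seeds; every stimulus records its seed in the manifest, and identical
specs + seeds give byte-identical outputs.  Intermediates stay in float64
everywhere; [0, 255] clipping happens only on export.

## Known limitations

* The PHOG absolute scale is implementation-specific (see above).
* The area-100k resize cannot hit 100,000 pixels within 1% for extreme
  aspect ratios (>~10:1), where the small dimension's rounding granularity
  exceeds the tolerance; face photographs are far from this regime.
* The slope estimator's annulus-rounding bias (~0.002–0.005 units) is
  visible only on exact power laws; it is negligible against photographic
  variability.
* Three-factor mixed designs (condition × stimulus age × gender) are not
  decomposed; stratified one-way analyses are the supported route.
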