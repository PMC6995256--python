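# Methods

This note documents the models and procedures implemented in `dynabody`,
the parameters that matter, the design decisions taken where the procedure
was genuinely open, and what the synthetic-data generators do and do not
emulate.

## Motion metric (`dynabody.motion`)

The metric quantifies low-level local visual motion in a clip without any
optical-flow or tracking machinery, which is exactly its point: it captures
the raw pixel churn that could drive early visual cortex, so that it can be
regressed out of the body-vs-object contrast.

1. **Luminance.** RGB frames are reduced by the Rec.601 weighting
   0.299 R + 0.587 G + 0.114 B.  The weighting choice is a convention;
   any fixed positive weighting that sums to 1 would serve, and grayscale
   input passes through unchanged.
2. **Noise surrogate.** The clip's static background (the chroma-key
   border) measures acquisition/compression noise.  For each consecutive
   frame pair we summarize |Δluminance| inside the background mask and
   average over pairs.  The summary statistic is configurable (`pNN`
   percentile, `mean`, `mean+Ksd`, `max`) because no single formula is
   canonical; the default is the per-pair 95th percentile.  For i.i.d.
   Gaussian pixel noise of sd σ, |Δ| is half-normal with scale σ√2, so the
   default statistic estimates σ√2·Φ⁻¹(0.975) ≈ 2.77 σ; the tests verify
   this closed form.
3. **Counting.** For each frame pair, pixels anywhere in the frame with
   |Δluminance| strictly above the scalar threshold are counted; the mean
   count over pairs is the clip's motion value (one scalar per clip), and a
   block's cumulative motion is the sum over its five clips.  Absolute
   differences are used; a signed variant is deliberately not offered.
   Counting covers the whole frame including the border region — with a
   scalar threshold the static border contributes only the statistic's
   tail fraction, and keeping the domain fixed makes values comparable
   across clips.

Per-pixel noise maps are out of scope: the noise surrogate is a single
scalar per clip by design.

Validation statistics: `correlate_ratings` computes the Pearson r between
clip motion and perceived-motion ratings with the two-sided p from the t
distribution on n − 2 df; `compare_block_motion` compares body vs object
cumulative block motion with a pooled-variance Student t (df = n₁ + n₂ − 2)
by default, Welch as an option.  Degrees of freedom are always computed
from the data supplied, never hard-coded.

## Block design (`dynabody.design`)

A run is 48 blocks of 10 s (total 480 s): 18 body blocks split 6/6/6
across angry/happy/neutral, 18 object blocks, 12 blank baselines.  The
emotion split is configurable (`emotion_counts`) since splits other than
the balanced one are conceivable.

Ordering comes from a maximal-length shift-register sequence over GF(3):
`s_n = (c₁s_{n−1} + … + c_k s_{n−k}) mod 3` with primitive feedback taps
(shipped defaults verified exhaustively: every nonzero k-tuple of states
occurs exactly once per period 3ᵏ − 1).  Non-primitive taps are rejected
with the realized period named.  One period (26 for the default k = 3)
cannot match the 18/18/12 composition, so the cyclic sequence is rotated
(seeded), tiled to 48, mapped (0 → baseline, nonzero symbols → body/object,
assignment seeded) and repaired: surplus conditions are edited to deficit
conditions one at a time, each edit placed to minimize the number of
adjacent same-condition pairs with a hard penalty on runs longer than 3,
ties resolved to the earliest index; a final swap pass enforces the run cap
strictly.  This preserves the m-sequence's decorrelation intent while
matching the printed composition exactly.  Onsets are at exact 10-s
spacing with no gaps, since none are specified.

`design_efficiency` reports corr(body, object) of the HRF-convolved
regressors and the contrast efficiency 1/(c′(X′X)⁻¹c).  Across 100 seeds
the |correlation| stays below 0.4 (empirically ≈ 0.39; the body and object
regressors are necessarily anticorrelated because the two conditions
compete for the same run time against a fixed baseline share).

## GLM engine (`dynabody.glm`)

* **HRF**: canonical double-gamma h(t) = g(t; 6, 1) − g(t; 16, 1)/6,
  normalized to peak 1 (peak ≈ 5 s).  No derivative terms are included —
  the localizer contrast does not need them.
* **Condition regressors**: boxcars on a 0.1-s grid convolved with the HRF
  and sampled at t = i·TR, then scaled to peak 1, so planted amplitudes in
  the synthetic generator are in signal units (peak signal change).  The
  0.1-s grid divides both the 10-s onsets and the 2.6-s TR exactly.
* **Motion covariate**: a boxcar whose height in each stimulus block is
  that block's mean-centered cumulative motion, convolved with the HRF
  (default) or entered raw per scan (option), as one column spanning both
  conditions (per-condition modulation is available as a flag).  Centering
  makes the column orthogonal to the intercept; if all block motions are
  equal it becomes identically zero and the fit falls back to the
  pseudo-inverse with a warning rather than failing.
* **Nuisance**: six mean-centered head-motion columns; a DCT drift basis
  with K = ⌊2·T/cutoff⌋ orthonormal components (K = 9 for 246 volumes at
  TR 2.6 s and a 128-s cutoff); one intercept.
* **Smoothing**: separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis
  converted to voxels (3.397 mm for the default 8 mm), truncated at 6σ so
  an interior delta conserves its mass to < 1e-6.
* **Fitting**: per-voxel OLS via the pseudo-inverse; df = n − rank(X);
  residuals orthogonal to the design by construction.  Rank deficiency
  warns and reduces df rather than erroring.
* **Contrast t**: zero-residual voxels get t = 0 when the effect is also
  zero and ±1e6 otherwise (a finite cap keeps maps finite on noise-free
  synthetic data).
* **High-pass filtering** is available both as drift columns in the design
  and as a standalone projection (`highpass_filter`); the two are
  algebraically equivalent.  The standalone filter also removes the mean
  (a constant filters to zero), so it projects out K + 1 dimensions.

The second level is a one-sample t across subject contrast images: with a
single contrast per subject, a random-effects ANOVA degenerates to exactly
this.

## Localization (`dynabody.localize`)

Three threshold levels are used throughout: p < .05 FWE-corrected at the
voxel level, p < .001 and p < .05 uncorrected, each combined with a
10-voxel cluster-extent minimum (6-connectivity by default; 18/26
configurable).  Thresholding is one-sided, matching the directional
body > object contrast.  For FWE the package implements Bonferroni
(default) and permutation max-T over subject sign flips (exact under
exchangeable symmetric errors); random-field-theory correction is
deliberately not implemented, so absolute FWE thresholds are conservative
relative to RFT-based software — on smoothed null data the realized
family-wise rate runs near 3% at nominal 5%.  The nesting
fwe_05 ⊆ unc_001 ⊆ unc_05 holds for every map.

ROI extraction searches 10-mm spheres (mm distance via the map affine)
around canonical seed coordinates of the dynamic body network; the peak is
the maximum-t surviving voxel, ties broken by first C-order index.  The
cluster-extent filter runs on the whole map before the sphere restriction,
so clusters straddling the sphere keep their full extent; per-subject
"presence" requires surviving both height and extent.  An empty sphere is
reported absent, not an error.  Group tables tally per-ROI presence
counts, mean voxel counts and mean/SD peak coordinates across subjects,
and `compare_to_reference` gives Euclidean distances to a reference
coordinate table (a literature-average table ships with the package).

## Synthetic data (`dynabody.synthetic`)

**Clips.** A rigid dark object (square, or a thinner bar) translates
1 px/frame across a uniform chroma-key green background; a square of edge
s changes exactly 2s pixels per step, which makes the planted
moving-pixel count analytic (and restricts it to even values).  Achromatic
Gaussian noise (the same draw on all three channels) is added after
rendering, so luminance noise has exactly the specified sd.  The generator
records the *realized* noise level — the largest background |Δluminance|
actually drawn — so thresholding at it recovers exactly the planted count;
generation fails loudly if the noise is so large that the planted count
would be ambiguous.  Defaults mirror the real stimuli (960 × 540 px, 50
frames at 25 fps, background RGB 159, 202, 145); tests use smaller rasters
with the same structure.  Not emulated: human figures, articulated motion,
facial masking, codec artifacts — so passing tests demonstrate the metric's
counting behaviour, not its adequacy for real video content.

**Stimulus sets** follow the real set's structure: 15 actors × 3 emotions
= 45 clips, with optional sex labels (6 male / 9 female in the validation
set) and per-clip planted motion varied deterministically over 0.5–1.5× the
template count so that rating correlations and block comparisons have
variance to work with.

**Ratings** are built by exact construction: standardized motions x̂ mixed
with an orthogonalized unit noise vector ẑ as r·x̂ + √(1−r²)·ẑ, giving a
sample Pearson correlation equal to the target to float precision
(comfortably inside the ±0.02 contract); the reported validation value
(r = .571, n = 61) is reproduced this way on synthetic ratings.  The n is
treated as the number of correlated pairs.

**BOLD.** Default acquisition geometry is 246 volumes at TR 2.6 s, 3-mm
isotropic voxels, with the affine mapping the grid center to MNI (0,0,0).
The 480-s schedule ends before the 639.6-s acquisition; the tail is plain
baseline.  Signal = baseline (100) + Σ sites amplitude × unit-peak
condition regressor within a 4-mm radius of the site + drift (linear +
slow cosine, random per-voxel weights) + head-motion components (six
smoothed, standardized random walks times random per-voxel weights) +
white Gaussian noise.  Because generator and design matrix share the same
regressor code path, noise-free recovery of planted amplitudes is exact to
float precision — this validates the algebra, and deliberately not the
HRF's correctness for real hemodynamics.  Head motion is added as a signal
component, not as an actual rigid-body resampling of the volume; it
exercises nuisance regression only.  The ground-truth record carries
planted voxel indices, amplitudes and the confound traces.

The default desk-scale grid is 20 × 24 × 20 voxels; the end-to-end demo
uses 46 × 54 × 38 so that all seven canonical seed coordinates (|x| up to
63, |y| up to 79, z up to 46 mm) fall inside the volume.

## Problem sizes and numerical choices

The test-suite and acceptance-script problem sizes are chosen as the
smallest that exercise each property cleanly: 50 clips at 120 × 90 px for
the metric oracle (exact equality, not a tolerance), 1000 voxels for the
GLM oracle (agreement to 1e-10), 200/500 Monte-Carlo null runs on a 12³
grid for threshold calibration (uncorrected rate 5% ± 1%; Bonferroni
family-wise rate ≤ 5%, run through the same smoothing as real analyses,
under which Bonferroni is conservative), and a 3-subject cohort at
amplitude 5× noise sd for end-to-end recovery (all 7 ROIs at p < .001 in
every subject, peaks within 2 voxels of the plants).  All randomness flows
through seeded `numpy` generators; identical configs and seeds reproduce
outputs bit for bit (the pipeline's report JSON is byte-identical across
reruns, with timing logs kept out of it).

## Known limitations

* No realignment, coregistration, segmentation or nonlinear normalization:
  the pipeline consumes already-registered volumes.
* No AR(1) prewhitening or slice-timing correction; df assumes white
  residuals.
* FWE is Bonferroni/permutation, not random-field theory; absolute
  thresholds differ from SPM-style outputs.
* The motion metric is a pixel-churn count, not a perceptual motion model;
  its validation against perceived motion lives in the rating correlation,
  which on synthetic data is reproduced by construction.
* Atlas-based anatomical labeling is out of scope; ROI names come from the
  seed table.
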