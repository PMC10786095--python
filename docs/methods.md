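# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `bmrsa`.

## Stimulus model

The walker is a 15-joint skeleton (head, sternum, pelvis, and left/right
shoulder, elbow, wrist, hip, knee, ankle) in 3D body coordinates with a
1-s gait cycle: sinusoidal limb swing at the gait frequency (right limbs
at phase φ, left at φ+π), torso bounce at 2φ, and lateral sway.  Gender
and emotion are additive displacement fields per morph-SD unit — broader
shoulders / narrower hips / more upper-body sway toward "male";  more
bounce, higher head, forward lean and larger arm swing toward "happy" —
applied before projection, so morphing is exactly linear.  The stimuli
use ±6 SD, matching the morph magnitude of the emulated study, but the
axes themselves are stylized inventions: nothing is claimed about
fidelity to any motion-capture morph space, only that the 2×2×2
attribute structure the analysis needs is present and controllable.

Facing is a true 3D azimuth rotation with orthographic projection.
"Right" is rendered at azimuth −45° and "left" at +135°; because
cos 135° = −cos(−45°) and sin 135° = −sin(−45°), the two projections are
exact mirror images frame by frame while both remain genuine rotated
views (an orthographic camera cannot distinguish a −45° view from the
mirrored 135° view).  Frames are rendered as truncated Gaussian dots
(σ = dot radius, cut at 4σ) on a black canvas whose aspect matches the
6.9° × 3.9° stimulus window; rendering refuses dots within 4σ of the
canvas edge rather than clipping silently.

## V1 model

S1 applies zero-mean, unit-norm Gabor filters (4 orientations; 4 scale
bands of two sizes each, 7–21 px, the standard C1 parameter table with
aspect ratio 0.3) as rectified normalized cross-correlations, so
responses lie in [0, 1] and are invariant to global intensity scaling;
the half-filter border, where the aperture is truncated by padding, is
zeroed.  C1 takes the max over the two scales within a band and then a
local spatial max on a half-overlapping grid (pool sizes 8–14).  A
stimulus feature is the arithmetic mean of per-frame C1 vectors (units
treated as instantaneous; no motion-energy channel).  The emulated study
names only "C1 units", so the exact constants are this package's
conventional choices and are exposed on `GaborBank`.  On the synthetic
stimuli the V1 RDM correlates most strongly with the gender model
(r ≈ 0.8 at the default morph settings), which mirrors the qualitative
pattern reported for the original stimuli; the exact values are
properties of our invented walkers and are not comparable numbers.

## Synthetic BOLD and behavioral data

One run is a leading 6-s fixation followed by 24 twelve-second stimulus
blocks (each stimulus exactly three times, seeded random order), each
followed by a 6-s fixation: 438 s = 219 volumes at TR 2 s.  This
leading-fixation convention is one of the two arrangements consistent
with the stated totals; the choice does not affect any analysis
quantity.

Planted truth: each attribute owns a cubic ROI (disjoint by
construction, clamped inside the gray-matter-analog mask, which is a
smooth radial tissue-probability field thresholded at 0.2).  The evoked
amplitude of stimulus *s* at voxel *v* is

    amp(v, s) = Σ_attr [v ∈ ROI_attr] · e_attr · w_attr(v) · sign_s(attr)
              + Σ_(a,b) [v ∈ ROI_a ∪ ROI_b] · c_ab · w_ab(v) · sign_s(a)·sign_s(b)

with per-voxel gains w ~ N(1, pattern_sd).  The gain field matters:
Pearson-based RDMs center patterns across voxels, so a spatially uniform
effect is invisible inside an ROI; voxel-wise heterogeneity is what makes
a planted effect pattern-decodable, and pattern_sd defaults to 1.  The
interaction term is product-coded (the attribute contrast differs by the
partner attribute's category) with its own gain map.  Coupling strength
1× the main effect is used as the "strong coupling" condition: the
coupled ROI's RDM then mixes the attribute RDM and the gender×emotion
(XOR) RDM with equal weight.  Substantially stronger coupling is
self-defeating — the XOR RDM regresses on the three theoretical RDMs
with coefficient −1/4 each, so at 2× coupling the standard partial beta
of the target cancels entirely.

The series is baseline (default 100, so effect 1 = 1% signal) plus
evoked amplitudes convolved with a double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6, unit peak), plus stationary AR(1) Gaussian
noise (marginal SD `noise_sd`, ar1 = 0.3), a random linear-plus-cosine
drift, and a small component coupled to six smoothed-random-walk motion
regressors.  `calibrate_noise_sd` computes, from the design matrix
alone, the per-volume noise SD at which the planted amplitude SD across
ROI voxels equals a target fraction (default 0.5) of the pooled
condition-beta standard error — i.e. a t-pattern SNR of 0.5, the regime
the recovery analyses run in.  No prewhitening is applied in the GLM;
under AR(1) noise OLS underestimates the SEs of low-frequency block
regressors, inflating the null |t| > 2 tail from ≈ 0.05 to ≈ 0.11, which
is verified by a test and absorbed by working at the group level.

Ratings: `round(4 + slope·sign + N(0, criterion_sd))` clamped to 1–7,
four repetitions per stimulus per attribute (96 trials).  Defaults
slope 1.5, criterion SD 1.0 emulate reliable but non-ceiling raters.

What the generator does **not** emulate: anatomy and inter-subject
spatial variability, physiological noise, actual head motion (only
nuisance-correlated signal), scanner drifts beyond two smooth terms, and
any nonlinear HRF effects.  Passing tests therefore demonstrate the
correctness and calibration of the analysis chain on data satisfying its
assumptions, not robustness to real-data violations of them.

## Analysis choices

- **Searchlights**: the 200 nearest mask voxels by Euclidean grid
  distance; distance ties (common on an integer grid) break by ascending
  linear voxel index, making neighborhoods fully deterministic; a
  brute-force k-NN oracle pins this down in tests.
- **RDM regression**: all 28-pair vectors z-scored; standardized OLS
  betas; the Fisher transform (atanh clipped to ±0.999) is applied to
  betas — the analysis this package emulates reports "correlation
  values" from a multiple regression without defining them further, and
  standardized betas are the CoSMoMVPA-style reading.  Semi-partial
  correlations were considered and not implemented; the scrambling and
  group stages are agnostic to this choice.
- **Group inference**: voxel-wise one-sample t (one-sided positive — the
  hypotheses are positive encoding; two-sided by flag); zero
  between-subject variance yields t = ±100 (capped) rather than ±∞.
- **Cluster correction**: supra-threshold clusters at voxel p = 0.001
  (26-connectivity default) scored against the sign-flip null of the
  maximum cluster *size*; p = (1 + #{null ≥ size})/(1 + n_iter).
  Cluster mass is a possible variant, not implemented.  The sign-flip
  family is this package's realization of the unnamed "cluster-based
  Monte Carlo" correction in the emulated analysis.
- **Scrambling**: joint row/column label permutation by default
  (preserves RDM structure); entry-level shuffling of the 28-vector is
  available for sensitivity analysis.  "z-score" is realized as the
  Fisher transform of each permutation's coefficient map, consistent
  with the main RSA; per-map spatial z-scoring is available by flag.  A
  scrambled binary RDM occasionally duplicates another predictor
  (probability ≈ 3% per draw for a balanced dichotomy); the minimum-norm
  least-squares solution is used, which splits the coefficient across
  exact duplicates — part of the scrambling noise that the 100–1,000
  permutation average integrates over.
- **MVPA**: LIBSVM linear SVM at C = 1; demeaning is per-pattern across
  searchlight voxels (amplitude removal), not per-voxel across samples.
  FDR families are per attribute network (all clusters × tests).
- **Behavioral RDMs**: the per-stimulus judgment on one attribute is a
  scalar, so the Euclidean distance of mean ratings reduces to the
  absolute difference of means; treating repetitions as paired 4-vectors
  has no pairing justification and is not used.  The behavior–neural
  link is a plain Pearson correlation of RDM vectors (Spearman by flag),
  not a regression with theoretical covariates.

## Problem sizes and calibration results

Desk-scale runs use a 20³ voxel grid (≈ 6,300 mask voxels) with 7³ ROI
cubes, 20 subjects, 100 scrambling permutations and 500 Monte Carlo
iterations (the test profile; 1,000/5,000 at the full profile), and a
12³ grid with 3³ ROIs at t-pattern SNR 2 for the decoding analyses.

The ROI linear size is deliberately at least the searchlight diameter.
A center-assigned searchlight statistic genuinely carries planted
information wherever its neighborhood intersects the ROI, so the
significant map approximates the ROI dilated by up to the searchlight
radius (≈ 3.7 voxels at k = 200).  Recovery is therefore reported twice:
Dice against the bare ROI (0.44–0.66 at SNR 0.5, n = 20 — bounded above
by the dilation geometry) and Dice against the searchlight-informed
support (0.61–0.86), which is the appropriate ground truth for a
searchlight map's spatial resolution.  Null calibration at these sizes:
cluster-level FWE 0.03–0.035 over 200 null repetitions at nominal 0.05;
label-permuted decoding 0.49–0.51; behavioral-link familywise false
positives 0.05–0.07 at FDR q = 0.05.

## Known limitations

- Single analysis path per stage: no rank-correlation RSA, no
  cross-validated RDM distances, no whitening of t-patterns, no TFCE.
- The hierarchy (DC) contrast between independent and coupled planting
  is a single-dial manipulation; real inter-attribute dependence is
  richer than a product-coded amplitude coupling.
- The walker morph axes are invented; V1-RDM correlation values are not
  comparable to any reported stimulus set.
- OLS without prewhitening intentionally mirrors the emulated pipeline;
  voxel-level single-subject p-values are anticonservative under AR(1)
  and should not be interpreted in isolation.
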