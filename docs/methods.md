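# Methods

This note documents the models, defaults and numerical choices behind
`ocapdt`, and what the synthetic-data experiments do and do not show.

## Signal model of the phantom generator

An OCT acquisition with a densely oversampled slow axis is emulated on a
`(depth, fast, slow)` grid (desk-scale default 64 × 256 × 256, voxel
23.4 × 9.4 × 9.4 µm; the instrument-scale 256 × 1024 × 1024 over a
2.4 × 2.4 mm field stays configurable):

- **Static tissue** is circular complex Gaussian speckle, low-pass filtered
  along the slow axis with a Gaussian kernel whose FWHM equals the
  `oversampling_factor` (default 8 positions per beam width, matching
  ~1024 positions over 2.4 mm with a ~20 µm beam). Adjacent slow positions
  of static tissue are therefore strongly correlated (unit-lag correlation
  > 0.98), which is the structure the high-pass filter rejects.
- **Perfused vessels** are piecewise-linear constant-radius tubes
  (default: one 0.05 mm-radius tube). Vessel voxels keep the tissue
  magnitude but receive an independent phase perturbation per voxel and
  slow position with SD `flow_decorrelation` (default 2 rad, i.e. nearly
  complete decorrelation, E[e^{iθ}] = e^{-2} ≈ 0.14). Setting it to 0
  makes vessels statistically identical to tissue (the no-flow null).
- **Bulk motion** is a global per-slow-position phase random walk with
  step SD `bulk_motion_amplitude` (default 0; tests use 1 rad). It
  multiplies entire frames — signal and noise alike — as a rigid tissue
  shift would.
- **Detection noise** is additive complex Gaussian at
  `speckle_snr` = 50 (signal-to-noise ~17 dB, a mid-range value for
  in-vivo OCT at moderate depth).

Beam propagation, attenuation, refraction and non-Gaussian speckle are out
of scope; the phantom is a *statistical* stand-in whose purpose is a known
ground truth for the filtering, detection and quantification chain. A
separate attenuation phantom (disc of distinct exponential depth-decay
rate, multiplicative speckle) serves the reflectivity-profile classifier.

## Angiographic reconstruction

Bulk motion is estimated Kasai-style: per adjacent slow-position pair, the
angle of the conjugate product summed over a depth window (default: full
depth) and the fast axis, cumulatively integrated and removed. On the
default phantom with 1 rad motion steps the estimate matches the injected
phases to < 0.05 rad RMS and the reconstruction agrees with the
motion-free reconstruction to < 5 % relative RMS.

The flow filter is an 11-tap equiripple (Parks–McClellan) high-pass along
the slow axis, passband edge at 0.25 of the slow-axis Nyquist, stopband
edge at half that. After the design the coefficients are shifted to sum
exactly to zero, so a slow-axis-constant volume maps to numerically zero
output instead of the stopband-ripple level. Edges are handled by
reflection, preserving volume shape. Both tap count and cutoff are
configurable; 0.25 Nyquist cleanly separates the static spectrum
(concentrated below ~1/oversampling_factor of the sampling rate) from the
white flow spectrum for any oversampling ≥ 2. The filter order, cutoff and
per-frame (rather than per-A-scan) motion estimation are this package's
choices; only the approach — interframe phase compensation followed by
high-pass FIR filtering in complex signal space — is fixed.

## Tumour segmentation

Each voxel is represented by the coefficients of its local depth
reflectivity profile (window `profile_length` = 32, reflected at depth
boundaries) projected onto two orthonormal bases, the leading principal
directions (`n_components_per_basis` = 4) of normal-tissue and of
tumour profiles respectively. Profiles are log-scaled (configurable),
mean-centred and L2-normalised before both basis construction and
projection, which makes features invariant to a global intensity scale and
to per-column illumination. The bases are computed by SVD of the
normalised profile matrix *without* sample-mean removal, so a degenerate
set of collinear profiles yields exactly its common direction; requesting
more components than the set's rank is an error naming the class.

A random forest (default 100 trees, seeded) classifies the concatenated
coefficients; training reports held-out accuracy on a stratified 25 %
split before refitting on all data. Depth-resolved labels are collapsed by
majority vote over depth; the 2D mask is closed (disk radius 2 px),
reduced to its largest connected component (ignoring specks below
8 px, so isolated false-positive columns cannot masquerade as a tumour)
and hole-filled. On attenuation phantoms the Dice overlap with the true
disc exceeds 0.90 across seeds. Expert mask files can bypass segmentation
entirely.

## Vessel quantification

The en-face image is the maximum intensity projection over the analysed
depth range. The background noise scale σ is estimated on the raw
projection as 1.4826 × the median absolute deviation (about the image
median) of the sub-median pixels — in sparse-vessel angiograms the lower
half of the intensity distribution is background, and on a flat Gaussian
field the estimator is consistent for σ.

A maximum projection also shifts the background to a positive pedestal
several σ above zero (max-of-N statistics), so the threshold is referenced
to the background level: the image median is subtracted (clipped at 0)
before denoising, and the binarisation keeps pixels above
`noise_sd_multiplier` × σ (default 3). Total-variation (ROF/Chambolle)
denoising precedes thresholding with weight expressed in units of σ
(default 5 σ): strong enough to flatten within-vessel speckle of the
projection, and making the whole chain exactly invariant to a global
intensity scale (an absolute TV weight would not be). Binary masks are
thinned with Lee's topology-preserving algorithm; PVD is
100 × skeleton pixels / region pixels, per region.

The peri-tumour region is the 0–2 mm annulus outside the tumour border
(morphological dilation by `margin_mm`/pixel radius minus the tumour,
clipped to the field of view); the bound resolves the source text's
ambiguity between "starting from 2 mm" and "up to ~2 mm" in favour of the
annulus adjacent to the border, which is the region the decision rule
evaluates. On phantoms with 1–10 vessels the measured PVD tracks the
ground-truth skeleton density with Pearson r > 0.99.

**Known limitation.** Raising the binarisation multiplier shrinks the
binary mask monotonically (strict set inclusion), but thinning is not
monotone under set inclusion: on speckled projections the skeleton length
jitters by roughly ±2 % as the mask narrows, because the centerline of a
narrower mask can be slightly longer (more tortuous). PVD is therefore
monotone in the multiplier only up to that jitter; the exact monotonicity
test uses images whose vessels are one pixel wide (skeleton = mask), where
the dominant mechanism — dimmer vessels dropping out as the threshold
rises — is isolated.

## Synthetic cohorts

A cohort is 31 animals by default: 18 responders (histology necrosis
> 95 % at day 7) and 13 non-responders, with PVD (%) per region
(tumour / peri-tumour) and time point (pre, 0 h, 5 h, 24 h). The
structural constraints are:

- responders have zero tumour PVD at 24 h; exactly 8 of 13 non-responders
  do as well (the remaining 5 draw positive values, floored at 0.05 %);
- peri-tumour 24 h values separate completely: the responder maximum is
  set to 0.8 % and the non-responder minimum to 1.2 %, so the midpoint
  threshold search returns exactly 1.0 % at every seed;
- all PVD values are non-negative.

Group statistics are target sample moments of the **emitted** values.
Peri-tumour pre and 24 h cells use the published values (3.14 ± 0.57 →
0.38 ± 0.22 % responders; 3.29 ± 0.59 → 2.21 ± 0.86 % non-responders);
0 h and 5 h interpolate linearly between them, since only the endpoints
are printed. Tumour-region group statistics are unpublished at all time
points; the defaults (pre 4.5 ± 1.0 %, decaying monotonically to the 24 h
state) are declared choices, exposed in `CohortSpec`, and no test depends
on them.

Because values are truncated at zero and the 24 h peri-tumour cells are
clamped to the separation extremes, drawing directly from N(mean, SD)
would bias the emitted moments (for the non-responder cell the clamp at
1.2 % alone adds ≈ +0.05 % to the mean, i.e. ≈ 4 standard errors over 200
cohorts). Each cell therefore draws from a latent normal whose parameters
are solved (moment-matching the analytically known clipped-normal mean and
SD, via `scipy.optimize.root`) so that the clamped population moments
equal the targets. The residual effect of forcing the two extreme order
statistics is O(0.002 %) and well inside Monte-Carlo noise at 200 cohorts.
Infeasible targets (e.g. an SD unreachable on the clamped interval) raise
a descriptive error. Determinism: one master seed; per-animal generators
derived by fixed `SeedSequence` arithmetic, so any record is reproducible
individually.

## Outcome prediction

Candidate thresholds are the midpoints between consecutive sorted unique
PVD values plus a below-minimum and an above-maximum boundary — no other
real threshold can change any decision, so the search is equivalent to an
exhaustive scan (property-tested against a brute-force oracle). The
decision direction is `PVD ≤ threshold ⇒ responder` (low perfusion after a
vasculature-targeted treatment indicates response); ties break toward the
smallest threshold, favouring sensitivity to residual perfusion.
Thresholds are derived on the full cohort, as appropriate for n = 31; no
train/validation split is performed.

Wilson score intervals use z = 1.959964 (two-sided 95 %, configurable);
reported bounds round to integer percent while exact proportions are kept.
The k = 0 and k = n endpoints are set to exactly 0 and 1 (they are
analytically exact and float rounding would otherwise drift by one ulp).
Published counts with internally consistent intervals reproduce exactly
(31/31 → 89–100 %, 27/31 → 71–95 %); several published interval entries
(e.g. 48–75 for 21/31, and two different intervals for the same 23/31
count) do not match the Wilson formula for any k/31 and are treated as
typographical, not as targets.

The combined rule (`tumour_epsilon` = 0: any perfused tumour vessel means
failure; otherwise peri-tumour PVD ≤ 1 %) classifies every animal of every
generated default cohort correctly — by construction of the complete
separation, so this validates the machinery, not the biology. The
tumour-only rule at 24 h yields 23/31 on the default cohort (8
non-responders share the responders' zero tumour PVD), reproducing the
published count.

## What the synthetic experiments do not show

The cohort generator encodes the published group statistics and the
observed complete separation; recovering the 1 % threshold and the 31/31
CPO from it demonstrates correctness of the estimator chain, not
generalisation to new animals. Real OCA images carry vessel shadowing,
depth-dependent signal loss, motion beyond a global phase, and tumour
borders far less regular than a disc; the phantom tests bound none of
those effects. Pre-treatment and intermediate-time-point tumour
statistics in the generator are invented defaults and should be
re-parameterised from data before being used to study anything but the
24 h decision rule.

## Problem sizes

Defaults are chosen so the full test suite runs in a few minutes on one
CPU: desk-scale phantoms (64 × 256 × 256), 200-cohort Monte-Carlo runs
(each cohort is 31 × 8 draws), and 300-profile training sets for the
segmentation forest. All sizes scale up through the same configuration
objects.
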