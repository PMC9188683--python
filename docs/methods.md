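# Methods

`ceusrad` implements a motion-robust, interpretable radiomics pipeline for
characterizing focal liver lesions (FLLs) on contrast-enhanced ultrasound
(CEUS).  This note records the model, the parameters that matter, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## Problem setting

A liver CEUS examination records ~60 s of a dual-view cine loop: B-mode
anatomy in one pane and the contrast-specific (microbubble) signal in the
other, covering the bolus wash-in, peak enhancement and the beginning of
wash-out.  The arterial phase (~10–45 s post-injection) overlaps the
portal-venous phase (from ~30–45 s), and probe/respiratory motion —
including out-of-plane excursions that 2-D imaging cannot compensate —
corrupts many frames.  The pipeline therefore avoids TIC model fitting and
motion compensation entirely, and instead extracts features designed to be
robust to both problems, feeding them to classifiers that separate benign
from malignant lesions.

## Processing chain

### Linearization

Scanner gray levels are log-compressed.  With dynamic range `DR` (dB) and
gray maximum `G` (255 for 8-bit), relative echo power is recovered as

    power(g) = 10^(DR · (g/G − 1) / 10)

so `power(G) = 1`.  The divisor 10 (echo-power convention, not amplitude)
is a package default; all downstream TIC quantities are in relative power.
The inverse (`log_compress`) restores gray levels to within rounding, which
the simulator uses as its forward model.

### ROI and frame selection

The analysis ROI is a square centered on the center of mass of the union of
the 1–3 manual lesion masks, with side
`clip(ceil(margin_factor · max bbox side), min_side, max_side)` —
defaults 2.0 / 200 px / 278 px.  The 200–278 px bracket reflects the ROI
sizes observed on clinical acquisitions; the margin rule itself is explicit
and configurable.  Boxes that would leave the frame are shifted (and only if
unavoidable clipped) with a logged warning.

Motion filtering: each B-mode frame's ROI crop is correlated (Pearson) with
the reference-frame crop; frames with r ≤ 0.8 are invalid.  The crop (not
the full pane) is used so that motion is assessed where it matters — this
is a documented choice, configurable.

Fiducial frames are found on the 5-s moving-average of the lesion-mean TIC.
Invalid frames carry motion-corrupted contrast values as well, so the mean
TIC is first bridged across them by linear interpolation between valid
neighbors; all subsequent rules are restricted to valid frames, and all
thresholds are relative to the valid-frame peak, so the selection is
invariant to affine TIC rescaling:

1. *appearance* = first valid frame at ≥ 10% of the maximum (no sub-frame
   interpolation; frame granularity);
2. straight lines are least-squares fitted to the rising limb between 5%
   and 50% of peak and to the second half of [appearance, end]; their
   intersection gives the initial peak guess (parallel or out-of-range
   intersections fall back to the TIC argmax, logged);
3. *peak* = argmax over valid frames within −20/+50 samples of the guess
   (ties → earliest);
4. *wash-in* / *wash-out* = the valid frame with the highest B-mode
   correlation to the reference within [appearance+5, peak−5] /
   [peak+10, end).

"Samples" are frame indices throughout; windows are clipped to the
recording.  An empty search window raises a stage-named error and the
lesion enters the exclusion manifest.  Note a feasibility constraint at
1 fps: the +5/−5 offsets require the appearance-to-peak interval to span
more than 10 frames, which constrains how fast a lesion's wash-in can be
before it becomes unanalyzable at this frame rate.

### Perfusion maps (5)

Per ROI pixel, after 5-s moving-average smoothing (centered, odd length,
shrinking at the edges): PeakIntensity (max), PeakTime (time of first max),
AppearanceTime (first sample ≥ 10% of peak), WashInTime (PT − AT),
WashInRate (PI / WashInTime).  Two conventions for the wash-in-rate
denominator coexist in the CEUS literature (time from appearance vs. from
recording start); `rate_denominator` selects between them, defaulting to
PI/(PT−AT).  All-zero TICs yield missing (NaN) parameters; a zero wash-in
time flags the rate as missing instead of dividing by zero.  Pixel TICs
are taken at fixed coordinates (no tracking), consistent with the
no-motion-compensation design.

### Similarity maps (3)

Each pixel TIC is compared with the TICs in an annular ring kernel of
inner radius 1 mm and outer radius 2.5 mm (bracketing the ~1.25 mm
avascular tumor size limit of the angiogenic switch).  Before comparison,
frames are speckle-regularized by a Perona–Malik-type edge-preserving
diffusion (10 iterations, conductance = 10% of the intensity range,
explicit step 0.15; flux-conservative, so total intensity is preserved),
and all TICs are windowed to 20 s from the lesion-level appearance time —
a common window for all pixels, keeping the measures arterial-phase-only.

Three measures are averaged over the ring (arithmetic mean, chosen for
variance reduction):

* **Correlation** — Pearson r;
* **Coherence** — Welch magnitude-squared coherence: Hann-tapered,
  mean-detrended segments of length `window/2` at 50% overlap, band-averaged
  over all non-DC bins below Nyquist (cutoff configurable); bins where an
  auto-spectrum vanishes are excluded from the average.  The estimator is
  verified against `scipy.signal.coherence` at matching parameters.
* **MutualInformation** — plug-in MI (nats) on equal-frequency (rank)
  binnings with ⌈√n⌉ bins per variable.  The estimator is positively biased
  at ~20 samples; that is acceptable because values are only compared
  across pixels computed with the same n.

Pixels with fewer than 50% of their ring partners inside the ROI, or
zero-variance TICs, are flagged missing.

### Texture maps (129)

A 21×21 window slides with stride 3 over the ROI of the wash-in, peak and
wash-out frames (prefixes `WiIm`/`PkIm`/`WoIm`).  Each window is first
quantized to 64 gray levels over its **own** min–max range
(`q = min(floor(L·(x−min)/(max−min)) + 1, L)`, constant windows → all 1),
which makes all matrix-based features invariant to affine intensity
rescaling.  43 features per window:

* Global (3): variance, moment skewness, non-excess kurtosis (normal = 3);
  constant windows → (0, 0, 0) by convention.
* GLCM (9): symmetric co-occurrence at distance 1, counts pooled over the
  four in-plane directions before normalization; statistics use 1-based
  level indices; entropy in bits; Correlation of a zero-variance matrix
  is 0.
* GLRLM (13): run-length counts pooled over the same four directions; run
  percentage is runs/(pixels·directions) so it lies in (0, 1].
* GLSZM (13): zones are 8-connected constant-level components; zone
  percentage is zones/pixels.
* NGTDM (5): Amadasun-style, 8-neighbor means over interior pixels, with a
  guard ε = 1e−6 in the Coarseness and Strength denominators (a constant
  window yields Coarseness 1/ε).

The 2-D directional/connectivity conventions are the standard 2-D
radiomics adaptation of 3-D toolbox definitions; the exact statistic
definitions are pinned by brute-force enumeration oracles in the test
suite, which every family must match on exhaustive small windows.  Texture
is computed on linearized intensities (pipeline order: linearize first);
stride-3 grids are nearest-neighbor upsampled to the pixel grid so all 137
maps share one support.

### Feature table (411) and filtering

Each of the 137 maps is condensed to median, IQR (linear-interpolation
quantiles) and moment skewness over non-missing ROI pixels (≥ 8 required,
else the feature is missing and later median-imputed).  Column naming:
`<MapName>_<median|iqr|skew>`; sets: spatiotemporal (24), WiIm/PkIm/WoIm
(129 each).

Filtering: (1) pairs with |r| > 0.9 visited in descending |r|, dropping the
member with the weaker point-biserial label correlation (ties drop the
later column); (2) per feature set, the number N of principal components
explaining 95% of the standardized set variance determines how many
features to keep, chosen by mutual information with the label
(nearest-neighbor continuous–discrete estimator, fixed seed — avoids
arbitrary binning on small cohorts).  The published workflow applies this
filtering once on the full table before cross-validation ("paper mode",
the default, with a logged leakage caveat); leak-free mode defers
filtering/imputation into training folds.

### Machine-learning bench

Repeated nested stratified 4-fold CV (5 repeats → 20 evaluations).
Training folds only are rebalanced: SMOTE (k = 5 neighbors, hand-rolled
k-NN interpolation) raises the benign minority to 0.5 of the malignant
count, then the malignant class is randomly undersampled to 0.7 of its
original size.  Test folds are never resampled (asserted at run time).

Models and grids (each grid contains the optimum reported for clinical
liver cohorts): LR C ∈ {0.1, 0.5, 1, 5, 10}; SVM kernel ∈ {rbf, linear},
C ∈ {1, 10, 50, 100}, γ ∈ {1e−4, 1e−3, 1e−2}, probabilities by sigmoid
(Platt) calibration on held-out thirds; RF min-leaf ∈ {1, 2, 5},
max-features ∈ {0.2, 0.5, √}; kNN k ∈ {3, 5, 7, 9}.  All models sit behind
a standardization pipeline.  Hyperparameters are grid-searched per fold
(inner 4-fold, bACC), the most frequent winners fixed, and the protocol
re-run for the reported metrics (ACC, bACC, SENS, SPEC, AUC; malignant =
positive).  Backward sequential feature selection (cross-validated bACC
scoring) optionally reduces features per model inside each training fold;
a soft-voting ensemble averages the base models' probabilities with ties
going to malignant, and an all-malignant naive baseline anchors the
imbalance (bACC 0.5 by construction).

Permutation feature importance is the mean bACC drop over 10 shuffles per
feature on the test fold, averaged over folds and normalized to max 1 per
model, reported with per-feature selection frequencies.

Model comparison uses the resampled t-test on the 20 per-fold bACC
differences with the Nadeau–Bengio variance correction:

    t = p̄ / sqrt(s² · (1/n + n₂/n₁)),   df = n − 1

with s² the sample variance of the differences, n₁/n₂ the train/test fold
sizes.  `correction_ratio = 0` recovers the uncorrected paired t-test
exactly (asserted against `scipy.stats.ttest_rel`).  Constant nonzero
differences (zero variance) are flagged degenerate (t = ±∞).

## Synthetic cine generator

The simulator provides ground-truthed inputs for every stage:

* **Kinetics** — per-pixel TIC = log-normal bolus (rescaled so its peak
  equals the amplitude; mode at `onset + exp(μ − σ²)`) plus a delayed
  logistic plateau emulating portal-phase inflow; zero before onset.
  Defaults (1 fps, 60 frames): parenchyma onset 14 s, amplitude 0.30,
  log-normal median 24 s, σ 0.5; lesion onset 12 s, amplitude 0.55,
  median 22 s; plateau 0.15 from ~40 s.  These place the parenchyma peak
  near 30 s and keep the appearance-to-peak interval above 12 frames —
  the minimum the fiducial window offsets require at 1 fps.
* **Speckle** — multiplicative unit-mean gamma field (shape 4), spatially
  low-pass filtered to a 1.5 px correlation length; an amplitude-statistics
  stand-in for fully developed speckle, not an acoustic simulation.
* **Motion** — per-frame integer rigid shifts (edge-replicated) applied
  jointly to both panes; out-of-plane events replace a frame's texture
  with an independent speckle draw, which drives its B-mode correlation
  with the reference far below the 0.8 validity threshold.
* **Phenotypes** — malignant lesions get earlier onset (~7 s), higher
  amplitude (~0.85) and per-pixel jitter of the kinetic parameters
  (spatially heterogeneous enhancement); benign lesions later onset
  (~13 s), lower amplitude, homogeneous kinetics.  This is a simulator
  convention that makes the two classes separable for end-to-end tests —
  it encodes the *direction* of known contrast differences, not their
  clinical effect size.

What passing tests therefore show: the pipeline recovers known kinetic
parameters, filters known motion, orders known heterogeneity, and the CV
protocol is unbiased (permuted labels → chance).  What they do not show:
clinical performance — real CEUS has nonlinear bubble response, attenuation
and depth dependence, non-rigid motion, vendor-specific compression, and
far subtler class differences than the simulator's phenotypes.

## Numerical conventions and degenerate inputs

* Constant windows/TICs: global moments 0; GLCM Energy 1; correlation of
  zero-variance pairs missing (NaN), never silently 0.
* Quantile convention: linear interpolation (NumPy default), pinned by an
  order-statistics test.
* All randomness flows from explicit seeds (simulator per-lesion seeds are
  drawn from a cohort-level generator; CV fold seeds derive from the bench
  seed); reruns are bit-identical.
* Problem sizes: tests and the acceptance script run recovery/similarity/ML
  stages on 96×96 grids with a 60-lesion cohort, and the structural checks
  at the full 256×256/60-frame acquisition scale — the pipeline itself is
  size-agnostic.

## Known limitations

* The simulator's B-mode pane is static texture under motion; real
  anatomical decorrelation (breathing drift) is only modeled as the binary
  out-of-plane case.
* The binned MI estimator's bias floor (~0.2–0.4 nats at 20 samples) makes
  absolute MI values comparable only within a run.
* Paper mode's pre-CV filtering leaks label information into feature
  selection by design (it mirrors the published workflow); leak-free mode
  is the statistically clean alternative.
* GLSZM/GLRLM statistic definitions have minor published variants; the
  in-repo brute-force oracles are the authoritative definitions here.
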