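# Methods

`neurofuse` implements a multimodal classification analysis for two-group
neuroimaging cohorts (here: chronic mild traumatic brain injury vs.
healthy controls): five voxelwise resting-state fMRI metrics and a PET
SUVR map are reduced to atlas-ROI mean features, classified with
autoencoder-pretrained multilayer perceptrons under fivefold
cross-validation, and interpreted through first-layer weight importance.
Because the study cohort this analysis style targets is not publicly
deposited, the package ships a synthetic cohort generator with planted
ground-truth effects; every empirical claim below is computed by the test
suite or by `scripts/acceptance.py`, never assumed.

## Temporal preprocessing

Input is a 4D BOLD-like grid with repetition time TR and a boolean brain
mask; spatial preprocessing (realignment, normalisation) is assumed done
upstream, and synthetic data are born aligned.

- **Initial-volume discard** removes the first k volumes (k = 10 for a
  180-volume acquisition, leaving T = 170).
- **Confound regression** takes one combined T x p regressor matrix (e.g.
  the six rigid-body motion parameters; any Friston-style expansion is the
  caller's to build), adds an intercept, and keeps the least-squares
  residual per voxel. A rank-deficient design raises an error naming the
  offending columns.
- **Band-pass 0.01-0.08 Hz** is an ideal frequency-domain filter: linear
  detrend, FFT, zero all bins outside the band, inverse FFT. This matches
  the sharp, testable stopband of the common rs-fMRI toolboxes.
- **Framewise displacement** uses the Power convention: sum of absolute
  backward differences of the translations plus rotations converted to arc
  length on a 50 mm sphere; FD[0] = 0. The exclusion rule (> 2 mm
  translation or > 2 deg rotation) is evaluated on the cumulative
  realignment parameters, the convention that phrase refers to.
- **Gaussian smoothing** uses sigma = FWHM / (2 sqrt(2 ln 2)) per axis in
  voxel units, constant (zero) padding, then re-masking
  (convolve-then-remask contract).

## Voxelwise metrics

All five metrics run per subject on the confound-regressed series; ReHo,
DC, FCS and VMHC additionally on the band-passed series, fALFF on the
unfiltered series (its ratio must see the whole spectrum).

- **fALFF** = sum of one-sided FFT amplitudes over 0.01-0.08 Hz divided by
  the sum over all positive frequencies up to Nyquist (0.25 Hz at
  TR = 2 s). The DC bin is excluded so the ratio is mean-invariant. The
  conventional amplitude (square-root-of-power) sums are the default; a
  `power_ratio` switch gives the literal power reading.
- **ReHo** is Kendall's coefficient of concordance W between a voxel and
  its 26 in-mask neighbours:
  W = 12 sum_i (R_i - mean R)^2 / (K'^2 (n^3 - n)), with R_i the rank sum
  of the K' raters at time i. K' is the actual rater count (centre plus
  in-mask neighbours, <= 27), so border voxels stay defined; midranks
  break ties and the tie-correction term is omitted (a small downward
  bias for heavily tied data). An isolated voxel degenerates to W = 1 and
  is flagged.
- **DC** sums Fisher-z weights atanh(r) over edges with Pearson r > 0.25
  (binary edge counting available).
- **FCS** averages atanh(r) over edges with r > r0 = 0.2, normalised by
  the total in-mask voxel count.
- **VMHC** is the Pearson correlation between a voxel and its exact
  mirror across the mid-plane of the x axis (even length required, no
  interpolation); voxels whose mirror leaves the mask are flagged missing
  and excluded from ROI means.
- Correlations are clipped at 1 - 1e-7 before atanh; constant series
  correlate 0 with everything and are flagged degenerate.

**Standardisation.** fALFF, ReHo, DC and FCS maps are standardised by
within-mask z-scoring (the toolbox zfALFF/zReHo/zDC convention); applying
a literal Fisher z-transform to those maps would be undefined since their
values are not correlations. VMHC, being correlation-valued, uses the
true Fisher z-transform. Smoothing order: fALFF smooths the preprocessed
volumes before the spectral step; ReHo and DC smooth the standardised map
afterwards; FCS and VMHC maps are not smoothed; all kernels are 6 mm
FWHM.

## PET SUVR

SUVR(voxel) = intensity / mean intensity over a reference region (a
cerebellar mask in whole-brain FDG studies), making the map invariant to
global dose and scanner gain; the reference-region mean is exactly 1.
Smoothing (6 mm) follows normalisation. Partial-volume correction is out
of scope: it needs tissue segmentation from upstream tools, and the
synthetic PET has no partial-volume blur.

## ROI features, scaling, folds

ROI features are means of in-mask, non-missing voxels per atlas label
(116 ROIs for an AAL-style atlas; 20 for the synthetic default). Feature
scaling is min-max to [0, 1], fitted on each fold's training rows only
and applied unchanged to its test rows (test values may leave [0, 1]);
refitting per fold avoids information leakage that a global fit would
introduce. Cross-validation uses stratified, seeded 5-fold splits — each
fold is the 20% test set once, which is exactly an 80:20 scheme repeated
five times; stratification is needed because a 40-vs-83 imbalance makes
unstratified folds unstable at this sample size.

## Classifier

The networks are plain dense NumPy implementations (deterministic under a
seed, no GPU):

- **Autoencoder**: one ReLU encoder layer of width d_latent, linear
  decoder, mean squared reconstruction error, Adam (lr 1e-3), up to 200
  epochs. d_latent defaults to min(62, R - 1) so that with 116 ROIs the
  encoder aligns with the classifier's first hidden layer (62), while
  small synthetic atlases still compress.
- **MLP**: ReLU hidden layers (62, 32, 16 by default), one sigmoid output
  giving P(case); binary cross-entropy with probabilities clipped to
  [1e-7, 1 - 1e-7]; Adam at lr 1e-3, mini-batch size 1, at most 500
  epochs. Glorot-uniform initialisation, seeded.
- **Early stopping**: 10% of the training rows (stratified for the
  classifier) are held out as a validation split; training stops after 5
  epochs without validation-loss improvement and the best epoch's weights
  are restored. Monitoring the test fold would leak, so it is never used.
- **Single-modality mode**: the trained encoder becomes the classifier's
  first layer and is fine-tuned end to end (a frozen-encoder flag exists).
- **Multimodal mode**: one autoencoder per modality acts as a frozen
  feature extractor; the per-modality latents are concatenated and a
  fresh MLP (62/32/16) classifies the fused vector.
- Decision threshold 0.5 (inclusive) on the sigmoid output; no class
  weighting.

## Scores and interpretation

Accuracy, sensitivity (= recall), specificity and precision follow the
usual confusion-count definitions with cases as positives; a zero
denominator yields an explicit undefined flag rather than NaN. F1 is the
harmonic mean 2PR/(P + R). AUC is the trapezoidal area under the ROC
curve swept over the unique predicted probabilities, equal to the
pairwise concordance probability with ties credited 0.5 (asserted against
a brute-force oracle). Scores are reported per fold and as mean +- SD
across folds.

ROI importance is the row-wise sum of absolute first-layer weights (one
row per ROI). Per fold, the top 10 ROIs are recorded; across folds, ROIs
are ranked by selection frequency (ties broken by mean importance, then
ROI id) and the final top 10 report importance as a percentage of the
final list's total. Rankings come from the single-modality models (the
fine-tuned first layer); the multimodal run exposes its unsupervised
encoders' rankings as well.

Demographics helpers: Pearson chi-square on a 2x2 table without
continuity correction (the convention matching the worked example the
package reproduces) and a pooled or Welch two-sample t-test from summary
statistics.

## Synthetic cohort generator

The generator defines the study conditions for every end-to-end test.
Defaults: 16 x 16 x 12 grid at 3 mm voxels, 20 ROIs, T = 170 at TR = 2 s
(the post-discard length of a 180-volume acquisition); 116-ROI atlases
are supported but not default, purely for test speed.

- **Atlas**: seed voxels are drawn in the left half of the grid and every
  voxel joins its nearest seed (Voronoi); the right half is the exact
  mirror, labels paired (2k-1, 2k) across the plane between the two
  middle columns — so VMHC ground truth is exact without interpolation.
- **Baseline BOLD**: unit-variance white noise plus three random in-band
  (0.01-0.08 Hz) sinusoids whose loadings are drawn per ROI with
  per-voxel jitter. The ROI structure gives ReHo, DC, FCS and VMHC a
  realistic non-degenerate baseline and realistic between-subject feature
  variability.
- **Planted effects** (case subjects only, target ROIs only), one axis
  per metric family: per-voxel independent band-limited signals raise
  fALFF (amplitude); an ROI-wide common broadband signal raises ReHo
  (synchrony); a broadband signal shared with random +-1 signs between a
  target ROI and a diffuse 8% of all other voxels raises DC/FCS (hub) —
  the random signs keep ReHo flat and the diffuse wiring keeps any single
  non-target ROI only fractionally involved; per-mirror-pair broadband
  signals raise VMHC (homotopic); and a mean shift of d x noise_sd raises
  the PET ROI mean (pet_mean).
- **Effect-size semantics**: `effect_size` is the targeted feature-level
  Cohen's d. For `pet_mean` this holds by construction. For the BOLD axes
  the effect amplitudes are scaled by per-axis gain constants calibrated
  once by simulation on the default grid (achieved d within ~15% of the
  request at d = 1.5); they are approximate because the metric responses
  are nonlinear in signal amplitude.
- **Motion**: bounded random walks (|translation| < 0.5 mm, |rotation| <
  0.5 deg), so no synthetic subject trips the exclusion rule;
  `inject_motion_spike` exists to test it.
- **PET**: baseline uptake 10 (arbitrary counts) with per-ROI
  between-subject offsets (SD `noise_sd`, default 0.5), voxel noise, and
  a global dose factor that SUVR removes. The inferior-slab reference
  region carries no ROI-level noise — mirroring the physiological reason
  a reference region is chosen — so the planted d is not absorbed by the
  normaliser.

**What the generator does not emulate**: hemodynamic response shapes,
scanner artefacts, anatomical structure, partial-volume effects,
realistic spatial autocorrelation. Passing tests therefore demonstrate
the correctness and statistical behaviour of the pipeline, not clinical
performance on real mTBI data.

**Known interaction**: when several BOLD axes are planted in the same
ROIs simultaneously, they interfere — e.g. the amplitude axis's
independent per-voxel signals dilute the synchrony axis's concordance, so
ReHo- and DC-based rankings recover planted ROIs less reliably than
fALFF- or PET-based ones on an all-axes cohort. The reference recovery
study therefore reads the ranking from the PET modality, whose planted d
is exact and interaction-free; per-axis selectivity is verified on
single-axis cohorts.

## Reference studies and problem sizes

The repeatable end-to-end studies (in `neurofuse.benchmarks`) use the
default grid with d = 1.5 planted in 5 of 20 ROIs: multimodal
classification on 40 + 40 subjects (accuracy averaged over three cohort
realisations, since one realisation's fold-mean is itself noisy);
PET-modality ROI recovery, null calibration (no effect) and
fALFF/PET fusion benefit over 10 seeds at 20 + 20 where repetition
matters more than single-cohort size. These sizes keep the full suite
runnable on a laptop while leaving the planted effects well powered.

## Limitations

- No hyperparameter search; the architecture and optimiser settings are
  fixed conventions, not tuned values.
- Batch-size-1 Adam training is sequential and CPU-bound; large atlases
  (116 ROIs) work but are slower.
- The weight-based importance ranking is a heuristic: it reflects what
  the network uses, which coincides with the planted ground truth only
  when the features are informative to the trained model.
- The demographics t-test reproduces standard pooled/Welch formulas from
  summary statistics; printed statistics in external tables may not be
  recoverable from their own summaries.
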