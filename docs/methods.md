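# Methods

This note records the modeling choices behind `mrfusion`: what each
component assumes, which knobs matter, what the synthetic data do and do
not emulate, and where the design was genuinely open.

## Imaging model and preprocessing

The toolkit operates on one 2D axial slice per patient and MRI sequence
(T2w, T1c, ADC), the slice with the largest lesion cross-section when a
volume is supplied. Sequences are assumed pre-aligned; the ROI drawn on
T2w is shared by all three. All geometry is normalized to 1 mm × 1 mm
pixel spacing before anything else happens: images are resampled
bilinearly, masks nearest-neighbour and re-binarized, and the output grid
is `round(shape × spacing)`. Patches are 80 × 80 windows centered on the
T2w ROI centroid (half-open `[r0, r0+80)`, zero-padded at borders),
stacked in the fixed channel order (T2w, T1c, ADC).

Per-channel patch normalization defaults to a z-score over the patch.
This removes scanner intensity-scale differences (the two emulated
cohorts use 1.5 T and 3 T systems) but couples lesion and background
statistics: if the lesion brightens, the normalized background darkens.
That coupling is harmless for classification yet degrades saliency maps
(see Grad-CAM below), which is why the saliency toy uses cohort-level,
class-blind standardization instead. Normalization is a caller-visible
switch (`crop_patch(..., normalize=False)`).

## Radiomic features

372 features per sequence: a 93-feature block on the original image plus
the same block on three Laplacian-of-Gaussian scales.

* **LoG scales**: σ ∈ {1, 2, 3} mm (= pixels at unit spacing) — fine,
  medium and coarse texture. The kernel is the sampled Gaussian-Laplacian
  impulse response, explicitly zero-mean corrected so constant and linear
  images map exactly to zero response (scipy's truncated kernel alone
  leaks a ~1e-3 DC term).
* **Discretization**: fixed bin count, 32 levels over the in-mask range,
  applied identically to original and filtered images. The in-mask
  minimum maps to level 1, the maximum to level 32; a constant ROI
  collapses to a single level without error.
* **First-order block (18)**: Energy, TotalEnergy, Entropy, Minimum,
  10th/90th percentile, Maximum, Mean, Median, IQR, Range, MAD, robust
  MAD, RMS, Skewness, Kurtosis, Variance, Uniformity — population
  moments; Entropy/Uniformity use the same 32-level binning as the
  texture matrices. At the enforced unit spacing TotalEnergy coincides
  with Energy; both names are kept so the block totals exactly 18.
* **Texture geometry**: distance-1 offsets in the four 2D directions
  (0°, 45°, 90°, 135°) for GLCM (symmetric, normalized) and GLRLM, with
  feature-wise averaging over directions; 8-connected zones for GLSZM;
  dependence threshold α = 0 and distance-1 8-neighbourhoods for GLDM;
  NGTDM over valid 8-neighbour means. Feature formulas follow the IBSI
  reference formulations.
* **Degenerate conventions** (all values must stay finite): skewness and
  kurtosis of a constant ROI are 0; GLCM correlation and MCC of a
  single-level ROI are 1; NGTDM coarseness is capped at 1e6 when its
  denominator vanishes.

Every texture feature is verified against brute-force enumeration oracles
(explicit pair/run/zone/dependence/neighbourhood loops plus explicit-sum
formulas) to 1e-9 on random ragged ROIs.

Feature standardization for modeling is a per-feature z-score whose
mean/SD are pooled over all three channels of the training cohort — one
scaler shared by channels, so the channel-attention weights remain
comparable across channels.

## Models

**RS.** Closed-form ridge via SVD on centered X and y (equivalent to an
unpenalized intercept; the printed loss has no intercept term, and
centering keeps scores comparable across cohorts). λ is selected by
stratified 5-fold CV over the 1000-value grid {0.001, …, 1.000},
maximizing mean out-of-fold AUC, ties broken toward the larger λ.
The per-fold SVD is factored once and reused across the grid, so the full
sweep at p = 1116 costs seconds. Note the grid's upper bound: at p ≫ n
even λ = 1 is nearly unregularized, so RS behaves like a minimum-norm
interpolator — a property inherited from the study design this package
follows, and the regime in which attention fusion has room to help.

**CFRS.** Conv stack 32×(3×1) → 32×(1×1) → 1×(1×1) with ReLU after the
first two convs and a linear third; the flattened 1 × n map feeds the
3-unit sigmoid attention head; the fused n-vector feeds the 1-unit sigmoid
output head. Both heads are zero-initialized so the attention starts at
0.5 per channel and the output at probability 0.5 — without this, training
on small cohorts occasionally stalls near chance. The forward pass
asserts the fused-feature identity f = ∑ w_c·row_c by construction and
exposes the emitted weights.

**DL / CFDL.** One shared backbone (3×3 convs, widths 16/32/64, BN, ReLU,
2×2 max-pool, FC 6400→64→1); CFDL inserts an SE gate on the 3-channel
input (reduction r = 1, i.e. a width-3 hidden layer) and one after the
first conv (r = 4). DL pins every gate to 1, which reproduces CFDL's
computation bitwise under shared weights — the ablation is
architecture-controlled. Gate placement and reduction are config fields.

**Training.** Adam on binary cross-entropy, batch 32, lr 1e-3, up to 200
epochs with early stopping on validation AUC (patience 20) and
best-validation checkpointing; seeds fix initialization, shuffling and
splits, so runs are bit-reproducible on one device. The logit gradient is
computed directly as (p − y)/n, which stays exact when the sigmoid
saturates in float32. For CFRS the defaults underfit (the early stop
fires on a noisy validation AUC before the 372-weight output head has
converged); the tests and examples therefore train CFRS with lr 3e-3,
patience 40 and up to 300 epochs. Optional class-weighted loss and
flip/rotation augmentation exist but are off by default. The layer stack
runs in float32; losses and AUCs are accumulated in float64.

## Evaluation statistics

AUC is the Mann-Whitney statistic with ties counted ½. Its CI and the
paired two-model test use DeLong structural components; the CI is
asymptotic normal on the AUC scale, clipped to [0, 1]. Degenerate cases:
identical AUCs with zero difference-variance give p = 1 by convention;
unequal AUCs with zero variance raise an error. Thresholded metrics use
`score ≥ t → poor` with Wilson 95% CIs; empty predicted classes yield NA
with a warning. The operating point is Youden's J maximized on the
training cohort (candidate thresholds are midpoints between adjacent
distinct scores, ties toward the lower threshold) and frozen for
validation cohorts. Multivariate logistic regression enters each model's
*binary* prediction at the frozen threshold alongside sex, age, CEA and
dummy-coded cT/cN; Wald CIs; perfect separation triggers an L2-penalized
refit flagged in the output (a score-based alternative is available via
`use_scores=True`). Cohort comparisons: two-sided Mann-Whitney for age,
Pearson χ² without continuity correction for categoricals (Yates optional).

The DeLong implementation is calibrated empirically: under the null its
type-I error at α = 0.05 sits inside [0.03, 0.07] over 2000 simulations,
and on a fixed separated case its p agrees with a 10,000-rep stratified
bootstrap within 0.02 (both in the test suite).

## Grad-CAM

Standard formulation: channel weights are the spatial means of
∂logit/∂activation at the chosen layer (the poor-responder logit,
pre-sigmoid), the map is the ReLU of the weighted activation sum,
bilinearly upsampled to 80 × 80 and max-normalized per image (an all-zero
map stays zero). Any spatial layer can be targeted, including SE-block
outputs. Overlays alpha-blend a jet colormap over a grayscale channel
with blend weight α·heatmap (α = 0.4), so zero-activation pixels keep the
base image.

A known limitation, visible in the tests: the channel-global weighting
discards *where* the gradient lives, so on small CNNs whose fully
connected head can read arbitrary spatial positions, the map is only as
localized as the learned channels are. Localization is therefore
verified on a detection toy (a bright disc present only in poor
responders, cohort-normalized so the disc is the sole class evidence) at
the first pooling layer, for the most confidently classified patients —
and even there one seed in five may fail; the acceptance bar is ≥ 4/5.

## Synthetic data

The generators emulate the *statistical* structure the models assume, not
MR physics (no bias fields, no Bloch simulation, no 3D anatomy).

**Phantom images.** Gaussian background noise per channel (distinct base
intensities for T2w/T1c/ADC), an elliptical lesion (radius 8–16 px,
random orientation and center) shared by all channels, and inside the
lesion: a class shift of `effect[c]` noise-SD units on the mean, a
texture-granularity shift (Gaussian-smoothed noise whose correlation
length grows with `effect[c]` for poor responders, so texture features —
not only first-order means — carry signal), and a patient-level random
intensity offset (SD 1.0 in noise units). That last term is what keeps
the attainable AUC finite: without it, a pixel-level shift is detectable
almost surely and every model saturates at AUC ≈ 1, far from the
performance regime treatment-response models actually operate in. With
the default effects (1.2, 0.66, 0.25) the combined class separation gives
a Bayes AUC ≈ 0.84, and trained models land in the high-0.7s — the range
the clinical problem exhibits. Clinical covariates are drawn with
marginals matched to the published cohort tables and independent of the
label (the study found no clinical variable predictive). Cohort defaults
mirror the study arithmetic: a 267-patient development cohort with 147
poor responders (55.1%; split 193/74) and a 155-patient external cohort
with 112 poor responders (72.3%), 422 patients in all, with the external
prevalence shift preserved.

**Feature tables.** Channel c of patient i draws a latent
t ~ N(y·signal[c], 1); the first `n_informative` (20) features are
`0.7·t` plus independent noise — redundant measurements of one latent, so
adding informative features saturates instead of stacking. Remaining
features share a class-independent equicorrelated nuisance factor
(ρ = 0.3). An earlier independent-shift design was discarded because it
made the task linearly separable (ridge AUC 1.0), failing the generator's
purpose of reproducing the study's difficulty regime.

What passing tests on these phantoms shows: the mechanisms work — the
attention heads recover ground-truth channel informativeness, attention
fusion does not lose to concatenation, the statistics are calibrated.
What it does not show: performance on real rectal-cancer MRI, robustness
to registration error, ROI variability, or scanner effects beyond a
global intensity scale.

## Problem sizes in the test suite

The acceptance-style tests run at desk scale, chosen as the package's own
trade-off between statistical resolution and turnaround: feature-model
comparisons at the study's own cohort size (n = 267, 193/74 split,
5 seeds); image-model comparisons at n = 240 with 10 training epochs;
SE-gate recovery at n = 160; the Grad-CAM toy at n = 64 with 20 epochs;
DeLong calibration with 2000 null replicates. The full suite takes about
ten minutes on a single CPU.

## Known limitations

* Single-slice 2D only; no 3D features, wavelet filters or shape features
  (the 372-feature schema contains none).
* The CNN's exact architecture beyond "SE + 3 conv + 2 FC" (widths,
  kernels, SE placement/reduction, activations) and all training
  hyperparameters are this package's own frozen-and-documented choices;
  they are configurable but the defaults are assumptions, not published
  values. The same applies to the LoG σs, the 32-level binning, the CI
  methods and the Youden operating rule.
* The combined CFDL+CFRS ensemble is out of scope (no defined method).
* Grad-CAM fidelity is bounded by the caveat above; treat maps as
  qualitative.
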