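# mrfusion

Channel-attention fusion of multiparametric MRI for predicting response to
neoadjuvant chemoradiotherapy (nCRT) in locally advanced rectal cancer
(LARC), built as a reusable toolkit: a from-scratch 2D radiomics extractor,
four predictive models, an evaluation-statistics suite, Grad-CAM saliency
maps and a synthetic phantom generator so that every mechanism is testable
without patient data.

## The problem

Poor responders to nCRT (tumor regression grade 2–3) gain little from
preoperative treatment but still suffer its toxicity, so predicting
response *before* therapy matters. Pre-treatment pelvic MRI provides three
complementary sequences — T2-weighted (T2w), contrast-enhanced T1 (T1c)
and the apparent-diffusion-coefficient map (ADC) — and the question the
toolkit operationalizes is whether a learned *channel attention* fusion of
the three sequences beats plain concatenation, for both hand-crafted
radiomics and end-to-end CNNs.

## Models

All models consume one axial slice per patient (the slice with the largest
lesion cross-section), resampled to 1 mm × 1 mm, with a binary tumor ROI
drawn on T2w and shared by all sequences.

**Radiomics side.** Each sequence yields 372 features: 93 (18 first-order
+ 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) on the original image
and the same 93 on three Laplacian-of-Gaussian scales (σ = 1, 2, 3 mm).

* **RS** — ridge regression on the concatenated 3 × 372 = 1116 features,
  minimizing ∑ᵢ(yᵢ − xᵢᵀw)² + λ‖w‖², with λ chosen by stratified 5-fold
  cross-validation over λ ∈ {0.001, 0.002, …, 1.000} to maximize mean
  out-of-fold AUC.
* **CFRS** — the 3 × n feature matrix passes a small conv stack
  (32 filters 3×1 → 32 filters 1×1 → 1 filter 1×1) into a 3-unit sigmoid
  head producing attention weights w ∈ (0,1)³; the fused feature
  fⱼ = ∑_c w_c m_{cj} feeds a 1-unit sigmoid head for the poor-responder
  probability.

**Image side.** The ROI is cropped by a shared 80 × 80 window centered on
the T2w mask centroid, giving a 3 × 80 × 80 patch.

* **DL** — a shallow CNN: three blocks of 3×3 conv (widths 16/32/64) +
  batch-norm + ReLU + 2×2 max-pool, then FC 6400 → 64 → 1 with sigmoid.
* **CFDL** — the identical backbone plus squeeze-and-excitation (SE)
  gates: s = σ(W₂ relu(W₁ ḡ)) rescales channels by s_c, with one SE block
  on the 3-channel input (r = 1) and one after the first conv (r = 4).
  DL is exactly CFDL with all gates pinned to 1, so the comparison
  isolates the attention mechanism.

**Evaluation.** Mann-Whitney AUC with DeLong confidence intervals and the
paired DeLong test between models; sensitivity/specificity/PPV/NPV/accuracy
with Wilson 95% CIs at a Youden-J operating point frozen on the training
cohort; multivariate logistic odds ratios of model predictions adjusted
for sex, age, CEA, cT and cN; χ²/Mann-Whitney cohort comparisons.
Grad-CAM renders, for any spatial layer, the ReLU of the
gradient-weighted activation sum, upsampled to 80 × 80.

The neural models and their exact-gradient training (Adam on binary
cross-entropy, early stopping on validation AUC) run on a compact numpy
reverse-mode layer stack included in the package — no GPU or deep-learning
framework required.

## Worked example

Train the two radiomics models on a synthetic study-scale cohort (267
patients, 193 fit / 74 validation) whose class signal is distributed
unevenly over the channels (latent shifts 1.2 / 0.66 / 0.25 SD):

```python
import numpy as np
from mrfusion import (FeatureTableSpec, TrainConfig, generate_feature_table,
                      train_model, predict_scores, roc_auc, delong_test)
from mrfusion.models import stratified_split

mats, y, truth = generate_feature_table(FeatureTableSpec(n_patients=267, seed=0))
X = np.stack([m.values for m in mats])
tr, va = stratified_split(y, 74 / 267, seed=0)          # 193 fit / 74 validation

cfg = TrainConfig(seed=0, learning_rate=3e-3, max_epochs=300, patience=40)
cfrs, _ = train_model("CFRS", (X[tr], y[tr]), cfg)
rs, hist = train_model("RS", (X[tr].reshape(len(tr), -1), y[tr]), cfg)

s_cfrs = predict_scores(cfrs, X[va])
s_rs = predict_scores(rs, X[va].reshape(len(va), -1))
print(f"lambda* = {hist.lambda_star:.3f}")
print(f"CFRS validation AUC = {roc_auc(s_cfrs, y[va]).auc:.3f}")
print(f"RS   validation AUC = {roc_auc(s_rs, y[va]).auc:.3f}")
print(f"DeLong p (CFRS vs RS) = {delong_test(s_cfrs, s_rs, y[va]).p:.3f}")
w = cfrs.forward(X[va])[1].mean(axis=0)
print("mean attention weights (T2w, T1c, ADC) =", np.round(w, 3))
```

prints

```
lambda* = 1.000
CFRS validation AUC = 0.766
RS   validation AUC = 0.744
DeLong p (CFRS vs RS) = 0.603
mean attention weights (T2w, T1c, ADC) = [1.    1.    0.377]
```

The attention model edges out concatenation (0.766 vs 0.744; the paired
DeLong test is far from significant at this cohort size, as expected), and
the attention head downweights the least informative channel (ADC). The
λ search hits its upper bound of 1.0 — with 1116 features and 193
patients, the capped grid leaves the ridge nearly unregularized, which is
precisely the regime where attention fusion helps.

The same pipeline runs from the shell on image phantoms:

```bash
mrfusion simulate --seed 1 --out data            # 422 patients, two cohorts
mrfusion extract-features --data data/development --out data/development
mrfusion train --data data/development --out ck --models RS,DL --seed 0
mrfusion evaluate --data data/external --checkpoints ck --out report
mrfusion explain --data data/development --checkpoint ck/DL.npz --out maps
```

## Layout

```
src/mrfusion/
  io_formats.py   slices, masks, patches, clinical tables
  radiomics.py    372-feature extractor (first-order + 5 texture matrices, LoG)
  _nn.py          numpy reverse-mode layers (conv, BN, pool, SE, Adam)
  models.py       RS, CFRS, DL, CFDL + training harness and checkpoints
  evaluation.py   AUC/DeLong, threshold metrics, logistic ORs, cohort tests
  gradcam.py      saliency maps and overlays
  synthetic.py    phantom images and feature-table generators
  cli.py          simulate / extract-features / train / evaluate / explain
```

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
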