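# thyrotex

Texture-based computer-aided classification of thyroid-nodule ultrasound
images into benign and malignant classes.

Thyroid nodules are extremely common and mostly harmless, but ruling
malignancy in or out from B-mode ultrasound is subjective and depends
heavily on the radiologist's experience. Second-order texture statistics
offer an objective alternative: malignant nodules tend to show rougher,
higher-contrast echotexture than benign ones. `thyrotex` implements a full
texture-classification pipeline around that idea and ships a synthetic
speckle-texture generator so the entire system runs and is tested without
any clinical data.

## The method

Given a grayscale nodule patch *I*:

1. **Hybrid Wiener–Gabor preprocessing.** An adaptive Wiener filter
   denoises each pixel from its local neighborhood statistics,
   `out = μ + max(σ²−σ²_n, 0)/σ² · (in−μ)`, then a Gabor bank — kernels
   `A·exp(−½(z₁²/σ₁² + z₂²/σ₂²))·exp(i2πF z₁)` over frequencies
   F ∈ {0.1, …, 0.4} cycles/px and orientations θ ∈ {0, π/4, π/2, 3π/4} —
   enhances oriented texture; per-pixel response magnitudes are combined
   and rescaled to [0, 1].
2. **Co-occurrence features.** The gray-level co-occurrence matrix
   P(q, z) is accumulated at four offsets sweeping 180° at distance Δ, and
   ten statistics — autocorrelation (AC), contrast (CT), correlation (CR),
   cluster prominence (CP), cluster shade (CS), dissimilarity (D), energy
   (EN), entropy (ET), homogeneity (H), maximum probability (MP) — are
   averaged over the sweep, giving a 90°-rotation-invariant vector.
3. **Wavelet subband energies.** A separable 2-D DWT adds normalized
   per-subband energy shares as complementary multi-scale features.
4. **AdaBoost.** Decision stumps h_t are boosted for T rounds; with
   β_t = ε_t/(1−ε_t), the strong classifier is the weighted majority

       H(x) = 1   iff   Σ_t log(1/β_t) h_t(x) ≥ ½ Σ_t log(1/β_t),

   and the signed distance from the quorum is the ROC score.

Performance is summarized by accuracy, sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), and the area under the ROC curve; a logistic
multiple regression (IRLS, Wald tests) is included for risk-factor
analysis. The malignant class is the positive class throughout.

See `docs/methods.md` for modeling assumptions, parameter defaults, and
numerical details.

## Worked example

Run the full pipeline on the default synthetic study (200 images, 64×64,
clinical 322:128 class proportions, 70/30 stratified split):

```bash
$ thyrotex run --out runs/demo --seed 0
{"accuracy": "91.7%", "sensitivity": "93.0%", "specificity": "88.2%", "auc": "0.977"}
artifacts: {"config": "runs/demo/config.yaml", "features": "runs/demo/features.csv",
            "metrics": "runs/demo/metrics.json", "model": "runs/demo/model.json",
            "roc": "runs/demo/roc.csv"}
```

91.7% of held-out nodule images are classified correctly; 93.0% of
malignant images are detected (sensitivity) while 88.2% of benign images
are correctly cleared (specificity), and the 0.977 AUC means a randomly
chosen malignant image outscores a randomly chosen benign one 97.7% of the
time. Rerunning the same command is byte-identical.

The same stages are available as a library:

```python
from thyrotex import synthetic_data as sd, preprocessing as pre, glcm_features as gf

ds = sd.generate_dataset(sd.default_config(4, seed=7))
enhanced = pre.hwgf_preprocess(ds.images[0])
feats = gf.extract_fglcm(enhanced, levels=32)
print("label:", ds.labels[0])
print("CT=%.3f  H=%.3f  EN=%.4f  ET=%.3f" % (feats.CT, feats.H, feats.EN, feats.ET))
```

```
label: 0
CT=2.500  H=0.570  EN=0.0097  ET=7.130
```

This benign (label 0) patch has low co-occurrence contrast (CT) and high
homogeneity (H) relative to typical malignant patches, which is exactly the
signal the classifier exploits.

Other subcommands: `thyrotex simulate` (write a PNG dataset + manifest),
`featurize`, `train`, `predict`, `evaluate` — see `--help` on each.

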