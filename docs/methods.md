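# Methods

## Problem and pipeline

`thyrotex` classifies 2-D grayscale ultrasound texture patches of thyroid
nodules as benign (0) or malignant (1). The pipeline has four stages:

1. **Hybrid Wiener–Gabor preprocessing.** A local-statistics Wiener filter
   suppresses acquisition noise, then a bank of Gabor kernels (Gaussian-
   windowed complex sinusoids over a grid of spatial frequencies and
   orientations) enhances texture; per-pixel response magnitudes are
   combined (max by default) and min–max rescaled to [0, 1].
2. **Co-occurrence features.** The gray-level co-occurrence matrix (GLCM)
   P(q, z) counts quantized level pairs at a displacement (Δrow, Δcol).
   Four offsets sweeping 180° at distance Δ — (0, Δ), (−Δ, Δ), (−Δ, 0),
   (−Δ, −Δ) — are used, and ten second-order statistics (autocorrelation,
   contrast, correlation, cluster prominence, cluster shade, dissimilarity,
   energy, entropy, homogeneity, maximum probability) are averaged over the
   sweep. The pooled vector is exactly invariant to 90° image rotations,
   which the tests verify numerically.
3. **Wavelet subband energies.** A separable 2-D DWT (periodization mode)
   splits each level into approximation and three detail subbands; the
   feature is each subband's mean squared coefficient, normalized to shares
   summing to one per level.
4. **AdaBoost.** Discrete AdaBoost over depth-1 decision stumps with the
   weighted-majority decision rule
   H(x) = 1 iff Σ_t log(1/β_t) h_t(x) ≥ ½ Σ_t log(1/β_t),
   β_t = ε_t/(1−ε_t). The signed distance of the weighted vote from the
   half-quorum is the margin score used for ROC analysis.

Evaluation reports accuracy, sensitivity (TPR among malignant) and
specificity (TNR among benign), ROC/AUC by trapezoidal integration over the
unique-score threshold sweep (equal to the tie-corrected Mann–Whitney
probability), and a logistic multiple regression fit by IRLS with Wald
standard errors for risk-factor analysis.

## Synthetic data: what it emulates and what it does not

No clinical image set ships with the package; a generator produces labeled
ultrasound-like patches so every stage is testable offline. Each image is

    clip( speckle × (base + contrast × field) + gaussian_noise )

where `field` is a unit-variance Gaussian random field smoothed at a class-
specific correlation length (optionally anisotropic), `speckle` is a
unit-mean Gamma(shape, 1/shape) field smoothed at the speckle grain scale,
and the additive term models acquisition noise.

Parameter defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| image_size | 64×64 px | patch size typical of a nodule ROI |
| class balance | 322 malignant : 128 benign | mirrors the emulated clinical series (scaled for smaller n) |
| benign texture | base 120, correlation length 4 px, contrast 10 | smooth, homogeneous echotexture |
| malignant texture | base 120, correlation length 1.5 px, contrast 40 | rougher, higher-contrast echotexture |
| speckle_shape | 10 | Gamma shape; SD ≈ 32% of local intensity, strong B-mode speckle |
| speckle_grain | 1.5 px | speckle-cell correlation scale; B-mode speckle has a finite grain size set by the imaging point-spread function, so a pixel-white field would overstate its high-frequency content and mask texture differences |
| gaussian_noise_sd | 2 gray levels | electronic/quantization noise floor |
| heterogeneity | 0.2 | per-image lognormal jitter (SD of log) on correlation length and contrast amplitude; models biological variation between nodules of a class. Zero would make every image of a class statistically identical — unrealistically easy, to the point that a single threshold on one feature classifies perfectly |

With these settings the two classes overlap but are clearly separable by
the pooled feature set: at the default 200-image study the held-out
accuracy is typically 0.92–0.98 with AUC near 0.98, and the boosted
ensemble beats the single best stump — the operating regime the package is
designed to demonstrate. The generator does **not** emulate beam geometry,
attenuation/shadowing, log compression curves, probe-frequency effects,
nodule boundaries or per-patient correlation between images (each image is
an independent sample). Passing tests therefore demonstrate correctness of
the algorithms and the expected qualitative behavior on speckled texture,
not clinical performance.

## Numerical choices

- **Quantization**: linear min–max binning into L = 32 levels (configurable);
  the maximum maps to L−1; a constant image maps entirely to level 0.
  Because binning is per-image min–max, GLCM features measure *relative*
  texture roughness, independent of overall gain.
- **GLCM accumulation** is asymmetric (one direction per offset); rotational
  coverage comes from the four-offset sweep. A `symmetric` flag adds the
  transpose before normalizing.
- **Homogeneity** uses 1 + |q−z| in the denominator, keeping it in (0, 1];
  **entropy** uses log₂ with 0·log 0 ≡ 0; **correlation** with a degenerate
  marginal (σ_e σ_g = 0) is reported as 0 with a flag rather than NaN.
- **Convolution** is true convolution (kernel flipped) with edge-mirroring
  boundary and same-size output; the Wiener window default is 3×3; unknown
  noise variance is estimated as the mean of local variances.
- **Gabor bank defaults**: frequencies {0.1, 0.2, 0.3, 0.4} cycles/pixel ×
  orientations {0, π/4, π/2, 3π/4}, σ₁ = σ₂ = 2 px, 13×13 kernels,
  max-magnitude combination. Frequencies above Nyquist (0.5) are rejected.
- **Wavelet**: db2 default (Haar supported for hand-checkable cases);
  periodization mode makes orthonormal energy conservation exact to
  rounding, which the tests assert at 1e-8. The DWT is not shift-invariant;
  tests use fixed alignment. Subband orientation naming is behavioral:
  the "horizontal" subband is the one that dominates on horizontal-stripe
  images (verified by test rather than assumed from any library convention).
- **Stump search** enumerates midpoints of consecutive sorted unique values
  plus below-min/above-max sentinels, both polarities; ties break toward
  the lowest feature index, lowest threshold, then ≤-polarity. Weighted
  errors are clamped to [0, 1] against cumulative-sum rounding.
- **Boosting**: T = 50 rounds default; a perfect round (ε_t = 0) is kept
  with β_t = 1e-10 and stops training; ε_t ≥ 0.5 drops the round and stops.
- **AUC ties** receive half credit, making the trapezoidal and pairwise
  definitions identical to machine precision.
- **Logistic IRLS**: Newton steps with step-halving (keeps the likelihood
  monotone), convergence at max |score| < 1e-8 or 100 iterations;
  separation is flagged (not raised) when the coefficient norm diverges
  (>1e4) or the fitted probabilities coincide with the labels within 1e-6.
- **Reproducibility**: one master seed is expanded through a seed sequence
  into substreams for data generation and the train/test split; all CSV and
  JSON artifacts are written with fixed float formatting ("%.12g"), so a
  rerun with the same config is byte-identical.
- **Study sizes** used by the tests and the acceptance script: 200-image
  default study for end-to-end checks, 450 images (322:128) for the
  clinical-balance run, oracle suites on 8×8 images with L = 8. These sizes
  make every oracle exhaustively checkable while exercising the same code
  paths as larger runs.

## Design choices that were genuinely open

- **"Functional" GLCM** is implemented as the standard matrix plus the
  four-offset sweep; nothing beyond that is operationally defined for it.
- **"Adaptive" wavelet selection**: the wavelet family and level are
  configurable; when selection is wanted it should be done by
  cross-validated training accuracy on the training split only. The default
  (db2, 1 level) is fixed rather than auto-selected to keep runs cheap and
  deterministic.
- **Feature fusion** concatenates the ten co-occurrence statistics with the
  wavelet energy shares (14 columns at 1 level); selection between the two
  blocks can be emulated by training on a column subset of the feature CSV.
- **Gabor combination** across the bank is per-pixel max (mean available):
  max preserves the strongest orientation response, which is what the
  co-occurrence stage should see.
- **Positive class** is malignant = 1 throughout, matching the clinical
  reading of sensitivity/specificity.

## Known limitations

- Per-image min–max quantization discards absolute intensity; classes that
  differ only in mean gray level are invisible to the GLCM features.
- The Wiener filter assumes additive noise; it attenuates but does not
  model multiplicative speckle.
- AdaBoost with exhaustive stump search is O(rounds × features × n log n);
  fine for hundreds of images and tens of features, not for large studies.
- The logistic module fits any user-supplied design matrix; it does not
  choose covariates.
- Margins from a small ensemble take few distinct values, so ROC curves
  from short boosting runs are coarse.
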