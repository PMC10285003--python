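# octood

Unsupervised out-of-distribution (OoD) detection for instrument-integrated
OCT (iiOCT) M-scans.

In robot-assisted retinal microsurgery, an OCT fiber built into the
instrument tip streams one-dimensional depth profiles (*A-scans*; here 674
pixels at 3.7 µm/pixel, grouped into *M-scans* of 10 consecutive A-scans).
A learned model reads each A-scan and estimates the distance from the
instrument to the internal limiting membrane (ILM) — the innermost retinal
surface. When the incoming signal is corrupted (noise bursts, saturation
stripes, probe artefacts), that distance estimate becomes silently wrong,
which is a patient-safety problem. This package implements the safety layer:
a detector that flags M-scans too far from the training distribution to be
trusted, plus everything needed to study it end to end.

## The method

**MahaAD.** A feature pyramid `f` with `K = 9` stages maps a preprocessed
M-scan (bicubic resize 10×674 → 64×224, ImageNet z-scoring) to `K`
spatially-averaged feature vectors `f_k(x)`. On `N` clean training M-scans
one multivariate Gaussian per stage is fitted,

```
μ_k = (1/N) Σ_i f_k(x_i),   Σ_k = (1/N) Σ_i (f_k(x_i) − μ_k)(f_k(x_i) − μ_k)ᵀ,
```

with the covariance regularized (Ledoit–Wolf shrinkage by default) so it is
invertible even when the feature dimension exceeds `N`. A test M-scan is
scored by the sum of per-stage Mahalanobis distances

```
s(x) = Σ_k √((f_k − μ_k)ᵀ Σ_k⁻¹ (f_k − μ_k)),
```

and is declared OoD when `s(x)` exceeds the single threshold `τ` (rank-based
evaluation avoids `τ` entirely). When an M-scan is OoD, all of its A-scans
are withheld from the downstream distance estimator.

Around the detector the package provides:

- `octood.phantom` — a synthetic M-scan generator with exact ILM ground
  truth (dark vitreous, bright ILM onset, textured retinal band,
  hyperreflective RPE stripe, multiplicative speckle, smooth ILM drift);
- `octood.corruptions` — the eight corruption operators (noise σ=50,
  smoothing σ=5, contrast {0.1,0.2,0.3,2,3,4}, intensity ±U(25,50), stripes,
  rectangle, depth shift ±U(25,100), zoom U(1.5,1.75)) and dataset-level
  corruption at a ratio `p`;
- `octood.retina` — the downstream model: a 1-D U-Net regressing per-A-scan
  ILM heatmaps (argmax → depth index → distance at 3.7 µm/pixel);
- `octood.baselines` — Raw-MahaAD (K=1 Gaussian on the raw signal), SNR,
  a supervised corruption classifier, heatmap-entropy uncertainty, and a
  no-rejection reference;
- `octood.evaluation` — rejection/MAE curves over corruption ratios and
  AUROC/average-precision detection metrics.

Detectors and the retina model are scikit-learn-style estimators
(`fit` / `ood_scores` / `predict`, `get_params`/`set_params`), so they
compose with sklearn tooling; a `octood` CLI exposes the pipeline
(`generate`, `corrupt`, `fit`, `score`, `train-retina`, `predict-retina`,
`run-rejection`, `run-detection`, `report`).

## Worked example

```python
import numpy as np
import octood as o

params = o.PhantomParams()                      # 10×674 M-scans, [0, 255]
train, _ = o.generate_mscans(334, params, seed=0)
test, ilm = o.generate_mscans(200, params, seed=1)

detector = o.MahaADDetector(extractor=o.make_test_extractor(0)).fit(train)

rng = np.random.default_rng(2)
corrupted, labels, specs = o.corrupt_dataset(test, p=0.5, rng=rng)
scores = detector.ood_scores(corrupted)
result = o.detection_metrics(scores, labels)
print(f"clean score mean     : {scores[labels == 0].mean():.1f}")
print(f"corrupted score mean : {scores[labels == 1].mean():.1f}")
print(f"AUROC                : {result.auroc:.3f}")
print(f"average precision    : {result.average_precision:.3f}")
```

prints

```
clean score mean     : 33.6
corrupted score mean : 245.8
AUROC                : 0.997
average precision    : 0.997
```

Clean M-scans score around 34 (summed distances across 9 stages), corrupted
ones roughly seven times higher, and ranking by score separates the two
groups almost perfectly: half the test set was corrupted (100 of 200
M-scans, each by one of the eight operators) and AUROC/AP ≈ 0.997 means a
randomly chosen corrupted M-scan outranks a randomly chosen clean one with
that probability.

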