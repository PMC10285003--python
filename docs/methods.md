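# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `octood`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

An iiOCT probe produces A-scans of `P = 674` depth pixels (3.7 µm/pixel,
2.49 mm depth) at ~700 Hz; ten consecutive A-scans form one M-scan, the
unit at which OoD decisions are made. The downstream task model `r` maps an
A-scan to a heatmap over depth whose argmax is the ILM location; the
instrument-to-retina distance is `index × 3.7 µm`. An M-scan flagged OoD
has all ten of its A-scans withheld from `r`.

## Synthetic phantom

Real iiOCT recordings are not distributable, so all experiments run on a
synthetic phantom that emulates the *statistical structure* the detector
and the ILM model rely on, with exact ground truth:

- piecewise-constant depth profile: vitreous (mean 20), step to the retinal
  band (mean 90) at the ILM index, a hyperreflective RPE-like stripe
  (mean 190, 14 px wide, 120 px below the ILM), attenuated signal below;
- multiplicative log-normal speckle with unit mean (σ_log = 0.35), the
  multiplicative-noise character of coherent imaging;
- the ILM depth starts at N(300, 40²) per M-scan and performs a reflected
  Gaussian random walk (σ = 2 px/step) across the ten A-scans, emulating
  smooth probe/eye motion. Reflection keeps the index inside [0.02·P, 0.9·P].

Intensities are generated directly on the [0, 255] scale the corruption
parameters assume, rounded to integers (so TIFF round-trips are
bit-identical), and clipped. Defaults mirror the study conditions:
T = 10, P = 674, 334 training M-scans, 2000 test M-scans.

What the phantom does **not** model: wave-optics speckle correlation,
depth-dependent attenuation profiles, real retinal layering beyond the
ILM/RPE bands, probe vignetting, or the appearance variability of real
ex vivo tissue. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the stated corruption model — not
performance on real recordings.

## Corruption operators

Eight operators, each applied with equal probability when corrupting a
dataset, all clipping back to [0, 255] (the corruption is defined on that
scale; clipping keeps outputs valid images):

| type | parameters |
|---|---|
| noise | additive Gaussian, μ=0, σ=50 |
| smoothing | 2-D Gaussian filter, σ=5 px, reflective boundary |
| contrast | factor from {0.1, 0.2, 0.3, 2, 3, 4} about the per-M-scan mean |
| intensity | one scalar shift, sign equiprobable, magnitude U(25, 50) |
| stripes | 1 or 2 A-scans replaced by per-stripe constants U(100, 200) |
| rectangle | width U{6..10} × depth U{15..30} px, one constant U(100, 200) |
| shift | suffix of A-scans (split point uniform) circularly rolled in depth by ±U(25, 100) px |
| zoom | one factor U(1.5, 1.75) per M-scan; linear resample + center crop |

Open readings resolved as package decisions: the contrast pivot is the
per-M-scan mean (preserves average brightness); the intensity shift is one
scalar per M-scan; "shift" rolls a contiguous suffix (circular roll, sign
equiprobable); zoom uses a single factor per M-scan (magnification only, so
center-cropping never needs padding). Dataset-level corruption perturbs
exactly `round(p·n)` M-scans (half-up rounding), not Bernoulli-p, so top-p
rejection is exactly aligned with the corrupted count.

## Feature extraction

M-scans are mapped to [0, 1], resized 10×674 → 64×224 with bicubic
interpolation — the A-scan (temporal) axis is stretched so it carries
weight comparable to depth — replicated to three channels and z-scored
with the ImageNet statistics (0.485/0.456/0.406, 0.229/0.224/0.225).

The default extractor is a **seeded random convolutional pyramid**: nine
3×3 conv + ReLU stages (channels 8→64, 2×2 average pooling after the first
five), He-initialized from a fixed-seed PCG64 stream. It downloads nothing
and is bit-deterministic across platforms. Untrained multi-scale conv
features are a weak but real representation; they suffice to separate
clean from corrupted phantoms by a wide margin (the end-to-end tests
compute the actual AUROCs). An ImageNet-pretrained EfficientNet-B0 is the
intended production extractor; it is exposed as an optional capability that
raises `CapabilityError` in installations without a deep-learning runtime,
never silently substituting.

## MahaAD

Per stage, the mean and the biased (1/N) covariance are fitted exactly as
written, then regularized as `c·S + α·I`:

- **ledoit-wolf** (default): `c = 1−ρ`, `α = ρ·tr(S)/d`, ρ estimated by the
  Ledoit–Wolf formula. Mandatory in practice: late-stage dims exceed N.
- **diag**: diagonal loading `α = ε·tr(S)/d`, ε = 1e-3 default.
- **none**: exact inverse; fitting fails if S is singular (used for the
  affine-invariance property test).

S is stored via the economy SVD of the centered data; distances use the
Woodbury identity, so nothing bigger than `d × rank` is ever formed and the
raw-signal baseline (d = 6740) stays cheap. The degenerate all-identical
case floors α at 1e-6 (regularized covariance = ε·I). Precision factors are
computed once at fit time; scoring never re-inverts.

`τ` is exposed as a config value plus a training-quantile helper
(`set_threshold_from_quantile`). Note that training scores are optimistic
(the Gaussians were fitted on them): at N = 334 the 99th-percentile
threshold flags ~2% of fresh clean data rather than 1%. The evaluation
protocols are rank-based and avoid `τ`.

## Downstream ILM model

A 1-D U-Net-like network: four down-pooling and four upsampling steps, one
3-tap convolution per step, skip connections by concatenation, channel
widths doubling per level (default base 16; tests use 8). Inputs are
A-scans scaled to [0, 1] and edge-padded from 674 to 688 (divisible by 16);
outputs are cropped back. Targets are unit-peak Gaussians of width
σ_gt = 3 px at the annotated ILM. Training: standard L2 loss, Adam at
lr 1e-4, batch 64, early stopping on validation loss (patience 10 default).

The output head is **linear**, clipped to [0, 1] at inference. With the L2
heatmap loss a sigmoid head collapses to the all-background solution (the
saturated units kill the sparse foreground gradient; empirically the
validation MSE converges exactly to the mean squared target and the argmax
is uninformative), while the linear head converges to sub-pixel MAE at the
stated learning rate. Argmax ties break toward the probe (smallest index)
— conservative for safety, reporting the nearer surface.

The network and its training loop are implemented directly in numpy
(im2col + GEMM convolutions, explicit backprop, Adam), which keeps training
deterministic for a fixed seed and free of any deep-learning runtime.

## Baselines

- **Raw-MahaAD**: one Gaussian on the flattened 10×674 raw M-scan
  (config switch for the resized image instead); identical to plugging a
  flattening extractor into the MahaAD machinery, which a test asserts.
- **SNR**: score = −mean/std over all pixels. The sign convention is a
  package decision (the canonical noisy-scan case should rank as more OoD);
  structural corruptions can invert its usefulness. A constant M-scan gets
  the −inf sentinel (logged).
- **Supervised**: perturbs exactly 50% of the clean training set with the
  four training corruption types (noise, smoothing, shift, intensity) and
  fits a small trainable classifier — an MLP (one hidden layer, 64 units)
  on 4×4-block means and standard deviations of the preprocessed image
  (brightness + local texture). This deliberately replaces fine-tuning a
  pretrained ImageNet backbone; the contract (binary corruption probability
  from the same preprocessed input, blind to the other four types) is
  unchanged.
- **Uncertainty**: Shannon entropy of the normalized predicted heatmap,
  averaged over an M-scan's A-scans; all-zero heatmaps count as uniform
  (maximal entropy). Whole-heatmap entropy is a deliberate reading of
  "uncertainty of the heatmap"; entropy of the scalar peak probability
  alone would be ill-defined.
- **No-rejection**: constant score 0; under top-p ranking the stable
  dataset order resolves ties, so the first `round(p·n)` entries are
  rejected.

## Evaluation protocols

**Rejection curves.** For each `p` in {0, 0.1, …, 0.9}: corrupt `round(p·n)`
test M-scans (fresh independent RNG stream per p), score all with the
detector, reject the top-p by score (stable-order ties), predict the ILM on
all retained A-scans and report MAE in px and µm (µm = 3.7·px) against the
**pre-corruption** annotations — the corruption is the fault, not a new
ground truth, so a detector that passes a geometrically shifted scan is
penalized, as the protocol intends. MAE aggregates all retained A-scans
equally. A perfect (oracle) detector rejects exactly the corrupted scans
and its curve stays at the clean MAE for every p.

**Detection metrics.** AUROC (rank statistic, midrank ties) and average
precision via scikit-learn; tests pin both against independent brute-force
oracles (exhaustive pair counting; rank-sweep PR area) to 1e-12. The
per-corruption report applies one type at a time at p = 0.5 and tabulates
AUROC per (detector, type), marking the four types the Supervised baseline
never saw (stripes, rectangle, zoom, contrast).

## Scales used by the test suite

Chosen as the package's own desk-scale defaults: the shared retina model
trains on 500 M-scans with 100 for validation (base width 8, ≤30 epochs);
rejection curves run on 300 annotated test M-scans; MahaAD fits on 334
training M-scans (the study's count) and is evaluated on 300; parameter
recovery uses >10⁵ pixels for the noise σ and a 101×401 impulse field for
the smoothing σ. All randomness is seeded; expected values in tests were
computed by the independent oracles described above.

## Known limitations

- The random pyramid is a stand-in representation: absolute scores and
  AUROCs are not comparable to a pretrained backbone, only the pipeline's
  behavior is.
- The phantom's simplicity makes most corruptions easy to detect; per-type
  AUROCs near 1.0 say little about real-world difficulty.
- No per-pixel anomaly localization, no Gaussian-mixture extension, no
  temporal filtering across M-scans (deliberate non-goals).
- The Glow flow-based baseline of the surrounding literature is not
  implemented; the detection harness accepts any labeled score file, so
  external scores can be evaluated with the same metrics.
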