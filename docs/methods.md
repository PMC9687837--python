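# Methods

This note documents the models, conventions and design choices behind
`paperecg`, in the order data flows through the toolkit.

## Synthetic sheet model (`synthio`)

A rendered sheet is a composite of four layers on a white page: the
millimetre grid, header/footer text labels, twelve lead-strip traces plus a
full-width rhythm strip, and page-level degradations (contrast compression
and additive Gaussian scanner noise). Geometry follows ECG paper
conventions: one minor grid square = 1 mm = 0.04 s at 25 mm/s and 0.1 mV,
so the minor-grid pixel pitch (8 px on the default 2213x1572 page) fixes
both the time scale (200 px/s) and the voltage scale (80 px/mV). Traces are
drawn as 3 px polylines in near-black ink; the grid is light gray
(intensity 210, major lines every 5th minor at doubled darkness). The
ink/grid contrast mirrors real sheets and is what makes Otsu binarization
separate trace from ruling.

**Beat template.** One beat is a sum of five Gaussians — P, Q, R, S, T
deflections with amplitudes (mV), centers (s) and widths (s):
P(0.15, 0.10, 0.025), Q(−0.10, 0.20, 0.012), R(1.0, 0.22, 0.020),
S(−0.25, 0.24, 0.012), T(0.30, 0.40, 0.040) — giving a QRS duration in the
physiologic 60–100 ms range. An ST-segment offset is added only between the
S and T centers; `t_polarity = −1` inverts the T wave. Beat onsets advance
by the RR interval perturbed by a uniform jitter fraction; a 0.4 Hz
baseline-wander sinusoid and white trace noise complete the trace.

**Class priors.** The five classes are *separable surrogates*, not clinical
simulations: NHB is the baseline template (72 ± 3 bpm); AHB has strongly
irregular RR intervals (jitter 0.30); MI has ST elevation (+0.30 mV) and a
deepened Q (−0.40 mV); HMI has a pathological Q (−0.45 mV) with an inverted
T; the COVID-19 surrogate has an elevated rate (112 ± 5 bpm) with a damped
T (0.08 mV). No published morphology exists for the COVID class; its prior
is an arbitrary separable choice. A depth-4 decision tree on rhythm-strip
summary features separates all five classes perfectly at 10 sheets/class,
which is the separability premise the training checks rely on.

**Determinism.** One top-level seed; image *k* of a dataset uses seed
`seed + k` (classes enumerated in NHB, AHB, MI, HMI, COVID order), so
`generate_dataset` is a pure function of `(counts, seed)` and re-runs are
byte-identical.

**What the generator does not emulate** — photographic perspective, paper
folds, lead-dependent electrophysiology (all strips share one waveform with
per-strip amplitude scaling), printer half-toning, and real label fonts.
Passing tests therefore demonstrate that the pipeline and model behave
correctly on sheets with these statistics, not clinical performance.

## Preprocessing (`preprocess`)

Stage order: crop → grayscale → Otsu → 2x2 opening → small-component
removal → invert → 3x3 Gaussian blur → non-local means → histogram
equalization. Each stage's output feeds the next; all intermediates are
retained.

Conventions and parameter choices:

- **Crop**: fixed ratios 2058/2213 x 1210/1572 of the input size (floor),
  removed columns split evenly, removed rows split 50/50 top/bottom
  (configurable via `crop_vertical_split`); the output is an exact
  sub-window, never resampled. No text detection is attempted — the label
  bands sit at fixed page fractions.
- **Otsu**: exhaustive 256-threshold maximization of between-class
  variance; ties take the lowest threshold; *dark* pixels (≤ t) are
  foreground since ink is dark. A constant image is flagged degenerate.
- **Opening**: erosion then dilation with a 2x2 rectangle anchored at the
  element's top-left; border handling is edge replication (avoids creating
  a dark frame that would become a spurious component). Verified
  anti-extensive and idempotent.
- **Component filter**: 8-connectivity, strict `area < 50` px. On synthetic
  sheets the binarization already excludes the lighter grid, and the
  opening plus the component filter remove residual fragments; measured on
  ground-truth masks, ≥ 95% of grid pixels are erased while ≥ 90% (typically
  ≈ 97%) of trace pixels survive.
- **Gaussian blur**: explicit sampled, normalized separable kernel;
  sigma 0.8 for the 3x3 default (the standard size↔sigma relation; the
  stage's origin leaves sigma unstated).
- **Non-local means**: classic formulation — weights
  `exp(−d/h²)` with `d` the Gaussian-kernel-weighted mean squared patch
  difference — implemented as a vectorized shift-and-accumulate over the
  search-window offsets. Defaults patch 5, search distance 6,
  `h = 1.15·σ̂` with `σ̂` from the wavelet-detail noise estimator. The
  8x8 double-loop oracle test pins the formula to 1e-6.
- **Histogram equalization**: lookup table `h_k = INT[255·t_k + 0.5]` over
  the empirical CDF; monotone by construction; applied to the single
  channel after denoising.

Ambiguity resolved: after the small-component set is identified, the
*component-removed signal image* (not the drawn grid image) is carried
forward to inversion; this matches the visual intent of the published
intermediate outputs.

## Quality metrics (`quality`)

MSE/RMSE on the [0,1] scale but PSNR from 8-bit MSE with MAX = 255: the two
printed scales are mutually inconsistent, and this combination reproduces
both orders of magnitude from a single image pair. The original for
comparison is the *label-cropped* image, so shapes match the processed
output. SSIM uses the standard uniform 7x7 window with K1 = 0.01,
K2 = 0.03, unbiased covariances. PSNR bins are upper-inclusive 1-dB
intervals (`x.01 – (x+1).00`); identical pairs (+∞ dB) are binned
separately and excluded from the PSNR mean.

## Splitting (`datakit`)

The 70:20:10 split is per class: `floor(0.7·n_c)` train, `floor(0.2·n_c)`
validation, remainder test, assignment by seeded shuffle. Per-class
flooring (rather than global rounding) is what makes the published class
sizes (546, 250, 203, 74, 859) reproduce the published totals
1351/384/197 exactly; global rounding would give 1352/386/194. K-fold
partitions deal shuffled class members round-robin, so per-class fold sizes
differ by at most one. "1-fold" is not a standard notion; it is interpreted
as a single seeded stratified holdout using the same 70:20:10 ratios, with
the 10% test portion as the evaluation fold.

## The InRes network (`inres`, `nn`)

The numerical core is a small channels-first numpy layer library with
explicit backward passes (im2col convolutions; gradients of every layer are
verified against finite differences in the test suite). All randomness
(weight init, shuffling) flows from one seed; training runs are
bit-reproducible.

**Architecture.** Block-1 stem: 3 conv + pool + 2 conv + pool. Blocks 2–4:
stacks of 3/5/3 residual units; a unit's inception branch has 6/5/4
convolutions plus one pooling layer, its residual branch 3 convolutions,
combined as `y = act(r(x) + α·i(x))`. Both branches map to the same filter
count, so no projection is needed on the skip path. `α` starts at 0.1,
trainable and unclamped (only the *initial* value is constrained to
[0.1, 0.3]); with scaling disabled `α ≡ 1` and is not a parameter — the
base (unscaled) variant used as the ablation starting point.

**Shape bookkeeping.** A stride-2 pool in every stacked unit would collapse
a 224 px input before the later blocks, and the residual sum forces both
branches to equal spatial shape; unit-internal pooling layers are therefore
2x2 *stride-1* size-preserving, and downsampling happens in the stem's two
pools plus one stride-2 transition pool after each residual block
(224 → 56 → 28 → 14 → 7). Transitions and the head are reported separately
from the per-block layer counts.

**Layer counting.** The primary convention counts convolutions + pooling
layers inside the four blocks: 7 + 30 + 45 + 24 = 106, the figure in the
model's name. (A published per-block figure of 28 for the last block is
inconsistent with its own 3 x (4+1+3) composition; the toolkit reports 24
and also totals under conv-only and conv+pool+activation conventions.)
`count_macs` reports multiply-accumulates from layer shapes
(`H·W·C_out·C_in·k²` per convolution); the unit of the published
"time complexity" column is undefined, so MACs are reported, not matched.

**Desk-scale preset.** `ModelConfig.reduced()`: 64x64 input, 8 filters,
one unit per block, 25 epochs. Training sheets for this preset are compact
256x192 single-column pages (2 lead rows + rhythm strip) so the beat
morphology survives downsampling to 64 px. On 250 synthetic images
(50/class, 80/20 split) the preset reaches ≈ 0.94 held-out accuracy in
about three minutes on one CPU core. Full-size training (224x224, 64
filters, 160 epochs) is out of desk scope by design.

## Ablation harness (`ablation`)

Greedy and sequential: ten studies in fixed order, each adopting one knob
value before the next study runs. Selection: among candidates within
`δ = 0.5` accuracy points of the study maximum, take the lowest
complexity; break ties by higher accuracy, then listing order. `δ` encodes
the one deviation from pure argmax in the recorded log (3x3 kernels chosen
over marginally better 5x5 at ~60% more compute); `δ = 0` degenerates to
argmax. Findings label each candidate against the running best accuracy
(improved / identical-to-2-decimals / dropped). Replaying the recorded
study log terminates in exactly the tuned configuration. Two batch-size
rows of the recorded log carry annotations inconsistent with the log's own
accuracy sequence under any single comparison rule; the tests freeze the
derived labels for those two rows and the recorded labels for the other 36.
The harness itself never trains full-size models; the evaluator is
injected.

## Evaluation (`evalkit`)

Macro (unweighted) averaging over classes for all one-vs-rest metrics;
0/0 ratios become NaN sentinels, excluded from macro means with a warning.
FPR/FNR/FDR are computed as exact complements of specificity/recall/
precision (identical denominators), so the complement identities hold to
the last bit. MAE/RMSE operate between one-hot actual vectors and score
vectors, averaged over all `n·K` entries — a documented convention, as the
operands are not standardized. Kappa uses row/column marginal chance
agreement; MCC is the generalized multiclass correlation. The Wilcoxon
signed-rank test drops zero differences, midranks ties, and for n ≤ 25
computes the exact two-sided p over the sign-flip null by dynamic
programming on doubled ranks (identical to enumerating all 2ⁿ assignments);
larger n uses the tie-corrected normal approximation with continuity
correction. Cross-validation reports per-fold accuracy, mean, and
*population* SD over folds.

## Numerical and degenerate-input choices

- Constant image → Otsu degenerate flag, all-background; σ̂ ≈ 0 is floored
  at 1e-3 before scaling the NLM strength.
- Identical image pairs → PSNR +∞ sentinel, own report bin.
- Max-pool ties break to the first window position (row-major); equal-
  accuracy ablation ties keep the first-listed candidate.
- All neighborhood operations replicate edges; convolutions zero-pad
  (their inputs are activations, not page images).
- Empty classes contribute zero to every split; `k` larger than a class
  size warns and allows empty per-class folds.

## Known limitations

- Synthetic sheets only; no claim of clinical fidelity or of reproducing
  accuracies reported on real scanned archives.
- The numpy backend is CPU-bound; full-size (224x224, 64-filter) training
  is supported in principle but not practical desk-side.
- The recorded study log ships as data for replay; live ablation with the
  reduced trainer is possible through the evaluator interface but is not
  exercised by default.
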