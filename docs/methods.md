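# Methods

`npcstage` implements a multi-task deep-learning pipeline that
simultaneously delineates a gross tumor volume (GTV) in a single
contrast-enhanced 3D MR-like volume and predicts the tumor's T-stage
(T1–T4), together with the synthetic data, metrics and statistics
needed to exercise every stage of the pipeline without clinical data.
This note records the model, the study conditions the phantom generator
encodes, the numerical choices, and what the shipped benchmarks do and
do not demonstrate.

## Model

**Segmentation network.** A U-shaped 3D encoder–decoder with eight
encoder units and seven decoder units. Each unit is a 3×3×3
convolution + instance normalisation + ReLU. Downsampling uses
max-pooling in-plane and average-pooling along the slice axis; the
schedule is derived from the input grid (each axis is halved while it
remains divisible and above a floor — anisotropic inputs are never
pooled into degenerate grids) and is fully configurable. Skip
connections join each encoder level to the decoder level of matching
resolution. A 1×1×1 convolution + sigmoid produces the voxelwise tumor
probability map p̂. The three most semantic feature maps — the seventh
and eighth (final) encoder units and the first decoder unit — are
tapped for cross-task fusion.

**Mask multiply.** The staging network's input is the elementwise
product of the input volume with the soft probability map. The product
is differentiable, so staging errors can reshape the segmentation
output (see *Gradient routing* below).

**Staging backbone.** A four-stage residual bottleneck network
("bottleneck transformer"): each block reduces channels 2× with a
pointwise convolution, applies a spatial operator, and expands back
with a residual connection. The final stage holds three blocks whose
spatial operator is multi-head self-attention (4 heads) instead of a
convolution; earlier stages stay convolutional. At desk scale the
widths are (w, 2w, 4w, 4w) with w = 4–8; ResNet-50-like widths are a
config away.

**Attention.** Per head, logits are (q·kᵀ + q·posᵀ)/√d_head, softmaxed
over key positions and applied to v; head outputs are concatenated and
mixed by a linear layer. The spatial position encoding `pos` is a
learned *absolute* encoding factorised per axis (a (D+H+W)×C parameter
budget, summed over the three axes). The factorised-absolute choice —
rather than relative offsets — matches the "position multiplied by q"
formulation directly and keeps the attention kernel simple; at the
small attention grids used here (tens of positions) the two encodings
span essentially the same function class.

**Feature-fusion-aware (FFA) module.** The three segmentation taps are
projected by 1×1×1 convolutions, resized (trilinear) to the backbone's
final grid, concatenated with the backbone features, reduced by a
pointwise convolution, and passed through a residual multi-head
self-attention block. The ablated variant (`wo_ffa`) stops after the
reduction — plain concatenation, no attention.

**Classifier.** Global average pooling followed by an affine map to 4
logits and a softmax. The affine weights start at zero, so training
starts from uniform stage probabilities.

## Loss

The objective is `L = λ_seg·L_seg + λ_cls·L_cls` with trainable task
weights. `L_seg` is the unweighted sum of a soft Jaccard loss
(smoothing ε = 1) and a focal loss (γ = 2, α = 0.25, probability clamp
1e-7); `L_cls` is cross-entropy on the 4 stage probabilities. The
weights are parameterised as λ = exp(−s) with trainable log-precisions
s initialised to 0 (so both weights start at 1) plus the regulariser
`s_seg + s_cls` — the homoscedastic-uncertainty scheme; the closed-form
optimum s\* = log L gives each task an effective weight inversely
proportional to its loss. Fixed weights (λ ≡ 1) are available by
config.

## Autodiff substrate

The networks, losses and trainer run on a small reverse-mode autodiff
engine written on numpy (`npcstage.nn`): broadcasted arithmetic,
batched matmul, stride-1 "same" 3D convolution (accumulated over kernel
offsets through BLAS matmuls), factor-2 pooling, nearest-neighbour
upsampling, trilinear resizing, a fused instance-norm op, and a
topological-sort backward pass. Analytic gradients are verified against
central finite differences in the test suite (1e-3 relative through the
full model in float64; 1e-6 for individual ops).

## Numerical choices that matter

- **Segmentation head bias init −2.** The sigmoid starts near the rare
  foreground rate (~12%), so early training is not spent un-learning a
  50% background prediction. Without it, short runs never clear the
  0.5 threshold.
- **Gradient routing at the mask edge.** The cross-entropy loss
  back-propagates gradients through the mask-multiply edge that are
  orders of magnitude larger than the Jaccard gradients on the shared
  weights (measured ~2000× at initialisation); in short runs this
  freezes segmentation learning entirely. The backward pass through the
  probability-map factor is therefore attenuated by
  `cross_grad_scale = 0.05` (forward untouched, path still
  differentiable). The feature taps are *not* attenuated — their
  gradients are well-scaled, and they carry the cross-task feature
  shaping that distinguishes joint from separate training.
- **Zero-initialised classifier head** avoids large, confidently-wrong
  initial logits whose gradients destabilise the shared trunk.
- **Optimiser.** Adam; desk-scale default lr 1e-2 with a 3× multiplier
  on staging-only parameters (the staging pathway sees fewer useful
  gradients until segmentation stabilises). The clinical-scale protocol
  (batch 4, lr 2e-4, ReduceLROnPlateau, stop at lr < 1e-9 or 300
  epochs) is the `TrainConfig` default stop rule; desk runs simply hit
  the epoch cap. Scheduler: factor 0.2, patience 10, monitored on
  validation total loss.
- **Checkpoint selection**: best validation total loss.

## Phantom generator (the study conditions)

Real cohorts for this task are private, so the generator reproduces the
*statistical structure* the model must exploit rather than MR physics:

- Grid 16×64×64 voxels at (6.0, 0.5, 0.5) mm — the fine-in-plane /
  coarse-between-slices anisotropy of axial head MR, at desk scale.
- Nested ellipsoidal shells in physical coordinates: core cavity
  (label 1) and three successively deeper bands (2–4), jittered per
  seed. Band radii at fractions (0.34, 0.46, 0.60, 0.74) of the head
  half-extent.
- Tumors grow from a random core voxel by randomized accretion ordered
  by jittered physical distance, 6-connected, to an exact target
  volume — connected, roughly mm-spherical blobs with irregular
  boundaries despite the coarse slice spacing.
- Stage = deepest band holding ≥ 5% of tumor voxels (or 1 if none).
  Stage labels are drawn first from the mixture (0.08, 0.44, 0.27,
  0.21) — the imbalance of a representative 320-case clinical cohort —
  and growth is retried until the realized invasion depth matches, so
  labels are exactly recomputable from the emitted masks.
- Per-stage target-volume ranges (30–80, 90–220, 400–1100, 1600–3200
  voxels) were calibrated once against the shell geometry so each
  stage is realizable with acceptance probability ≳ 40%, and so mean
  volume rises strictly with stage.
- Image = shell baseline + low-frequency Gaussian texture (amplitude
  0.3) + tumor contrast (1.0) + smooth additive bias field (0.2) +
  voxel noise (σ = 0.15). Intensities are arbitrary units; the
  clinical cohort's intensity distributions are uncharacterised, so
  these are free parameters, not claims about MRI.

What the phantoms deliberately omit: Rician noise physics, multi-
sequence contrast, anatomical realism, observer variability in the
reference masks. Passing benchmarks on phantoms therefore demonstrates
that the architecture, losses, training loop and evaluation stack are
correct and that the multi-task mechanism can be exercised end to end —
not that clinical-grade accuracy is reached.

## Preprocessing

Resample to a target spacing (third-order spline in-plane, nearest
neighbour along slices; masks nearest-neighbour on all axes, so they
stay strictly binary), z-score normalise (after resampling, before
cropping — configurable), and centre-crop/zero-pad to a fixed grid.
The crop is centred on the mask centroid when a mask is available
(training), else on the volume centre. The target spacing defaults to
the per-axis median of the cohort when a manifest is given.

Desk-scale training uses target spacing (6, 1, 1) mm and grid
12×24×24: the slice axis is *not* resampled, because nearest-neighbour
slice decimation destroys thin tumors (a 2× slice thinning empties
20–30% of small masks), while in-plane 2× coarsening preserves them.

## Cross-validation and ablations

Stage-stratified k-fold (k = 3) splitting with per-stage fold counts
differing by at most one. Cohort metrics are pooled *out-of-fold*
predictions — every case scored exactly once by a model that never saw
it. Three training modes run under identical data, splits, seeds and
total epoch budgets:

- `full` — joint end-to-end training with attention fusion;
- `wo_ffa` — joint training, fusion by plain concatenation;
- `separate` — the segmentation network is trained alone for half the
  budget, frozen (enforced bit-exactly), then the staging network is
  trained on its masked output and detached taps for the other half.

The shipped benchmark (`npcstage.experiments.multitask_benchmark`)
runs all three modes on 100-case cohorts over 5 seeds, 6 epochs per
run, and compares median pooled staging AUC (micro-average
one-vs-rest). Problem sizes — the 12×24×24 training grid, the tiny
channel widths and the 6-epoch budget — were chosen once so the full
benchmark completes in a fraction of an hour on a single CPU core.

## Metrics and statistics

- DSC = 2|A∩G|/(|A|+|G|); defined as 1 when both masks are empty, 0
  when exactly one is.
- ASD: symmetric average surface distance in mm. Surface voxels are
  mask voxels with a face-adjacent background voxel (6-connectivity);
  distances use the exact Euclidean distance transform under the
  recorded anisotropic spacing; the two directed means are averaged.
  Undefined (and excluded from aggregates) when either mask is empty.
- Cohort summaries: median, IQR (interpolated quartiles), bootstrap CI
  of the median (seeded, 10,000 resamples by default).
- ACC with exact Clopper–Pearson (beta-quantile) CIs; SEN/SPE as
  macro-averaged one-vs-rest recall/TNR over the four stages (the
  single-number reduction for a 4-class problem is otherwise
  underdetermined; macro is documented and fixed here).
- ROC-AUC one-vs-rest, micro (flattened indicator/score pairs) and
  macro (unweighted mean of per-stage AUCs), mid-rank tie handling.
- Tests: Pearson chi-square without continuity correction (this
  convention exactly reproduces published cross-cohort p-values from
  printed counts); Mann–Whitney U (exact when min n ≤ 8 and untied,
  tie-corrected normal otherwise); Wilcoxon signed-rank (zeros
  dropped; exact for n ≤ 25 untied, else normal, no continuity
  correction); McNemar (exact binomial under 25 discordant pairs, else
  continuity-corrected chi-square); DeLong's test for correlated AUCs
  via structural components, applied to the micro-average one-vs-rest
  construction in the 4-class setting.

## Known limitations

- The engine is CPU-bound; clinical-scale grids (21×224×224) forward
  fine but are not practical to train here.
- Uncertainty weighting adapts λ's on loss scale only; it does not
  correct the cross-task gradient-magnitude mismatch (handled by the
  mask-edge attenuation instead).
- At desk budgets the separate-training ablation is a strong baseline
  (its staging phase sees a clean, frozen segmentation from epoch
  one); the joint model's advantage emerges but with modest margins,
  so mode comparisons are reported as medians over seeds.
- One published fixture family (the 2×2 sex-distribution comparisons
  involving the third cohort) is not reproducible from its printed
  counts under Pearson, Yates-corrected, or Fisher conventions; those
  cells are excluded from the fixture suite.
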