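# npcstage

Joint **gross-tumor-volume (GTV) segmentation** and **T-stage
prediction** for nasopharyngeal-carcinoma-like 3D MR volumes, as a
single multi-task network — plus everything needed to exercise it
end-to-end without clinical data: a synthetic phantom generator, the
preprocessing chain, segmentation/classification metrics, and the
statistical test battery used to compare models and cohorts.

## The problem and the model

Delineating the primary tumor and assigning its T-stage (T1–T4, the
local-invasion-depth component of TNM staging) are two halves of one
clinical judgement: both depend on how far the tumor extends into
surrounding structures. `npcstage` couples the two tasks:

- a U-shaped 3D segmentation network (8 encoder / 7 decoder units,
  instance norm, anisotropy-aware pooling) produces a voxelwise tumor
  probability map p̂ through a 1×1×1 convolution and sigmoid;
- the map multiplies the input volume, and the product feeds a 4-stage
  residual **bottleneck-transformer** backbone whose final three blocks
  use multi-head self-attention (4 heads, logits q·kᵀ + q·posᵀ with a
  factorised learned position encoding);
- a **feature-fusion-aware module** projects the three bottom-of-U
  segmentation feature maps, resizes them to the backbone grid,
  concatenates them with the backbone features and fuses them with a
  residual self-attention block;
- a classifier (global average pool → affine → softmax) outputs the
  four stage probabilities ŷ.

Both tasks are trained together with

  L = λ_seg·L_seg(p, p̂) + λ_cls·L_cls(y, ŷ),

where L_seg is soft-Jaccard + focal loss, L_cls is cross-entropy, and
the task weights λ = exp(−s) have trainable log-precisions s
(initialised so both weights start at 1). Everything runs on a small
numpy reverse-mode autodiff engine shipped in `npcstage.nn`, so the
package has no deep-learning-framework dependency.

Because the clinical cohorts for this problem are private, the
`phantoms` module generates anisotropic head phantoms — a bright
connected tumor grown inside nested anatomical shells, with the stage
label defined as the deepest shell band the tumor invades — so that
segmentation and staging are *jointly* learnable at desk scale and
every claim in the test suite is reproducible from a seed.

## Worked example

`examples/` holds one short narrative script per capability
(generation, preprocessing, training + prediction, segmentation
metrics, statistics). For instance:

```sh
$ python examples/statistics_report.py
-- cohort comparability from printed counts --
sex, cohort1 vs cohort2:      chi2=0.373, p=0.541
T-stage, cohort1 vs cohort3:  chi2=0.292, p=0.962
staging accuracy 225/320 = 0.70 (95% CI 0.65, 0.75)

-- paired model comparisons on simulated predictions --
DeLong AUC difference:  z=+2.74, p=0.0061
McNemar accuracy diff:  p=0.1378
Wilcoxon per-case error: W=5609, p=0.0000
```

The chi-square lines say the cross-validation cohorts are
exchangeable in sex and stage composition (p ≫ 0.05); the
Clopper–Pearson line turns a 225-of-320 staging accuracy into an exact
binomial interval; the paired tests detect that a model with less
score noise ranks cases significantly better (DeLong) and has smaller
per-case errors (Wilcoxon) than a noisier one evaluated on the same
cases, while the accuracy difference is not yet significant (McNemar).

Training end to end on phantoms:

```sh
$ python examples/train_and_stage.py
epoch 0: train loss 2.306, val DSC 0.000, val staging acc 0.250
epoch 1: train loss 2.763, val DSC 0.000, val staging acc 0.500
epoch 2: train loss 2.056, val DSC 0.000, val staging acc 0.500
epoch 3: train loss 1.920, val DSC 0.532, val staging acc 0.500
epoch 4: train loss 1.918, val DSC 0.654, val staging acc 0.500
epoch 5: train loss 3.008, val DSC 0.635, val staging acc 0.500

held-out case case_0001: true stage T4
  stage probabilities: {'T1': 0.034, 'T2': 0.542, 'T3': 0.289, 'T4': 0.134}
  predicted mask: 279 voxels, DSC vs truth 0.625
```

Validation Dice breaks through once the segmentation head escapes the
rare-foreground regime (epoch 3) and staging accuracy doubles over
chance (0.25) within a few epochs; the 100-case benchmarks in
`scripts/acceptance.py` train the same protocol longer and reach
median out-of-fold DSC around 0.9.

A command-line interface mirrors the library for shell use:
`npcstage generate`, `npcstage train`, `npcstage cv`,
`npcstage predict` (see `npcstage --help`).

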