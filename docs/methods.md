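# Methods

## Model

The segmenter is a two-class (background/brain) encoder–decoder applied to
2D slices. Encoder: five blocks, each two (3×3 conv, stride 1, zero
padding 1 → batch norm → ReLU) stages, with 2×2 max pooling after blocks
1–4 only, so the grid shrinks by 16× to the bottleneck (256×256 → 16×16 at
the default grid) while channels grow 3 → 16 → 32 → 64 → 128 → 256. The
stated channel endpoints (3 in, 256 at the bottleneck, 2 out) fix only the
ends of the schedule; doubling per level is the conventional completion,
and widths are configurable. Decoder: four blocks of 2×2 stride-2
transposed convolution → ReLU, each output concatenated with the
same-resolution encoder feature map; decoder blocks contain no
normalization and no further plain convolutions; a final 1×1 convolution
maps to the two-class scores. Pixels are classified by softmax foreground
probability > 0.5, with exact ties resolved to background.

The ResTLU variant replaces the leading convolution of each *encoder*
block with a pre-activation residual unit x ↦ f(x) + shortcut(x), where
f = BN → ReLU → conv(cin→cout) → BN → ReLU → conv(cout→cout) and the
shortcut is the identity for matching widths, else a 1×1 projection
(ResNet option B — an identity mapping is undefined across channel
widths). The block then applies its two plain conv stages, a
three-transform composition per block. Decoder blocks contain only a
transposed convolution, so there is no leading convolution to wrap on that
side. Whether the residual unit should span one or two convolutions is
genuinely open; the two-convolution transform written above is implemented
because that is the general residual form the architecture is described
with.

Loss: mean binary cross-entropy of the softmax foreground probability
against the binary mask, probabilities clamped to [1e-7, 1−1e-7].
Optimizer: Adam, lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8, batch size 8. The
network, its backward passes (im2col convolutions, batch-norm and pooling
gradients) and Adam are implemented directly in NumPy (float32) and run on
CPU; gradient correctness is checked against central differences in the
test suite.

## Slice pipeline

Slices are taken along a configurable axis (default: third array axis,
treated as axial; the orientation used in practice is a per-run choice
recorded in the run config). Each slice is resampled to the square network
grid — bilinear for intensities, nearest-neighbor for masks so the value
set {0,1} is preserved — then standardized per slice to mean 0, population
variance 1 (slices with variance below 1e-12 map to zeros). Normalization
is per-slice, not per-volume, because the operation lives inside the
resampling layer that processes one slice at a time. The 3 input channels
default to three copies of the slice (`replicate`); an `adjacent` 2.5D
policy (slices k−1, k, k+1 with edge replication) is available, since what
the three channels should carry is not fixed by the architecture.
Predictions are resampled back to the original in-plane shape by
nearest-neighbor and re-stacked, so the output mask always has exactly the
input volume's dimensions. No denoising, bias correction or registration
is performed anywhere; affines are carried through untouched.

## Training protocol

Stage one (pretraining, default 10 epochs) uses the paired-modality source
cohort: each subject's T1w and T2w volumes enter as independent samples
against the shared mask. The alternative wiring — modalities stacked as
input channels — is not the default because it would change the 3-channel
input contract; separate samples keep it intact. Stage two (fine-tuning,
default 40 epochs) updates all layers; no freezing is supported on
purpose. After every epoch the model is evaluated by mean volume-level
Dice over the validation subjects using the full extraction pipeline
(slice → resample → normalize → forward → decode → restore); the
checkpoint with the highest validation Dice is the stage's result —
volume-level rather than slice-level because reported performance is per
subject. Epoch shuffling is seeded per epoch from (config seed, epoch), so
fixed seed + fixed data reproduces a run exactly, and resuming from a
mid-training checkpoint (weights, batch-norm statistics, Adam moments,
epoch counter) reproduces the remaining trajectory exactly. One caveat:
when resuming, best-checkpoint selection can only compare against the
resumed state itself, so if the overall-best epoch predates the checkpoint
the uninterrupted and resumed runs return different "best" states even
though their trajectories agree.

## Evaluation

Per subject, predicted and true masks are tallied into TP/FP/TN/FN and the
eight metrics evaluated from that one confusion matrix. FNR and FPR
deliberately use the Jaccard denominator FN+TP+FP — not the conventional
FN/(FN+TP), FP/(FP+TN) — so the identities VOE = 1 − Jaccard and
Jaccard + FNR + FPR = 1 hold exactly; the conventional rates are exposed
as `fnr_conventional`/`fpr_conventional` to avoid silent confusion.
Degenerate denominators take the perfect-agreement reading: empty truth
and empty prediction score 1 on overlap metrics and 0 on error rates;
empty truth with a nonempty prediction scores TPR = PPV = 0. Cohort
summaries average per-subject metrics (equal subject weight) and report
the sample (n−1) standard deviation; the mean of per-subject Dice is not
the Dice of pooled voxels when subjects differ in size, and per-subject
averaging is the reading consistent with mean ± std reporting (pooled
aggregation is available via `ConfusionCounts` addition).

Split planning is subject-level and seeded. k-fold: shuffled subjects are
partitioned into near-equal test folds; each fold's remaining pool splits
into train and validation (default validation fraction 0.2, at least one
subject). Site holdout: whole acquisition sites are sampled out; every
subject of a held-out site is test, so no site contributes to both sides.

## Phantom generator

Each phantom is a geometric head on a voxel grid: brain ellipsoid, skull
shell and fat layer (concentric ellipsoidal shells), and two eye spheres
anterior to the brain. One label field renders two modalities from
per-tissue class means — T1-like (fat brightest, fluid dark) and T2-like
(fluid brightest) — each multiplied by a smooth seeded bias field
(Gaussian-filtered white noise standardized and scaled to mean 1 ±
amplitude, correlation length in voxels) and degraded with additive
Gaussian noise. Gaussian rather than Rician noise is used for simplicity;
no pulse-sequence or relaxometry physics is modeled. A low-amplitude
smooth texture inside the brain prevents the segmentation task from
degenerating to constant-region thresholding. The ground-truth mask is
exactly the brain-class voxel set, so pipeline errors are attributable to
the model, never the labels.

Default desk-scale volumes are 64×64×48. The source ("human-like") cohort
has a large round brain, thin skull and small eyes; the target
("macaque-like") cohort has a smaller elongated brain (≈40% of the source
brain volume), thicker skull and fat, larger eyes, a shifted contrast
profile, and stronger site-to-site scatter: sites differ in volume
dimensions, global contrast scale (±12%), noise SD (0.015–0.035), bias
amplitude (0.05–0.15) and a field-strength tag. Per-subject anatomy is
jittered ±10% in size with small center shifts. What the phantoms do *not*
emulate — partial-volume boundaries, gyral folding, susceptibility and
motion artifacts, genuinely multimodal intensity histograms — bounds what
passing tests show: they validate the pipeline, training dynamics and
site-generalization machinery, not clinical-grade accuracy on real MRI.

## Desk-scale study conditions

The self-contained study the tests and `scripts/acceptance.py` run uses
grid 64 with encoder widths (8, 16, 32, 48, 64), a 2-site × 3-subject
paired source cohort (4 train / 2 validation), and a 6-site × 2-subject
64³ target cohort with 2 sites held out (8 train / 2 validation / 4 test);
training uses every second slice. Pretraining keeps its 10 epochs;
fine-tuning runs 12 epochs, a scaled-down stand-in for the full 40 chosen
to match the smaller problem, where validation Dice plateaus well before
that. Under these conditions the fine-tuned ResTLU model reaches mean Dice
≈ 0.96–0.97 on subjects from sites never seen in training, and
fine-tuning from the pretrained checkpoint reaches validation Dice 0.85 at
least as fast as random initialization in the majority of seeds — the
direction, not the magnitude, of the transfer effect is the claim tested.

## Numerical notes and limitations

- float32 everywhere in the network; losses accumulated in float64.
- Batch-norm inference uses running statistics (momentum 0.1, eps 1e-5).
- Nearest-neighbor restoration can shift mask boundaries by up to one
  voxel at strong downsampling ratios; the disk round-trip test bounds the
  effect (Dice ≥ 0.95 for a 2× cycle).
- Checkpoints are NumPy `.npz` archives with a JSON metadata record;
  reloads are bit-exact, and identical seeds give byte-identical masks in
  serial CPU runs.
- Masks read with values outside {0,1} are binarized at 0.5 with a
  warning; grids must be divisible by 16.
- 3D context is ignored by design (2D slicing keeps memory and compute
  small); volumetric variants are out of scope.
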