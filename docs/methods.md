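# Methods

## Problem setting

Fetal ultrasound examinations select *standard planes* (SPs) — protocol-
defined sectional views such as the trans-ventricular brain plane or the
abdominal circumference plane — from which biometric measurements are
taken.  Automating SP recognition is a multi-class image classification
problem with two practical constraints: ultrasound images have low
contrast, speckle noise and high intra-class variability, and the target
deployment platform (a portable scanner) restricts the classifier to a
small, fully convolutional network.

`sonodistill` implements a knowledge-distillation (KD) pipeline for this
setting: a large, well-performing *teacher* network transfers its
knowledge to a compact *student* through a combined loss on the output
logits and on intermediate feature maps.

## The distillation objective

The student minimises

```
L        = L_KD + β · L_FMD
L_KD     = λ · L_SL + (1 − λ) · L_logits
L_SL     = H(softmax(a_s), y_r)
L_logits = τ² · KL( softmax(a_t/τ) ‖ softmax(a_s/τ) )
L_FMD    = Σ_i MSE_i                    (i over associated tap pairs)
```

with `a_s`, `a_t` the student/teacher logits (here always the
global-average-pooled pre-softmax K-channel outputs), `y_r` the ground
truth, `H` the cross-entropy, and `τ ≥ 1` the softening temperature.  The
KL divergence takes the teacher distribution as its first (target)
argument, so the gradient drives the student towards the teacher; the
teacher receives no gradient anywhere.  The `τ²` factor keeps the logit
term's gradient magnitude roughly temperature-independent; for zero-mean
logits `τ²·KL → ‖a_t − a_s‖²/(2K)` as `τ → ∞` (checked numerically in the
test suite at τ = 10³ and 10⁴).

Degenerate cases are exact, not approximate: `β = 0` recovers pure logit
distillation (BasicKD), and `β = 0, λ = 1` is ordinary supervised
training — the test suite asserts trajectory-level bit-identity between
`distill` and `train` in that configuration.

### Feature association and alignment

Feature distillation uses a *hand-crafted* association between rectified
convolution outputs ("taps") of teacher and student.  With `m` rectified
convolutions at 1-based depths `1..m`:

* 2 tiers: first and last;
* 3 tiers (default): first, median `(1+m)//2`, last;
* 4 tiers: additionally the midpoint of the second half, `(median+1+m)//2`.

For each associated pair, both maps are adaptive-average-pooled to the
element-wise minimum of their spatial sizes, and the student map is passed
through a trainable projection — a 1×1, 3×3, 1×1 convolution stack with
ReLU between the convolutions, output width equal to the teacher tap's
channel count, middle width equal to the output width.  Projections train
jointly with the student and are discarded at inference.

Two numerical choices matter here and were open design points:

* **MSE is the per-element mean**, not the sum.  This makes the β grid
  comparable across tap sizes and tier counts; with summed MSE the
  effective feature weight would scale with map size.
* **The projection's final convolution is zero-initialised.**  The
  projected student map then starts at zero, so at the beginning of
  training the feature loss is constant with respect to the student and
  only the projections receive gradient; the student starts feeling the
  feature term once the projections have adapted to the teacher's feature
  scale.  Without this, the randomly initialised projections inject large
  early gradients into the student's pre-logit layers (whose target maps
  are much larger in magnitude than the unit-scale inputs) and training
  degrades sharply.  This is the same device as zero-initialising
  residual branches.

The teacher is evaluated on the same augmented batch as the student
(online distillation) rather than on pre-computed clean-image outputs:
this is the simplest reading of a joint teacher/student forward pass and
keeps the two networks' inputs identical.

## Architectures

Two fully convolutional families are built natively (plus a VGG16
classification head as the classical-CNN teacher).  Internals are pinned
by requiring exact agreement with the published per-model "total
parameters" under a fixed accounting convention: convolution/dense weight
entries + bias entries + 4 stored entries per batch-norm channel (scale,
shift, running mean, running variance).

* **SmallNet** (base width C): conv 7×7→C, pool, conv 5×5→2C, pool,
  conv 3×3→4C, conv 3×3→4C, conv 1×1→2C, conv 1×1→K, global average
  pool.  All convolutions biased; ReLU after all but the last; no batch
  norm.  C = 32 gives 282,950 parameters, C = 16 gives 71,334.
* **SonoNet** (base width C): thirteen 3×3 convolutions in five
  max-pooled blocks of widths (C,C | 2C,2C | 4C,4C,4C | 8C,8C,8C |
  8C,8C,8C), every convolution biased + batch-normalised + rectified,
  then a 1×1 adaptation convolution to 4C (BN, ReLU) and a 1×1
  convolution to K (BN), global average pool.  No fully connected layer.
  C ∈ {8, 16, 32, 64} gives 234,966 / 933,646 / 3,722,238 / 14,864,350
  parameters.
* **VGG16 head**: the 13-convolution VGG16 extractor (3-channel input,
  no batch norm), global average pool, one dense 512→K layer; 14,717,766
  parameters at K = 6.

Each count is verified in the tests against an independent closed-form
per-layer accounting (Σ k²·c_in·c_out + c_out, + 4·c_out per BN).
Students take 1-channel input; the VGG16 teacher takes replicated
grayscale.  Networks are fully convolutional, so counts are independent
of resolution; the default working resolution is 224×288 and every
resolution ≥ the pooling depth works (the desk experiments use 32×32).
External model-zoo teachers (DenseNet and friends) are out of scope; any
object exposing logits and ordered rectified-conv taps can be plugged in
as a teacher.

## The numerical layer library

No deep-learning framework is a dependency: the package ships a small
numpy layer library (`sonodistill.nn`) with explicit forward/backward
passes for convolution ('same' padding, stride 1, shift-and-add
contraction), batch normalisation, ReLU, 2×2 max pooling, adaptive and
global average pooling, dense layers, and Adam (with the optional
exponential schedule multiplying learning rate and weight decay by 0.9
every 100 steps).  Every backward pass is validated against central
finite differences in the test suite, including gradient injection at
feature taps.  All computation is float64, single-threaded, and
deterministic given the seeds, which makes run-to-run reproducibility a
testable contract rather than a hope.

## Training protocol

* **Validation split**: 10% of the training set, class-stratified and
  patient-disjoint (whole patients move to the validation side; a class
  with fewer than two patients falls back to image-level stratification
  with a warning).  Patient-disjointness prevents leakage between frames
  of one subject.
* **Model selection**: the checkpoint with maximal validation accuracy
  (VA), ties to the earliest epoch.  Balanced accuracies (VAB on
  validation, TAB on test) are reported, never optimised.  Balanced
  accuracy is the mean per-class recall — the mean of the diagonal of the
  row-normalised confusion matrix; classes with no evaluated samples are
  excluded with a warning.
* **Recipes**: students use Adam, fixed learning rate 1e-3, batch 16.
  Teachers use Adam with the exponential schedule (initial weight decay
  5e-5).  Default epoch budget 50 with early-stop patience 10 on VA; the
  desk benchmark uses 30 epochs without early stopping so baseline and
  distilled runs see identical budgets.
* **Augmentation** (training split only, applied after normalising to
  [0,1]): horizontal and vertical flips with probability 0.5 each, gamma
  correction with γ ∈ [0.3, 1.7] (emulating gain settings), zoom with
  factor ∈ [0.8, 1.2] (canvas size preserved: crop on zoom-in, edge-pad
  on zoom-out), rotation ∈ [−10°, +10°], bilinear resampling, output
  clamped to [0,1].  Normalisation precedes gamma because a power law on
  un-normalised intensities is ill-posed.
* **Grid search**: λ ∈ {0.1,…,0.9}, τ ∈ {1,…,10},
  β ∈ {1, 5, 10, 100, 200, 400, 800}, weight decay ∈ {5e-5, 5e-6, 1e-5,
  1e-6, 1e-7, 1e-8}, learning rate ∈ {0.01, 0.001, 1e-4, 5e-5} — 15,120
  configurations in full factorial.  Because that is infeasible at desk
  scale, a seeded uniform-without-replacement sampler with a configurable
  budget is the default (full enumeration remains available); selection
  is by VA with ties to the first point in deterministic enumeration
  order, and the full report table is persisted.

## Synthetic data generator

The generator emulates the statistical structure the method assumes
without modelling ultrasound physics.  Six analytic class templates echo
the benchmark's plane classes — ring (brain), ellipse with two interior
blobs (abdomen), bright oblique bar (femur), periodic vertical bands
(thorax), bright wedge (cervix), random clutter (other) — rendered inside
a fan-shaped scan mask, multiplied by unit-mean Rayleigh speckle (lightly
Gaussian-smoothed, σ = 0.7 px, for realistic granularity), scaled by a
per-image gain drawn from [0.7, 1.3], and clipped to [0,1].  Patients
share a geometric jitter (position/scale/orientation perturbation, scale
0.08), so frames group naturally; train/test splits are patient-disjoint
by construction.

Defaults: 6 classes × 150 images (100 train / 50 test) at 32×32, 15
patients per class (10 frames per patient) — chosen so that a
patient-disjoint 10% validation split is exactly one patient per class.
What the generator does *not* emulate: beamforming and point-spread
anisotropy, attenuation shadows, calipers and annotations, operator
variability beyond affine jitter, and the extreme "Other" class
heterogeneity of real data.  Passing the packaged benchmark therefore
shows the pipeline's machinery works end-to-end and that the distillation
signal is beneficial under controlled conditions; it does not certify
clinical performance.

## The packaged benchmark

`sonodistill.experiments.synthetic_kd_benchmark` trains a width-4
SmallNet teacher on the default synthetic dataset (600 train / 300 test,
32×32), then for each of five training seeds trains a width-2 SmallNet
student from scratch and distils the same initialisation from the
teacher, comparing mean balanced test accuracies.  The demo distillation
configuration (λ = 0.3, τ = 8, β = 200, 3 tiers, lr = 0.01, weight decay
1e-8) was fixed once by the package's own seeded budget-12 grid search on
validation accuracy and is not tuned per run.  Baseline students keep the
fixed student recipe (Adam, lr 1e-3): the protocol trains baselines with
a fixed recipe but searches the distillation hyperparameters including
the optimiser settings, so part of the distilled student's advantage is
that the soft teacher targets and feature hints stabilise the more
aggressive learning rate the grid selected.  Problem sizes
(30 epochs, width-2/4 networks, 32×32 images) were chosen so the whole
benchmark completes in a few minutes on one CPU core.

## Known limitations

* The hand-written numpy layers are orders of magnitude slower than a
  GPU framework; the package targets method development and desk-scale
  validation, not full-benchmark training (the data loader supports the
  public benchmark layout, but training at that scale is out of scope).
* Batch-norm statistics make distillation results depend on batch
  composition; determinism holds only for fixed seeds and batch sizes.
* With aggressive feature weights (β ≳ 10 on these small BN-free
  students) the feature term can dominate and degrade accuracy; the grid
  search is the intended mechanism for choosing β, mirroring the
  observation that small students tolerate only a few associated layers.
* The adaptive-pooling alignment assumes teacher and student maps are
  spatially commensurate (same pooling depth ordering); wildly different
  downsampling schedules would pool most of one map away.
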