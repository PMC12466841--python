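# Methods

## Problem

Colloidal-gold immunoassay (CGIA) test cards report veterinary antibiotic
residues through two chromogenic bands in a membrane window: a control line
(C) that validates the test and a detection line (T) that, in this
competitive format, *disappears* when analyte is present.  The line
elimination rule therefore reads (C ✓, T ✗) as **positive**, (C ✓, T ✓) as
**negative**, and any card without a control line as **invalid**.  A tray
holds up to 48 strips, 16 single-window cards, or 10 triple-window cards;
the task is to locate every color-development window on a tray photograph
and classify it, i.e. two-class object detection (negative / positive) with
implicit background.

## Detector

VetStar is a deliberately small anchor-free detector for this fixed-geometry
task.  The backbone is a stride-2 stem (3→8 channels) and four stages, each
a transition convolution plus one StarBlock, with widths 12→24→32→32.  The
stride schedule is 2-2-2-2-1: three stages downsample, the last refines at
stride 16, so the single detection grid (C4) has pitch 16 px.  Because trays
present near-constant object scale, no feature pyramid or multi-scale head
is used.

**StarBlock.**  Each block is depthwise 3×3 → two parallel biased 1×1
projections multiplied element-wise → ReLU6 → 1×1 fusion → depthwise 3×3,
with a residual connection.  The element-wise product of two linear maps of
the bias-augmented feature f′ = (f, 1) expands to
Σᵢ Σⱼ m1ᵢ m2ⱼ f′ᵢ f′ⱼ — about (d+2)(d+1)/2 ≈ d²/2 distinct monomials — so
the block reaches a high-dimensional nonlinear feature space without wide
layers.  The expansion factor of the projections is 2.

**DR-head.**  A partially coupled head at C4: a shared stack of one
depthwise 3×3 convolution (with batch-norm; 352 trainable scalars) and one
reparameterizable convolution ("Rep-Conv"), followed by separate 1×1
classification (2 sigmoid logits) and box-regression (4×16 offset-bin
logits) convolutions.  The Rep-Conv trains as parallel 3×3+BN and 1×1+BN
branches (10,368 scalars) and is merged for inference by folding each
batch-norm into its branch, zero-padding the 1×1 kernel into the 3×3
centre, and summing — a single biased 3×3 convolution (9,248 scalars) with
forward outputs equal to the training form within 1e-5 in single precision.

**Budget.**  The merged reference model has 43,010 trainable parameters
(0.04 M) and 0.33 GFLOPs at 640×640 input under the
multiply-add-counts-as-two convention 2·Cin/g·Cout·K²·H·W summed over
convolutions.  The stem/stage widths and expansion factor were chosen to
meet those two budgets simultaneously; widening stage 1 to 16 channels
already exceeds both.

## Training

Boxes are regressed as discrete offset distributions (DFL): each edge
distance (in stride units, 16 bins) is a softmax whose expectation is the
offset.  Targets are assigned on the C4 grid by task alignment:
candidate cells have centers inside a ground-truth box (boxes smaller than
the grid pitch fall back to the nearest cell), the alignment metric
score^0.5 · IoU^6 selects the top 10 cells per box, and conflicts go to the
best-aligned box.  Soft classification targets are the per-box-normalized
alignment.  The loss is 0.5·BCE + 7.5·(1−CIoU) + 1.5·DFL; an image with no
objects contributes only background BCE.  Optimization is Adam with cosine
decay and early stopping on validation mAP50; batch size 8; everything is
seeded.  Inference decodes the expectation of the offset distributions,
thresholds independent per-class sigmoid scores, and applies per-class
greedy NMS at IoU 0.7.  For average-precision computation detections are
decoded at a 0.05 confidence floor (AP integrates over the ranking);
operating-point metrics (precision/recall, confusion matrix, reports) use
the 0.5 threshold.

## BCKD distillation

Softmax-based logit matching normalizes class scores to sum to one, so a
student whose logits are an affine copy of the teacher's looks "done" and
stops learning — precisely the failure mode for faint T-lines, where
absolute confidence gaps carry the signal.  BCKD maps each class logit
through an independent sigmoid and treats the N×K score map as N·K binary
tasks: the classification term is Σ β·BCE(s′_s, s′_t) with
β = |s′_t − s′_s| (stop-gradient), and the localization term is
Σ max_j(β)·(1 − IoU(o_s, o_t)) between the decoded boxes of the two models
at the same grid position, computed densely over all positions.  The two
terms are combined with a fixed localization:classification ratio of 15:1,
and the total objective is λ·L_dis + L_gt with λ = 1.3.  Because the
equations are plain sums over positions, the trainer divides each term by
the number of grid positions before weighting, so λ and the 15:1 ratio act
on a per-position scale commensurate with the supervised loss.  The teacher
is a width-multiplied (4×) member of the same family with the identical
single C4 head (same grid, classes and bins — required for positionwise
matching) and is frozen throughout.

**Teacher construction.**  Rather than training the wide teacher from
scratch, the package widens a trained student function-preservingly
(every channel replicated 4×, fan-in weights divided by 4 — exact through
the channelwise star products and batch-norm), perturbs weights by 2%
relative noise to break the replication symmetry, and fine-tunes briefly at
a low learning rate.  This yields a teacher at least as strong as the
student at a small fraction of the from-scratch cost, which is what the
distillation protocol needs.

## Synthetic trays

Real tray photographs are not distributable, so the generator renders
parametric stand-ins: white tray background, near-white card housings on a
jittered grid (jitter clamped to the free space per cell so cards never
collide), membrane windows with C and T bands whose intensity maps to the
saturation of a wine-red colloidal-gold color, a mild horizontal
illumination gradient, and Gaussian pixel noise.  A band is *visible* when
its intensity is ≥ τ = 0.15.  Classes follow the line-elimination rule
applied to the generating intensities, so label consistency is exhaustively
checkable from the manifest; invalid windows are only generatable behind an
off-by-default flag and never enter training data.  Default rates: 17%
positive windows (the share in the real data), 15% of negatives with a
faint T in [τ, τ+0.1] (the hard cases), defaults otherwise: 1944 px images
at full tray occupancy (48/16/10 cards), uniform jitter ≤ 8 px.  Datasets
split 6:2:2 per layout kind, so all three kinds appear in every split.

What the generator does **not** emulate: perspective and lens distortion,
specular reflections, card-housing texture and printing, smear or partial
wetting of the membrane, and real intensity distributions (the shared data
report no such statistics; rates here are stipulated).  Passing tests
therefore demonstrate that the pipeline is correct and trainable, not field
accuracy on real trays.

## Benchmarks and problem sizes

Two profiles of the "easy" benchmark ship with the package:
`easy_benchmark_config` (512 px, full occupancy, 240/80/80 images) as the
reference desk-scale configuration, and `small_benchmark_config` (256 px,
occupancy scaled with resolution: 12 strips / 6 cards / 4 triple cards per
tray, 36/12/12 images) which the test-suite trains on.  The small profile's
training schedule (240 epochs × 5 batches = 1200 steps, learning rate 2e-3)
matches the step budget of 40 epochs on the reference profile; the
supervised reference run reaches validation mAP50 ≈ 0.98.

Two training profiles accompany the small benchmark, and the distinction
matters.  `small_train_config` is the plain recipe (no warmup, no weight
averaging): it attains the highest absolute validation mAP50 and is used
wherever a single model is trained.  `comparison_train_config` exists for
paired A/B experiments such as the distillation regression: short runs on a
12-image validation split are dominated by checkpoint-selection noise (the
best-on-val checkpoint is the maximum of a noisy trajectory, and a single
lucky spike can swing a 60-epoch run's headline number by ±0.1), so the
comparison profile adds a 3-epoch learning-rate warmup and evaluates an
exponential moving average of the weights (decay 0.99, ramped as
1 − e^(−t/100)), which smooths the evaluated trajectory.  Both arms of a
comparison must use it identically; the distillation regression compares
paired 60-epoch runs (same seed, same data, with and without the BCKD term)
over three seeds against a no-harm margin of 0.01.

## Numerical choices

* All tensors are float32; the network stack (reverse-mode autodiff,
  im2col convolutions with a depthwise fast path, fused batch-norm) is part
  of the package and gradient-checked against central differences.
* BCE from logits uses the stable max(x,0) − x·t + log(1+exp(−|x|)) form;
  distillation scores are clamped to (1e-7, 1−1e-7) before logarithms.
* CIoU's aspect-ratio trade-off weight is treated as a constant during
  backpropagation (standard practice); degenerate boxes get IoU 0.
* AP uses COCO-style 101-point interpolation; classes absent from the
  ground truth are excluded from means with a warning; empty-denominator
  rates are 0, not NaN.
* Accuracy is defined as the ground-truth-count-weighted mean of class
  recalls, since true negatives are ill-defined in detection.
* The classification bias is initialized to −4 so the background-dominated
  BCE starts near its floor.
* The general-purpose `TrainConfig` defaults to the warmup + EMA recipe;
  the benchmark profiles override it as described above.
* Ties in row clustering for tray reports use half the median box height as
  the row tolerance.

## Limitations

* The NumPy stack is single-threaded BLAS-bound; the package targets
  desk-scale experiments, not GPU-scale training.
* mAP50-95 is systematically below mAP50 here (as in the source task, fine
  localization is not the goal).
* The invalid class is interpretable via `interpret_lines` but never
  modelled by the detector.
* ONNX export and embedded-device latency are out of scope; the latency
  helper measures wall-clock inference of any callable and is reported for
  information only.
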