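# Methods

This note documents the models, objectives, numerical choices and known
limitations of `laaseg`, in the order the pipeline runs them.

## 1. Problem setting

Given a grayscale TEE frame x ∈ [0,1]^{H×W} and a binary mask g of the
left atrial appendage (LAA) cavity, the task is pixel-level segmentation
under three difficulties: speckle noise, low tissue/cavity contrast, and
strong anatomical variability between patients (lobes, neck width,
curvature). The central idea is to distill anatomical plausibility — a
*shape prior* — from the masks themselves into a latent code, and to pull
the image encoder's latent toward that code during training, so that the
decoder receives globally plausible shape information rather than relying
only on local echo intensities.

## 2. Networks

**Encoder (shared family).** ConvNeXt layout: a 4×4 stride-4 stem with
channel layer normalization, four stages of residual blocks (depthwise 7×7
convolution → LN → 1×1 convolution to 4·dim → GELU → 1×1 convolution back
to dim → residual add), and LN + 2×2 stride-2 downsamplers between stages.
No batch normalization anywhere in the encoder. For input side L the
bottleneck latent has shape (dims[3], L/32, L/32). Default widths follow
the ConvNeXt-Tiny convention (96, 192, 384, 768) with depths (3, 3, 9, 3);
both are configurable, and the desk-scale configuration used by the tests
is (16, 32, 64, 128) with depths (1, 1, 2, 1) at 64×64 input.

**Segmentation decoder.** Three stages of (bilinear ×2 upsample →
concatenate the encoder skip → residual block with two 3×3 convolutions,
LN and GELU), then a final bilinear ×4 upsample and a 1×1 head to C = 2
class logits at full resolution.

**Mask auto-encoder.** The same encoder (1 input channel) and the same
decoder *without* skip connections — without skips the decoder can only
read the bottleneck, which forces the latent to carry the whole shape.
The reconstruction head is a 1-channel 1×1 convolution followed by
`clip(·, 0, 1)` with a straight-through gradient at the rails (§5).

**Discriminator.** Five 3×3 stride-1 convolutions, each followed by
LeakyReLU(0.2) and batch normalization, then a single fully connected
layer to one raw score. Channel widths taper from the latent width c as
[c, c/2, c/4, c/8, c/8] (minimum 8). The least-squares objective acts on
the raw score; no squashing. Because of the batch-norm layers the
discriminator is only used with training batches ≥ 2.

**Initialization.** Trunk convolutions and linears use the ConvNeXt
convention, truncated normal with σ = 0.02 (clipped at ±2σ); decoder
residual blocks, output heads and the discriminator use He-normal. The
tiny trunk initialization pairs with the pervasive LN — activations stay
well-scaled while parameter updates are large *relative to the weights* —
which matters for the short training schedules used here; the He-scaled
heads make output amplitude available from the start. The segmentation
head's biases start at the empirical foreground log-odds of the training
masks (class-prior initialization), so early steps are spent on shape, not
on finding the base rate.

**Input standardization.** Both networks map inputs to [−1, 1]
(x ↦ 2x − 1) before the stem. This is not cosmetic: binary masks and
sector-masked images contain exact-zero regions, and a stem whose biases
are zero then hands the stem LN a zero-variance vector — a point where the
LN forward is discontinuously sensitive and its backward is amplified by
1/√eps. Standardizing makes the background a nonzero constant whose stem
response varies across channels, restoring smoothness.

## 3. Objectives

With p the softmax output and g the one-hot ground truth:

* Cross-entropy, averaged over pixels. Soft Dice on the foreground softmax
  channel, 1 − (2Σpg + ε)/(Σp² + Σg² + ε) with ε = 10⁻⁶ (the ratio makes
  normalization unnecessary). Segmentation loss = λ_CE·CE + λ_Dice·Dice,
  both weights 1.
* Reconstruction: mean per-pixel L1 between the clipped reconstruction and
  the mask.
* Least-squares adversarial game on latents: the discriminator minimizes
  ½·mean((D(k) − 1)²) + ½·mean(D(G(x))²) with k the frozen mask-encoder
  latents ("real") and G(x) the image latents ("fake"); the generator
  minimizes ½·mean((D(G(x)) − 1)²).
* InfoNCE on pooled latents: each latent map is global-average-pooled and
  L2-normalized; for query qᵢ the positive key is its own mask's kᵢ and the
  denominator sums over all B in-batch keys, temperature τ = 0.1, computed
  with a max-shifted log-sum-exp. Batch size must be ≥ 2 (otherwise there
  are no negatives). The generator's total objective is
  L_seg + λ_GAN·L_GAN + λ_CL·L_CL with λ_GAN = λ_CL = 1 and an implicit
  weight of 1 between the segmentation and alignment parts.

Sum-versus-mean aggregation over pixels is a free constant under Adam's
per-parameter normalization; means are used so reported magnitudes are
resolution-independent.

## 4. Training procedure

Stage 1 trains the mask auto-encoder alone (Adam, lr 10⁻⁴, β₁ = 0.9,
β₂ = 0.999, polynomial decay lr·(1 − t/T)^0.9, batch 8, ±10° rotation
augmentation applied to the masks). Stage 2 freezes it — its parameters
are bit-identical before and after — and trains the segmentation network
and discriminator with one D step then one G step per batch, same
optimizer settings. Real latents are recomputed from the augmented
ground-truth masks every step so augmentation applies consistently to both
paths; for the D step, real and fake latents are concatenated into one
forward pass (shared batch-norm statistics). Augmentation rotates image
and mask by the same angle, bilinear for the image and nearest-neighbor
for the mask (which therefore stays exactly binary). A checkpoint is kept
at the best validation Dice (evaluated every `eval_interval` steps); the
returned network carries those weights. Non-finite losses abort with a
diagnostic rather than continuing.

Setting λ_GAN = λ_CL = 0 skips the alignment machinery entirely and the
per-step segmentation losses become bit-identical to
`train_segmentation_baseline`, a separate plain CE+Dice trainer with no
alignment code — the ablation configuration. Determinism: all randomness
in a run derives from one seed via independent `SeedSequence` children
(network init, discriminator init, batch order, augmentation), so
identical configurations reproduce identical loss curves bit for bit, and
the baseline consumes the same streams as the full trainer.

**Patient-level split.** Whole patients are assigned to train/val/test so
that image counts approximate 4:1:1: exhaustive minimization of the
absolute count deviation for ≤ 9 patients (ties broken uniformly by the
rng), greedy largest-first placement into the most-deficient split
otherwise. Each split always receives at least one patient; no patient
ever spans splits.

## 5. The reconstruction head: why clipped-linear, not sigmoid

LAA masks are heavily class-imbalanced (~5 % foreground at desk scale).
Under per-pixel L1 with a *sigmoid* output, training reliably collapses to
the empty prediction: the 95 % background majority drags the whole logit
map downward, the sigmoid saturates, and its vanishing derivative then
suppresses the foreground pull and the background pull symmetrically —
the map freezes at "all empty" (held-out Dice 0.0 even with 8× the step
budget, at any learning rate). A binary-cross-entropy control trains fine
(its foreground gradient does not vanish), isolating the
sigmoid-saturation dynamics, not the architecture, as the cause. The head
therefore uses r = clip(z, 0, 1) with a straight-through gradient at the
rails: updates that would move a railed output back inside the interval
pass through; all others are blocked. Pixels already at their target rail
go silent instead of dragging shared parameters deeper into saturation,
while the unsatisfied minority keeps its full gradient. The training loss
is still exactly mean |g − r| on the [0,1]-valued output. With this head
the same budget reaches held-out L1 ≈ 0.023 and thresholded Dice ≈ 0.85.

## 6. Synthetic TEE cohort

The generator emulates the *structure* of a clinical TEE LAA cohort, not
its physics. Per patient, one base shape is drawn — an elliptical body
(semi-axes 0.14–0.22 and 0.45–0.68 of that, relative to image side), 1–4
accessory lobes on the distal boundary, a neck channel of width 0.15–0.4
of the body diameter, a curvature term bending the whole shape, a small
low-frequency boundary wobble — and each frame jitters every field by
≤ 10 %. Rendering places the cavity (intensity 0.15) in a tissue field
(0.6) inside a 75° sector wedge, multiplies unit-mean Gamma speckle with
dispersion 0.3, blurs with a 1-px Gaussian point-spread function, and
zeroes everything outside the sector. Thrombus patients (23/41 of the
cohort, the clinical prevalence) get a bright blob (0.85) strictly inside
the cavity. Every output is a pure function of (parameters, seed); masks
round-trip through 8-bit PNG exactly; foreground prevalence stays within
[1 %, 25 %] per frame.

What this does **not** emulate: real speckle statistics and spatial
correlation, shadowing and reverberation artifacts, probe-angle
variability, annotation noise, and true anatomical shape distributions.
Passing tests therefore demonstrate that the pipeline's machinery —
objectives, gradients, alignment, split discipline, metrics — behaves as
specified on data with the right structure; they are not evidence of
clinical-grade accuracy.

## 7. Desk-scale results and their honest limits

All training-quality checks run the scaled configuration (64×64, widths
(16, 32, 64, 128), depths (1, 1, 2, 1), 300 steps per stage, batch 8 —
sizes chosen so the whole suite runs on one CPU in minutes). Two
observations from these runs are worth stating plainly:

* The mask auto-encoder reaches held-out L1 ≈ 0.02–0.04 easily, but the
  Dice of its *thresholded* reconstruction saturates around 0.85: with a
  2×2×128 bottleneck, no skips, and a final ×4-upsampled 1×1 head, 1–2 px
  necks and lobe boundaries are at the representational limit at 64×64.
* The end-to-end test Dice on held-out patients lands near 0.80–0.90
  depending on the seed, and the benefit of the alignment terms over the
  plain CE+Dice ablation is seed-dependent at this scale (alignment wins
  at some seeds, loses at others). 300 steps is enough for the alignment
  cosine to rise markedly — the validation-set median cos(q, k₊)
  increases monotonically from step 0 — but not always enough for that
  better-aligned latent to pay off in boundary accuracy. The clinical
  claim that alignment helps is a statement about a far larger cohort and
  training budget; the desk-scale runs verify the mechanism, not the
  effect size.

## 8. Numerical and convention details

* Arrays are channels-first float32 in training; gradient-check tests cast
  to float64. Convolutions are lowered to GEMMs via patch extraction;
  depthwise convolutions run as kernel-footprint shift-accumulate loops.
* Bilinear upsampling uses half-pixel-center interpolation matrices; its
  backward is the exact transpose.
* Coordinates are row-major, origin top-left, 0-based. Masks on disk are
  8-bit PNG {0, 255} with 255 = foreground; manifests are CSV with header
  `image_path,mask_path,patient_id,thrombus,split` and paths relative to
  the manifest file.
* Metric conventions: prediction threshold 0.5; empty-ground-truth cases —
  Dice/IoU are 1.0 when the prediction is also empty, else 0.0; κ at
  p_e = 1 is 1.0 for a perfect prediction, else 0.0; AUC on a
  single-class ground truth is recorded as NaN with a warning and excluded
  from aggregation. AUC uses midrank tie handling (equal to the
  trapezoidal area over distinct thresholds). Aggregate spread is the
  population (n-divisor) standard deviation over test images; metrics are
  always computed per image, never pooled over the dataset.
* "Momentum 0.9" with Adam is read as β₁ = 0.9. The decaying schedule is
  polynomial with power 0.9; both are configurable.
* The degenerate all-zero latent pools to the zero vector with a warning
  (its cosine is undefined); it cannot occur after the first optimizer
  step in practice.

## 9. Known limitations

2-D only; no pretrained weights; the numpy stack is single-threaded apart
from BLAS, so full-size (448×448) training is impractical — the full-size
configuration is exercised for architecture contracts and inference only.
The synthetic generator's realism bounds what the test results can claim
(§6, §7). Discriminator batch normalization ties its statistics to the
training batch composition; inference-mode scoring uses running statistics
and is deterministic.
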