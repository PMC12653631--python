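# Methods

`latatk` implements a lesion-area-constrained adversarial attack on
medical image classifiers.  A trained generator G emits a perturbation
field for an input image x; the field is scaled to an L∞ budget ε,
restricted to a binary lesion mask M, and added to x:

    x_adv = x ⊙ M̄  +  clip_{x,ε}( x + ε·G(x) ⊙ M )

Pixels outside the mask are preserved bit-exactly and
‖x_adv − x‖_∞ ≤ ε by construction (the Tanh head of G bounds the raw
field to [−1, 1]; ε-scaling plus clamping then satisfies both the
amplitude and the ball constraint constructively).  G is trained against
a frozen surrogate classifier F by Adam on

    L = −L_adv − λ_CAM·L_CAM + λ_LBP·L_LBP,     λ_CAM = 1, λ_LBP = 0.5,

so that minimising L *maximises* the surrogate's cross-entropy L_adv and
the disruption of its Grad-CAM attention L_CAM while *minimising* the
local-binary-pattern texture change L_LBP.  At inference the attack is a
single generator forward pass per image — no per-sample iteration.

## Loss terms

**Adversarial term.**  L_adv = CE(F(x_adv), y) with y the true label and
the cross-entropy taken on pre-softmax logits.

**Class-activation term.**  Grad-CAM at a chosen convolutional layer:
channel weights are the spatial means of ∂l_y/∂A (l_y the pre-softmax
logit of the true class, A the layer activations); the map is the
rectified channel-weighted sum of A at the layer's native resolution,
without min-max normalisation.  L_CAM is the mean of squared differences
between the maps of x (a detached reference) and x_adv.  Because the map
already contains one gradient, training through it requires second-order
derivatives; the bundled autodiff engine (below) supports this.

**Texture term.**  The LBP code of an interior pixel is the 8-bit number
whose bit q is set iff neighbour q (clockwise from top-left) is ≥ the
centre; codes are grayscale-shift invariant (BT.601 luma is used for the
grayscale).  The hard code has zero gradient almost everywhere, so
training uses a soft relaxation in which the step becomes
logistic(Δ/temperature); temperature defaults to 0.1 on the [0,1]
intensity scale, converging elementwise to the hard code as T→0 wherever
no neighbour-centre difference is exactly zero.  Hard codes are used for
all reporting, and a straight-through estimator (hard forward values,
soft backward gradient) is available as a third mode.  Both squared
norms (CAM and LBP) reduce by the mean over cells — scale-stable across
image and layer sizes; a sum mode exists.

## Networks

All networks run on a package-authored reverse-mode autodiff engine over
NumPy (`latatk/_autodiff.py`).  Every primitive's backward rule is
itself built from the same primitives, so gradients are differentiable
again — which is exactly what the CAM loss needs.  Convolutions are
fused einsum primitives over zero-copy sliding-window views; arrays are
float32 by default (numerical-oracle tests switch to float64 via a
context manager).  Adam follows the classical formulation with L2 decay
folded into the gradient.

- **Generator** (`generator`): encoder–decoder, 3×3 convs + ReLU, 2×2
  max-pool down / 2×2 transposed-conv up, skip connections concatenating
  encoder features into the decoder, 1×1 conv + Tanh head.  Default
  depth 3 and base width 4, sized for 64-px fixtures (bottleneck 8×8).
  The head is zero-initialised so the untrained generator emits a zero
  field: training starts from the clean image instead of from random
  texture the LBP term must first undo.  The generator consumes the
  *classifier-view* image (the surrogate's per-channel input
  normalisation, frozen onto G at training time), which makes the
  class-dependent sign of the useful perturbation directly visible in
  its input; composition and clipping happen in raw [0,1] space.
- **Segmenter** (`segmentation`): standard U-Net (two 3×3 conv + ReLU
  per stage, 4 down / 4 up, skip connections, sigmoid head), trained
  with Dice loss, binarised at 0.5.  Masks may instead be loaded from
  {0,255} PNG files; the engine accepts either source.
- **Tiny classifiers** (`fixtures`): two fixed architectures — A with
  conv widths (8,16,32), B with (6,12,24,48) — each a stack of
  conv-ReLU-pool blocks with global average pooling and a linear head,
  exposing the last conv layer by name for Grad-CAM.  Trained classifiers
  carry their input normalisation (training-set per-channel mean/sd, the
  convention of pretrained-backbone pipelines).  The per-image
  normalisation variant of the input transform is available in the
  engine (`per_channel_normalize`) and in `AttackConfig.norm_stats`.
  Training augments each image with a random constant intensity shift
  of the pixels *outside* the lesion mask (uniform ±0.1).  The class
  signal lives entirely inside the mask, so this teaches the model to
  decide from the lesion rather than from background brightness — the
  lesion-dominated attention that motivates a mask-restricted attack in
  the first place.  Without it these very small CNNs lean heavily on
  global intensity statistics, and the unmasked attack variant can
  succeed with near-invisible background nudges, which says more about
  the toy classifier than about the attack.

## Synthetic data

The fixture generator emulates dermoscopy-like data at desk scale:
64-px RGB images containing one rotated elliptical lesion (radius 8–16
px) with sinusoidal texture (8 cycles/image, amplitude 0.06) and a
2-px darkened rim, on a lower-frequency textured background (3
cycles/image), plus Gaussian pixel noise (sd 0.02) and 8-bit PNG
quantisation.  The class label is carried by the lesion's mean intensity:
levels are drawn from [0.30, 0.47] for class 0 and [0.53, 0.70] for
class 1 (threshold 0.5; the 0.03 margin, plus mean-compensation of the
texture and rim inside the mask, guarantees noise and quantisation can
never flip the rule label).  Labels are re-derived from the final image,
so the class signal lives entirely inside the mask — shuffling
background pixels cannot change a label.  Everything is a pure function
of (spec, seed, index).

What this does *not* emulate: multi-scale lesion morphology, hair and
ruler artefacts, camera vignetting, inter-class texture differences, or
the class structure of real dermoscopy/fundus collections.  Passing
tests therefore demonstrate the *mechanics* of the attack — mask-
restricted ε-bounded perturbation, CAM/texture loss behaviour,
white-box effectiveness above a noise baseline — not attack rates
transferable to clinical data.

## Desk-scale study conditions

The end-to-end run used by the acceptance suite: 400 fixture samples,
two classes, surrogate A and target B trained to ≥0.90 held-out
accuracy; generator trained 10 epochs at ε = 0.1 (the perturbation
ceiling used for attack evaluation; ε = 0.01 remains the config default)
with ground-truth masks; ASR and SSIM measured on the full set.
The attack-training learning rate for this run is 3e-3: Adam moves each
parameter ≈ lr per step, so saturating Tanh pre-activations (an O(1)
parameter displacement) within the 130 steps of a 10-epoch desk run
requires lr on the order of 1/130 ≈ 8e-3; 3e-3 is a conservative choice
of that scale.  The published 5e-5 remains the `AttackConfig` default —
it belongs to 50-epoch training on full-size datasets.

Evaluation: ASR = 100·|{i : F(x_i)=y_i and H(x_adv,i)≠y_i}|/N with N the
full adversarial set (the printed formula; the convention that divides
by the number of F-correct samples is available behind a flag).  SSIM
defaults to single global statistics per channel (c1 = 0.01², c2 = 0.03²
on the [0,1] scale), averaged over channels; the conventional 11×11
Gaussian-windowed mean-SSIM (via scikit-image) is the `windowed` option.
The Ensemble row of a transfer report averages the per-target fooling
indicators per sample before the ASR counting — algebraically equal to
the mean of the per-target ASRs.

## Numerical and design choices

- Both-empty Dice and IoU are defined as 1.0 (perfect agreement).
- Max-pool ties break toward the first window slot; ReLU and clipping
  use their almost-everywhere derivatives.
- `clip_to_ball` clamps into [x−ε, x+ε] ∩ [0,1]; the ε constraint is
  enforced as ≤ after clamping.
- Per-channel normalisation of a constant channel returns zeros via a
  stabiliser (1e-8 on the variance).
- LBP neighbour order is fixed (clockwise from top-left, bit q weighted
  2^q); any fixed order is valid since both maps in the texture loss use
  the same order.
- Masks are computed once per sample and cached during attack training
  (the segmentation input never changes).
- NaN in any loss component aborts training with the history retained.
- Checkpoints are single-file .npz archives with a JSON header carrying
  the config and input-transform statistics.

## Known limitations

- The CAM loss is scale-sensitive: with tiny classifiers the Grad-CAM
  magnitudes (and hence L_CAM) are orders of magnitude smaller than on
  ImageNet-scale backbones, so at λ_CAM = 1 the term contributes little
  at desk scale.
- The amortised generator underfits the white-box optimum at desk
  scale: per-sample masked PGD flips several times more samples than the
  10-epoch generator, so reported desk-scale ASRs measure the
  generator's conditional capacity as much as the classifier's
  robustness.
- Hard-LBP rotation invariance is not claimed: only grayscale-shift
  invariance holds for the basic 8-neighbour code.
- The segmenter is trained and validated on synthetic fixtures only.
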