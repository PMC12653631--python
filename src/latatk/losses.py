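"""Loss terms of the attack objective.

The composed training loss is

    L = -L_adv - λ_CAM · L_CAM + λ_LBP · L_LBP

minimised by gradient descent, which simultaneously *maximises* the
surrogate's classification loss (L_adv) and the disruption of its
Grad-CAM attention (L_CAM) while *minimising* the change in local-binary-
pattern texture (L_LBP).

Hard LBP codes are integer 8-bit patterns used for reporting; training
uses a logistic soft relaxation because the hard threshold has zero
gradient almost everywhere.  Squared norms are reduced by the MEAN over
cells (a "sum" mode exists), keeping scales comparable across image and
layer sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

#: BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

#: 8-neighbour offsets, clockwise from top-left; bit q carries weight 2^q
LBP_NEIGHBORS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


@dataclass
class LossWeights:
    lambda_cam: float = 1.0
    lambda_lbp: float = 0.5

    def __post_init__(self):
        if self.lambda_cam < 0 or self.lambda_lbp < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class SoftLBPConfig:
    """Differentiable LBP relaxation: the step s(Δ) becomes
    logistic(Δ/temperature); hard codes are recovered as temperature→0
    wherever no neighbour-centre difference is exactly zero."""

    temperature: float = 0.1    # on the [0,1] intensity scale

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


# ---------------------------------------------------------------------------
# grayscale and LBP
# ---------------------------------------------------------------------------

def to_grayscale(image):
    """BT.601 luma. Accepts (...,H,W,3) arrays (channels last) or NCHW
    Tensors; returns the same kind without the channel axis."""
    if isinstance(image, Tensor):
        if image.ndim != 4 or image.shape[1] != 3:
            raise ValueError("expected NCHW Tensor with 3 channels")
        w = _LUMA.reshape(1, 3, 1, 1)
        return ad.sum_op(ad.mul(image, w), axis=1)
    image = np.asarray(image, dtype=np.float64)
    if image.shape[-1] != 3:
        raise ValueError("expected channels-last RGB image")
    return image @ _LUMA


def _neighbor_slices(H: int, W: int):
    for q, (dy, dx) in enumerate(LBP_NEIGHBORS):
        yield q, (slice(1 + dy, H - 1 + dy), slice(1 + dx, W - 1 + dx))


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Hard 8-bit LBP codes on the interior grid: bit q is set iff the
    q-th neighbour is >= the centre (s(0)=1). (H,W) -> (H-2,W-2) ints."""
    gray = np.asarray(gray, dtype=np.float64)
    H, W = gray.shape[-2], gray.shape[-1]
    if H < 3 or W < 3:
        raise ValueError("image must be at least 3x3 for LBP")
    center = gray[..., 1:H - 1, 1:W - 1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for q, (sy, sx) in _neighbor_slices(H, W):
        codes += ((gray[..., sy, sx] - center) >= 0).astype(np.int64) << q
    return codes


def soft_lbp(gray, cfg: SoftLBPConfig = SoftLBPConfig()):
    """Soft LBP value map in [0, 255]; Tensor in -> Tensor out."""
    is_tensor = isinstance(gray, Tensor)
    g = gray if is_tensor else Tensor(np.asarray(gray, dtype=np.float64))
    H, W = g.shape[-2], g.shape[-1]
    if H < 3 or W < 3:
        raise ValueError("image must be at least 3x3 for LBP")
    center_idx = (Ellipsis, slice(1, H - 1), slice(1, W - 1))
    center = ad.getitem(g, center_idx)
    out = None
    for q, (sy, sx) in _neighbor_slices(H, W):
        delta = ad.add(ad.getitem(g, (Ellipsis, sy, sx)), ad.mul(center, -1.0))
        bit = ad.sigmoid(ad.mul(delta, 1.0 / cfg.temperature))
        term = ad.mul(bit, float(2 ** q))
        out = term if out is None else ad.add(out, term)
    return out if is_tensor else out.data


def ste_lbp(gray: Tensor, cfg: SoftLBPConfig = SoftLBPConfig()) -> Tensor:
    """Straight-through LBP: hard codes in the forward pass, the soft
    relaxation's gradient in the backward pass."""
    soft = soft_lbp(ad.as_tensor(gray), cfg)
    hard = lbp_codes(np.asarray(gray.data if isinstance(gray, Tensor) else gray))
    return ad.add(soft, Tensor(hard - soft.data))


def lbp_loss(x_adv, x, mode: str = "hard",
             cfg: SoftLBPConfig = SoftLBPConfig(), reduction: str = "mean"):
    """Squared difference of the LBP maps of the two grayscale images.

    `x_adv`/`x` are grayscale maps ((N,)H,W).  Hard mode takes/returns
    NumPy (reporting); "soft" (logistic relaxation) and "ste"
    (straight-through estimator) accept Tensors for training.
    """
    if mode == "hard":
        a = lbp_codes(np.asarray(x_adv.data if isinstance(x_adv, Tensor) else x_adv))
        b = lbp_codes(np.asarray(x.data if isinstance(x, Tensor) else x))
        if a.shape != b.shape:
            raise ValueError("grid mismatch")
        d = (a - b).astype(np.float64)
        return float((d ** 2).mean() if reduction == "mean" else (d ** 2).sum())
    if mode not in ("soft", "ste"):
        raise ValueError("mode must be 'hard', 'soft' or 'ste'")
    op = soft_lbp if mode == "soft" else ste_lbp
    a = op(ad.as_tensor(x_adv), cfg)
    b = op(ad.as_tensor(x), cfg)
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    diff = ad.add(a, ad.mul(b, -1.0))
    sq = ad.mul(diff, diff)
    return ad.mean_op(sq) if reduction == "mean" else ad.sum_op(sq)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam(model, x, labels, layer_name: str) -> Tensor:
    """Gradient-weighted class activation map at `layer_name`.

    Channel weights are the spatial means of ∂(logit of the true label)
    /∂(activation); the CAM is the rectified channel-weighted sum of the
    activations, at the layer's native resolution (no upsampling, no
    min-max normalisation).  The returned Tensor stays differentiable
    w.r.t. `x` (the gradient itself is a graph node), so CAM-based losses
    can be trained through.

    x: NCHW Tensor/array, already on the model's input scale;
    labels: (N,) ints. Returns (N, C_layer is reduced) -> (N, h_k, w_k).
    """
    x = ad.as_tensor(x)
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    logits = model(x)
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("label out of range")
    acts = model.activations.get(layer_name)
    if acts is None:
        raise KeyError(
            f"unknown layer {layer_name!r}; available: {sorted(model.activations)}")
    # Sum of per-sample true-label logits: activations of sample n only
    # influence logit n, so d(sum)/dA recovers per-sample gradients.
    l_y = ad.sum_op(ad.take_rows(logits, labels))
    (g,) = ad.grad(l_y, [acts])
    weights = ad.mean_op(g, axis=(2, 3), keepdims=True)      # a_k^c, (N,C,1,1)
    return ad.relu(ad.sum_op(ad.mul(weights, acts), axis=1))  # (N,h_k,w_k)


def cam_loss(model, x, x_adv, labels, layer_name: str,
             reduction: str = "mean") -> Tensor:
    """Squared difference between the CAMs of x and x_adv at the hooked
    layer.  The x-branch CAM is a detached reference; gradients flow only
    through the x_adv branch."""
    ref = gradcam(model, ad.as_tensor(x).detach(), labels, layer_name).detach()
    cam_adv = gradcam(model, ad.as_tensor(x_adv), labels, layer_name)
    diff = ad.add(cam_adv, ad.mul(ref, -1.0))
    sq = ad.mul(diff, diff)
    return ad.mean_op(sq) if reduction == "mean" else ad.sum_op(sq)


def adv_loss(model, x_adv, labels) -> Tensor:
    """Cross-entropy of the surrogate on the adversarial batch."""
    logits = model(ad.as_tensor(x_adv))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("label out of range")
    return ad.cross_entropy(logits, labels)


def total_loss(l_adv, l_cam, l_lbp, weights: LossWeights = LossWeights()):
    """L = -L_adv - λ_CAM·L_CAM + λ_LBP·L_LBP (minimised during training)."""
    for name, v in (("l_adv", l_adv), ("l_cam", l_cam), ("l_lbp", l_lbp)):
        data = v.data if isinstance(v, Tensor) else v
        if not np.all(np.isfinite(data)):
            raise FloatingPointError(f"{name} is not finite (training divergence)")
    t = ad.add(ad.mul(ad.as_tensor(l_adv), -1.0),
               ad.mul(ad.as_tensor(l_cam), -weights.lambda_cam))
    t = ad.add(t, ad.mul(ad.as_tensor(l_lbp), weights.lambda_lbp))
    return t if any(isinstance(v, Tensor) for v in (l_adv, l_cam, l_lbp)) else t.item()
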