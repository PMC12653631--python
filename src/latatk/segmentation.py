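"""Binary lesion masks: the U-Net segmenter that produces them, and the
mask algebra (complement, Hadamard masking, Dice/IoU) the attack relies on.

A mask is a plain (H, W) float array with values exactly {0, 1}; 1 marks
the attackable (lesion) region, 0 the protected complement.  Masks may
come from a trained segmenter or from ground-truth PNG files — the attack
engine accepts either source.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from . import fixtures
from ._autodiff import Tensor


@dataclass
class SegmenterConfig:
    depth: int = 4              # downsampling / upsampling stages
    base_channels: int = 4      # sized for the 64-px synthetic fixtures
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must be in (0,1)")


# ---------------------------------------------------------------------------
# mask algebra
# ---------------------------------------------------------------------------

def validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=np.float64)
    if not np.isin(mask, (0.0, 1.0)).all():
        raise ValueError("binary mask must contain only 0 and 1")
    return mask


def complement(mask: np.ndarray) -> np.ndarray:
    """Non-attackable mask: 1 - M, elementwise."""
    return 1.0 - validate_mask(mask)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Hadamard product; the mask broadcasts across trailing channels."""
    image = np.asarray(image, dtype=np.float64)
    mask = validate_mask(mask)
    if image.shape[: mask.ndim] != mask.shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match image {image.shape}")
    if image.ndim == mask.ndim + 1:
        return image * mask[..., None]
    return image * mask


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a∩b|/(|a|+|b|); both-empty defined as 1.0."""
    a, b = validate_mask(a), validate_mask(b)
    if a.shape != b.shape:
        raise ValueError("mask grids differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a * b).sum() / denom)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union; both-empty defined as 1.0."""
    a, b = validate_mask(a), validate_mask(b)
    if a.shape != b.shape:
        raise ValueError("mask grids differ")
    union = np.maximum(a, b).sum()
    if union == 0:
        return 1.0
    return float((a * b).sum() / union)


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

class _ConvBlock(ad.Module):
    """Two 3x3 conv + ReLU layers at a fixed resolution."""

    def __init__(self, cin, cout, rng):
        self.c1 = ad.Conv2d(cin, cout, k=3, pad=1, rng=rng)
        self.c2 = ad.Conv2d(cout, cout, k=3, pad=1, rng=rng)

    def __call__(self, x):
        return ad.relu(self.c2(ad.relu(self.c1(x))))


class UNet(ad.Module):
    """Symmetric encoder-decoder with skip connections at every resolution
    and a sigmoid head emitting an (N, H, W) lesion-probability map."""

    def __init__(self, config: SegmenterConfig, in_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        d, bc = config.depth, config.base_channels
        chans = [bc * 2 ** i for i in range(d + 1)]
        self.enc = [
            _ConvBlock(in_channels if i == 0 else chans[i - 1], chans[i], rng)
            for i in range(d)
        ]
        self.bottleneck = _ConvBlock(chans[d - 1], chans[d], rng)
        self.ups = [ad.ConvTranspose2x2(chans[i + 1], chans[i], rng) for i in reversed(range(d))]
        self.dec = [_ConvBlock(2 * chans[i], chans[i], rng) for i in reversed(range(d))]
        self.head = ad.Conv2d(chans[0], 1, k=1, pad=0, rng=rng)

    def _check_size(self, H, W):
        f = 2 ** self.config.depth
        if H % f or W % f:
            raise ValueError(
                f"input size {H}x{W} is not divisible by 2^depth = {f}; "
                "pad or resize the image, or lower the segmenter depth")

    def __call__(self, x) -> Tensor:
        t = ad.as_tensor(x)
        self._check_size(t.shape[2], t.shape[3])
        skips = []
        for block in self.enc:
            t = block(t)
            skips.append(t)
            t = ad.maxpool2x2(t)
        t = self.bottleneck(t)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            t = up(t)
            t = block(ad.concat([skip, t], axis=1))
        logits = self.head(t)                      # (N,1,H,W)
        prob = ad.sigmoid(logits)
        return ad.reshape(prob, (t.shape[0], t.shape[2], t.shape[3]))


def build_unet(config: SegmenterConfig | None = None, in_channels: int = 3,
               seed: int = 0) -> UNet:
    return UNet(config or SegmenterConfig(), in_channels=in_channels, seed=seed)


def soft_dice_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - soft Dice, averaged over the batch."""
    t = Tensor(np.asarray(target, dtype=np.float64))
    inter = ad.sum_op(ad.mul(prob, t), axis=(1, 2))
    sums = ad.add(ad.sum_op(prob, axis=(1, 2)), ad.sum_op(t, axis=(1, 2)))
    dice_coeff = ad.mul(ad.add(ad.mul(inter, 2.0), eps),
                        ad.pow_const(ad.add(sums, eps), -1.0))
    return ad.mean_op(ad.add(1.0, ad.mul(dice_coeff, -1.0)))


def predict_mask(segmenter: UNet, image: np.ndarray,
                 threshold: float | None = None) -> np.ndarray:
    """Probability map thresholded to a {0,1} mask. image: (H,W,3) in [0,1]."""
    thr = segmenter.config.binarize_threshold if threshold is None else threshold
    x = fixtures.to_nchw(np.asarray(image, dtype=np.float64))
    prob = segmenter(Tensor(x)).data[0]
    return (prob >= thr).astype(np.float64)


def train_segmenter(segmenter: UNet, manifest_dir_or_arrays, epochs: int,
                    seed: int, lr: float = 3e-3, batch_size: int = 8,
                    holdout_fraction: float = 0.25):
    """Train with Dice loss; returns (segmenter, held-out mean Dice).

    Dice is evaluated on binarized predictions at the configured threshold.
    """
    if isinstance(manifest_dir_or_arrays, (str, Path)):
        images, masks, _ = fixtures.load_manifest_arrays(manifest_dir_or_arrays)
    else:
        images, masks, _ = manifest_dir_or_arrays
    x = fixtures.to_nchw(images)
    masks = np.asarray(masks, dtype=np.float64)

    rng = np.random.default_rng(seed)
    n = len(x)
    perm = rng.permutation(n)
    n_test = max(1, int(round(holdout_fraction * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    opt = ad.Adam(segmenter.parameters(), lr=lr)
    for _ in range(epochs):
        order = rng.permutation(train_idx)
        for i in range(0, len(order), batch_size):
            b = order[i:i + batch_size]
            prob = segmenter(Tensor(x[b]))
            loss = soft_dice_loss(prob, masks[b])
            opt.step(ad.grad(loss, segmenter.parameters()))

    thr = segmenter.config.binarize_threshold
    scores = []
    for i in range(0, len(test_idx), batch_size):
        b = test_idx[i:i + batch_size]
        pred = (segmenter(Tensor(x[b])).data >= thr).astype(np.float64)
        scores.extend(dice(pred[j], masks[b][j]) for j in range(len(b)))
    return segmenter, float(np.mean(scores))
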