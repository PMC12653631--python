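"""Attack assembly and the generator training loop.

An adversarial sample is built as

    x_adv = x ⊙ M̄  +  clip(x + ε·G(x) ⊙ M)

i.e. original pixels outside the lesion mask, ε-scaled generator
perturbation added inside it, clamped into the intersection of the
ε-ball around x and the valid [0,1] range.  Pixels outside the mask are
preserved bit-exactly and ‖x_adv − x‖_∞ ≤ ε always holds.

The generator is trained against a *frozen* surrogate classifier by
Adam on the composed loss (see `losses`).  Masks come either from the
ground-truth mask files of the manifest or from a trained segmenter;
they depend only on x, so they are computed once and cached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autodiff as ad
from . import fixtures, losses, segmentation
from ._autodiff import Tensor
from .generator import Generator
from .losses import LossWeights, SoftLBPConfig


@dataclass
class AttackConfig:
    """Training/assembly parameters; defaults follow the published setup
    (Adam 5e-5 / weight decay 1e-5 / batch 32 / 50 epochs, ε = 0.01)."""

    epsilon: float = 0.01
    norm_order: str = "inf"
    learning_rate: float = 5e-5
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 50
    weights: LossWeights = field(default_factory=LossWeights)
    soft_lbp: SoftLBPConfig = field(default_factory=SoftLBPConfig)
    use_mask: bool = True      # off = "w/o Seg" ablation (perturb everywhere)
    use_lbp: bool = True       # off = "w/o LBP" ablation
    use_cam: bool = True
    normalize_per_channel: bool = True
    norm_stats: str = "model"  # "model": the surrogate's own input transform;
                               # "per_image": each image's channel statistics
    seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.norm_order != "inf":
            raise ValueError("only the infinity norm is supported")
        # the adversarial CE term is always active, so at least one loss
        # term is present for any flag combination

    def to_dict(self):
        return asdict(self)


@dataclass
class AdversarialSample:
    image: np.ndarray          # (H,W,3) floats in [0,1]
    source_index: int
    applied_mask: np.ndarray   # (H,W) in {0,1}


# ---------------------------------------------------------------------------
# assembly operations
# ---------------------------------------------------------------------------

def clip_to_ball(candidate: np.ndarray, source: np.ndarray,
                 epsilon: float) -> np.ndarray:
    """Elementwise clamp of candidate into [source-ε, source+ε] ∩ [0,1]."""
    candidate = np.asarray(candidate, dtype=np.float64)
    source = np.asarray(source, dtype=np.float64)
    if candidate.shape != source.shape:
        raise ValueError("candidate/source grids differ")
    lo = np.maximum(source - epsilon, 0.0)
    hi = np.minimum(source + epsilon, 1.0)
    return np.clip(candidate, lo, hi)


def compose_adversarial(x: np.ndarray, raw_pert: np.ndarray, mask: np.ndarray,
                        cfg: AttackConfig, source_index: int = 0) -> AdversarialSample:
    """η = ε·raw_pert ⊙ M; x_adv = clip(x + η) — all in channels-last NumPy.

    With use_mask off the mask is treated as all-ones (the "w/o Seg"
    ablation). Non-attackable pixels equal x bit-exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    raw_pert = np.asarray(raw_pert, dtype=np.float64)
    mask = segmentation.validate_mask(mask)
    if x.shape[:2] != mask.shape or raw_pert.shape != x.shape:
        raise ValueError("image/perturbation/mask grids differ")
    applied = np.ones_like(mask) if not cfg.use_mask else mask
    eta = cfg.epsilon * raw_pert * applied[..., None]
    adv = clip_to_ball(x + eta, x, cfg.epsilon)
    # clamping is the identity where eta == 0, so the complement region
    # is untouched; enforce bit-exactness against float round-off anyway
    adv = np.where(applied[..., None] == 0.0, x, adv)
    return AdversarialSample(image=adv, source_index=source_index,
                             applied_mask=applied)


def per_channel_normalize(image, eps: float = 1e-8):
    """Standardise each channel by the image's own statistics.

    Tensor NCHW in -> Tensor out (differentiable; used on the classifier
    input branch during training); arrays are handled channels-last.
    A constant channel maps to all-zeros via the stabiliser.
    """
    if isinstance(image, Tensor):
        mu = ad.mean_op(image, axis=(2, 3), keepdims=True)
        cent = ad.add(image, ad.mul(mu, -1.0))
        var = ad.mean_op(ad.mul(cent, cent), axis=(2, 3), keepdims=True)
        return ad.mul(cent, ad.pow_const(ad.add(var, eps), -0.5))
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:  # (H,W,C)
        mu = image.mean(axis=(0, 1), keepdims=True)
        var = image.var(axis=(0, 1), keepdims=True)
    else:                # (N,H,W,C): per-image statistics
        mu = image.mean(axis=(1, 2), keepdims=True)
        var = image.var(axis=(1, 2), keepdims=True)
    return (image - mu) / np.sqrt(var + eps)


def _surrogate_input(x_nchw: Tensor, surrogate, cfg: AttackConfig) -> Tensor:
    """Differentiable classifier-input transform for the attack loop."""
    if not cfg.normalize_per_channel:
        return x_nchw
    if cfg.norm_stats == "model" and getattr(surrogate, "norm_mode", None) == "dataset":
        scale = 1.0 / surrogate.input_std
        return ad.mul(ad.add(x_nchw, -surrogate.input_mean), scale)
    return per_channel_normalize(x_nchw)


def _set_generator_transform(G, surrogate, cfg: AttackConfig) -> None:
    """The generator consumes the classifier-view (normalised) image; the
    transform is frozen onto G at training time so crafting matches."""
    if not cfg.normalize_per_channel:
        G.input_transform = None
    elif (cfg.norm_stats == "model"
          and getattr(surrogate, "norm_mode", None) == "dataset"):
        G.input_transform = "dataset"
        G.input_mean = np.asarray(surrogate.input_mean, dtype=np.float64)
        G.input_std = np.asarray(surrogate.input_std, dtype=np.float64)
    else:
        G.input_transform = "per_image"


def generator_input_np(G, x_nchw: np.ndarray) -> np.ndarray:
    """Apply the input transform stored on a trained generator."""
    mode = getattr(G, "input_transform", None)
    if mode == "dataset":
        return (x_nchw - G.input_mean) / G.input_std
    if mode == "per_image":
        return fixtures.per_image_normalize_np(x_nchw)
    return x_nchw


# ---------------------------------------------------------------------------
# mask sources
# ---------------------------------------------------------------------------

def resolve_masks(mask_source, images: np.ndarray,
                  masks_from_manifest: np.ndarray | None) -> np.ndarray:
    """(N,H,W) {0,1} masks from a segmenter, a directory of mask PNGs,
    or the manifest's own ground-truth masks (mask_source=None)."""
    if mask_source is None:
        if masks_from_manifest is None:
            raise ValueError("no mask source available")
        return np.asarray(masks_from_manifest, dtype=np.float64)
    if isinstance(mask_source, segmentation.UNet):
        return np.stack([
            segmentation.predict_mask(mask_source, img) for img in images
        ])
    mask_dir = Path(mask_source)
    paths = sorted(mask_dir.glob("*.png"))
    if len(paths) != len(images):
        raise ValueError(
            f"mask directory {mask_dir} has {len(paths)} PNGs for {len(images)} images")
    return np.stack([fixtures.load_mask(p) for p in paths])


def _weights_digest(model: ad.Module) -> str:
    h = hashlib.sha256()
    for name, p in model.named_parameters():
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train_attack(G: Generator, surrogate, mask_source, manifest_dir_or_arrays,
                 cfg: AttackConfig):
    """Optimise the generator against the frozen surrogate.

    Per batch: mask -> raw perturbation -> ε-scaled masked composition ->
    per-channel normalisation -> L_adv / L_CAM (soft) / L_LBP (soft) ->
    composed loss -> Adam step on the generator parameters only.

    Returns (G, history DataFrame with per-step loss components).
    """
    if isinstance(manifest_dir_or_arrays, (str, Path)):
        images, gt_masks, labels = fixtures.load_manifest_arrays(manifest_dir_or_arrays)
    else:
        images, gt_masks, labels = manifest_dir_or_arrays
    if len(images) == 0:
        raise ValueError("empty manifest")

    masks = resolve_masks(mask_source, images, gt_masks)
    if not cfg.use_mask:
        masks = np.ones_like(masks)

    x_all = fixtures.to_nchw(images)             # (N,3,H,W)
    m_all = masks[:, None, :, :]                 # (N,1,H,W)
    layer = surrogate.last_conv_layer
    digest_before = _weights_digest(surrogate)
    _set_generator_transform(G, surrogate, cfg)
    g_in_all = generator_input_np(G, x_all)

    # per-sample reference quantities depend only on x: cache them
    cam_ref = None
    lbp_ref = None
    if cfg.use_cam or cfg.use_lbp:
        cam_chunks, lbp_chunks = [], []
        for i in range(0, len(x_all), cfg.batch_size):
            xb = Tensor(x_all[i:i + cfg.batch_size])
            if cfg.use_cam:
                inp = _surrogate_input(xb, surrogate, cfg)
                cam_chunks.append(
                    losses.gradcam(surrogate, inp, labels[i:i + cfg.batch_size],
                                   layer).data)
            if cfg.use_lbp:
                gray = losses.to_grayscale(xb)
                lbp_chunks.append(losses.soft_lbp(gray, cfg.soft_lbp).data)
        if cfg.use_cam:
            cam_ref = np.concatenate(cam_chunks)
        if cfg.use_lbp:
            lbp_ref = np.concatenate(lbp_chunks)

    rng = np.random.default_rng(cfg.seed)
    opt = ad.Adam(G.parameters(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    rows = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_all))
        for i in range(0, len(order), cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            x = Tensor(x_all[b])
            m = Tensor(m_all[b])
            pert = G(Tensor(g_in_all[b]))
            eta = ad.mul(ad.mul(pert, m), cfg.epsilon)
            lo = np.maximum(x_all[b] - cfg.epsilon, 0.0)
            hi = np.minimum(x_all[b] + cfg.epsilon, 1.0)
            x_adv = ad.clip_const(ad.add(x, eta), lo, hi)
            inp = _surrogate_input(x_adv, surrogate, cfg)

            l_adv = losses.adv_loss(surrogate, inp, labels[b])
            if cfg.use_cam:
                cam_adv = losses.gradcam(surrogate, inp, labels[b], layer)
                diff = ad.add(cam_adv, Tensor(-cam_ref[b]))
                l_cam = ad.mean_op(ad.mul(diff, diff))
            else:
                l_cam = Tensor(0.0)
            if cfg.use_lbp:
                soft = losses.soft_lbp(losses.to_grayscale(x_adv), cfg.soft_lbp)
                diff = ad.add(soft, Tensor(-lbp_ref[b]))
                l_lbp = ad.mean_op(ad.mul(diff, diff))
            else:
                l_lbp = Tensor(0.0)

            try:
                total = losses.total_loss(l_adv, l_cam, l_lbp, cfg.weights)
            except FloatingPointError as exc:
                err = RuntimeError(
                    f"attack training diverged at step {step}: {exc}")
                err.history = pd.DataFrame(rows)
                raise err from exc
            grads = ad.grad(total, G.parameters())
            opt.step(grads)
            row = {"step": step, "epoch": epoch, "l_adv": l_adv.item(),
                   "total": total.item()}
            if cfg.use_cam:
                row["l_cam"] = l_cam.item()
            if cfg.use_lbp:
                row["l_lbp"] = l_lbp.item()
            rows.append(row)
            step += 1

    if _weights_digest(surrogate) != digest_before:
        raise RuntimeError("surrogate weights changed during attack training")
    return G, pd.DataFrame(rows)


def write_history(history: pd.DataFrame, path) -> None:
    history.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# crafting
# ---------------------------------------------------------------------------

def craft(G: Generator, mask_source, manifest_dir_or_arrays, cfg: AttackConfig,
          out_dir=None) -> list[AdversarialSample]:
    """One AdversarialSample per manifest row; optionally written as PNGs
    with a JSON sidecar recording ε, mask source and seed."""
    if isinstance(manifest_dir_or_arrays, (str, Path)):
        images, gt_masks, labels = fixtures.load_manifest_arrays(manifest_dir_or_arrays)
    else:
        images, gt_masks, labels = manifest_dir_or_arrays
    masks = resolve_masks(mask_source, images, gt_masks)

    samples = []
    bs = cfg.batch_size
    for i in range(0, len(images), bs):
        x = generator_input_np(G, fixtures.to_nchw(images[i:i + bs]))
        pert = fixtures.to_nhwc(G(Tensor(x)).data)
        for j in range(len(pert)):
            samples.append(compose_adversarial(
                images[i + j], pert[j], masks[i + j], cfg, source_index=i + j))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            fixtures.save_image(out_dir / f"adv_{s.source_index:05d}.png", s.image)
        sidecar = {
            "epsilon": cfg.epsilon,
            "mask_source": ("ground_truth" if mask_source is None
                            else type(mask_source).__name__
                            if isinstance(mask_source, segmentation.UNet)
                            else str(mask_source)),
            "use_mask": cfg.use_mask,
            "seed": cfg.seed,
            "n_samples": len(samples),
        }
        (out_dir / "attack.json").write_text(json.dumps(sidecar, indent=2))
    return samples


def masked_uniform_noise_attack(images: np.ndarray, masks: np.ndarray,
                                cfg: AttackConfig, seed: int = 0) -> list[AdversarialSample]:
    """ε-matched baseline: i.i.d. uniform [-1,1] raw perturbation confined
    to the same mask and clipped to the same ball."""
    rng = np.random.default_rng(seed)
    out = []
    for i, (img, m) in enumerate(zip(images, masks)):
        raw = rng.uniform(-1.0, 1.0, size=img.shape)
        out.append(compose_adversarial(img, raw, m, cfg, source_index=i))
    return out
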