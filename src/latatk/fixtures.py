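"""Synthetic dermoscopy-like lesion datasets and tiny classifier models.

Every sample is a textured elliptical "lesion" blob on a lower-frequency
textured background, with a ground-truth binary lesion mask.  The class
label is carried by a lesion property (its mean intensity by default), so
the decision signal lives entirely inside the mask — mirroring the way
lesion areas dominate classifier decisions on real dermoscopy data.

All outputs are pure functions of (spec, seed, index), so datasets and
trained models are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import _autodiff as ad
from ._autodiff import Tensor

BY_MEAN_INTENSITY = "by_mean_intensity"
BY_TEXTURE_FREQ = "by_texture_freq"

#: margin (intensity units / cycles-per-image) kept clear of every class
#: boundary when drawing the class-carrying lesion property, so that
#: texture, pixel noise and 8-bit PNG quantization cannot flip the label
_CLASS_MARGIN_FRACTION = 0.15


@dataclass
class SyntheticSpec:
    """Generation parameters for the synthetic lesion dataset."""

    image_size: int = 64
    lesion_radius_range: tuple[int, int] = (8, 16)
    lesion_texture_freq: float = 8.0   # cycles per image
    background_texture_freq: float = 3.0
    noise_sd: float = 0.02             # on the [0,1] intensity scale
    n_classes: int = 2
    class_rule: str = BY_MEAN_INTENSITY
    seed: int = 0
    # intensity band the lesion mean level is drawn from
    intensity_range: tuple[float, float] = (0.30, 0.70)
    texture_amplitude: float = 0.06
    # darkened border band, as in pigmented-lesion dermoscopy; its intensity
    # deficit is mean-compensated inside the mask so it cannot move the
    # class-defining masked mean
    rim_depth: float = 0.12
    rim_width: int = 2

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.lesion_radius_range[1] >= self.image_size / 2:
            raise ValueError("max lesion radius must be < image_size/2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.class_rule not in (BY_MEAN_INTENSITY, BY_TEXTURE_FREQ):
            raise ValueError(f"unknown class_rule {self.class_rule!r}")

    @property
    def class_thresholds(self) -> np.ndarray:
        """Interior boundaries splitting the property range into classes."""
        lo, hi = self._property_range()
        return np.linspace(lo, hi, self.n_classes + 1)[1:-1]

    def _property_range(self) -> tuple[float, float]:
        if self.class_rule == BY_MEAN_INTENSITY:
            return self.intensity_range
        return (self.lesion_texture_freq * 0.5, self.lesion_texture_freq * 1.5)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        d["lesion_radius_range"] = tuple(d["lesion_radius_range"])
        d["intensity_range"] = tuple(d["intensity_range"])
        return cls(**d)


@dataclass
class LabeledSample:
    """One image with its binary lesion mask and integer class label."""

    image: np.ndarray   # (H, W, 3) floats in [0, 1]
    mask: np.ndarray    # (H, W) in {0, 1}
    label: int


def rule_label(spec: SyntheticSpec, prop_value: float) -> int:
    """Class index from the lesion property per the spec's class rule."""
    return int(np.digitize(prop_value, spec.class_thresholds))


def masked_mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean over channels of the pixels inside the mask."""
    return float(image[mask.astype(bool)].mean())


def _sinusoid(size: int, freq: float, theta: float, phase: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / size
    return np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)


def _draw_property(spec: SyntheticSpec, rng: np.random.Generator,
                   target_class: int) -> float:
    lo, hi = spec._property_range()
    edges = np.linspace(lo, hi, spec.n_classes + 1)
    band_lo, band_hi = edges[target_class], edges[target_class + 1]
    margin = (band_hi - band_lo) * _CLASS_MARGIN_FRACTION
    return float(rng.uniform(band_lo + margin, band_hi - margin))


def generate_lesion_sample(spec: SyntheticSpec, index: int) -> LabeledSample:
    """Deterministically generate sample `index` of the dataset.

    The intended class cycles through `index % n_classes` (which is what
    makes `generate_dataset` balanced); the emitted label is re-derived
    from the generated lesion property, and for the intensity rule it is
    additionally verified against the actual masked mean of the final
    noisy image.
    """
    S = spec.image_size
    target_class = index % spec.n_classes

    for attempt in range(8):
        rng = np.random.default_rng([spec.seed, index, attempt])

        # geometry: rotated ellipse roughly centred
        r_lo, r_hi = spec.lesion_radius_range
        ra, rb = rng.uniform(r_lo, r_hi, size=2)
        cx, cy = rng.uniform(0.35 * S, 0.65 * S, size=2)
        rot = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:S, 0:S]
        xr = (xx - cx) * np.cos(rot) + (yy - cy) * np.sin(rot)
        yr = -(xx - cx) * np.sin(rot) + (yy - cy) * np.cos(rot)
        mask = ((xr / ra) ** 2 + (yr / rb) ** 2 <= 1.0).astype(np.float64)
        if mask.sum() < 1:
            continue

        # class-carrying property
        if spec.class_rule == BY_MEAN_INTENSITY:
            lesion_level = _draw_property(spec, rng, target_class)
            lesion_freq = spec.lesion_texture_freq
        else:
            lesion_freq = _draw_property(spec, rng, target_class)
            lesion_level = rng.uniform(*spec.intensity_range)

        bg_level = rng.uniform(0.45, 0.60)
        bg = bg_level + spec.texture_amplitude * _sinusoid(
            S, spec.background_texture_freq, rng.uniform(0, np.pi),
            rng.uniform(0, 2 * np.pi))
        lesion_tex = spec.texture_amplitude * _sinusoid(
            S, lesion_freq, rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi))
        # zero-mean the texture inside the mask so it cannot move the
        # masked mean across a class boundary
        lesion_tex -= (lesion_tex * mask).sum() / mask.sum()
        structure = lesion_tex
        if spec.rim_depth > 0 and spec.rim_width > 0:
            from scipy.ndimage import binary_erosion
            interior = binary_erosion(mask.astype(bool),
                                      iterations=spec.rim_width)
            rim = mask.astype(bool) & ~interior
            rim_field = np.where(rim, -spec.rim_depth, 0.0)
            rim_field -= (rim_field * mask).sum() / mask.sum()
            structure = structure + rim_field
        base = bg * (1 - mask) + (lesion_level + structure) * mask

        img = base[:, :, None] + rng.normal(0, spec.noise_sd, size=(S, S, 3))
        img = np.clip(img, 0.0, 1.0)

        if spec.class_rule == BY_MEAN_INTENSITY:
            label = rule_label(spec, masked_mean_intensity(img, mask))
        else:
            label = rule_label(spec, lesion_freq)
        if label == target_class:
            return LabeledSample(image=img, mask=mask, label=label)

    raise RuntimeError(
        f"could not realise class {target_class} for sample {index}; "
        "spec margins too tight")


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def save_image(path, image: np.ndarray) -> None:
    """Write an (H,W,3) float [0,1] image as 8-bit RGB PNG."""
    arr = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64)
    return arr / 255.0


def save_mask(path, mask: np.ndarray) -> None:
    arr = (mask > 0.5).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def load_mask(path) -> np.ndarray:
    """Load a {0,255} single-channel mask PNG as a {0,1} float array."""
    arr = np.asarray(Image.open(path).convert("L"))
    bad = set(np.unique(arr)) - {0, 255}
    if bad:
        raise ValueError(f"mask {path} contains values other than 0/255: {sorted(bad)}")
    return (arr == 255).astype(np.float64)


def generate_dataset(spec: SyntheticSpec, n: int, out_dir) -> pd.DataFrame:
    """Write `n` samples (image/mask PNGs + CSV manifest + spec sidecar).

    Class counts in the manifest differ by at most one whenever n is a
    multiple of n_classes (labels cycle with the index).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        s = generate_lesion_sample(spec, i)
        img_rel = f"images/sample_{i:05d}.png"
        msk_rel = f"masks/sample_{i:05d}_mask.png"
        save_image(out_dir / img_rel, s.image)
        save_mask(out_dir / msk_rel, s.mask)
        rows.append({"filename": img_rel, "mask_filename": msk_rel,
                     "label": s.label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "spec.json").write_text(spec.to_json())
    return manifest


def load_manifest_arrays(manifest_dir):
    """Load a written dataset back as (images NHWC, masks NHW, labels)."""
    manifest_dir = Path(manifest_dir)
    manifest = pd.read_csv(manifest_dir / "manifest.csv")
    images = np.stack([load_image(manifest_dir / f) for f in manifest["filename"]])
    masks = np.stack([load_mask(manifest_dir / f) for f in manifest["mask_filename"]])
    labels = manifest["label"].to_numpy(dtype=np.int64)
    return images, masks, labels


def dataset_arrays(spec: SyntheticSpec, n: int):
    """In-memory dataset (no disk round trip): images NHWC, masks, labels."""
    samples = [generate_lesion_sample(spec, i) for i in range(n)]
    return (np.stack([s.image for s in samples]),
            np.stack([s.mask for s in samples]),
            np.array([s.label for s in samples], dtype=np.int64))


def to_nchw(images: np.ndarray) -> np.ndarray:
    """(N,H,W,3) or (H,W,3) -> NCHW batch."""
    if images.ndim == 3:
        images = images[None]
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2))


def to_nhwc(batch: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(batch.transpose(0, 2, 3, 1))


# ---------------------------------------------------------------------------
# tiny classifiers (structurally distinct surrogate/target pair)
# ---------------------------------------------------------------------------

class TinyConvNet(ad.Module):
    """conv3x3-ReLU-maxpool blocks, global average pool, linear head.

    The last conv layer is exposed by name for Grad-CAM hooks; the most
    recent forward pass's activations are kept in `activations`.
    """

    def __init__(self, widths, n_classes, in_channels=3, seed=0):
        rng = np.random.default_rng(seed)
        self.convs = []
        cin = in_channels
        for w in widths:
            self.convs.append(ad.Conv2d(cin, w, k=3, pad=1, rng=rng))
            cin = w
        self.head = ad.Linear(cin, n_classes, rng=rng)
        self.widths = tuple(widths)
        self.n_classes = n_classes
        self.activations: dict[str, Tensor] = {}

    @property
    def last_conv_layer(self) -> str:
        return f"conv{len(self.convs)}"

    def conv_layer_names(self):
        return [f"conv{i + 1}" for i in range(len(self.convs))]

    def __call__(self, x) -> Tensor:
        """x: NCHW Tensor or array -> (N, n_classes) logits."""
        t = ad.as_tensor(x)
        self.activations = {}
        for i, conv in enumerate(self.convs):
            t = ad.relu(conv(t))
            self.activations[f"conv{i + 1}"] = t
            t = ad.maxpool2x2(t)
        pooled = ad.mean_op(t, axis=(2, 3))          # global average pool
        return self.head(pooled)


_ARCHS = {"A": (8, 16, 32), "B": (6, 12, 24, 48)}


def build_tiny_classifier(arch_id: str, n_classes: int, seed: int = 0) -> TinyConvNet:
    """Two fixed small architectures: A (3 blocks) and B (4 blocks, other
    widths), so surrogate-vs-target transfer between them is meaningful."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if arch_id not in _ARCHS:
        raise ValueError(f"unknown arch_id {arch_id!r}; choose from {sorted(_ARCHS)}")
    return TinyConvNet(_ARCHS[arch_id], n_classes, seed=seed)


def per_image_normalize_np(images_nchw: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """NumPy twin of engine.per_channel_normalize for inference paths."""
    mu = images_nchw.mean(axis=(2, 3), keepdims=True)
    sd = images_nchw.std(axis=(2, 3), keepdims=True)
    return (images_nchw - mu) / np.sqrt(sd ** 2 + eps)


def apply_input_transform(model: TinyConvNet, images_nchw: np.ndarray) -> np.ndarray:
    """Apply the per-channel input normalization the model was trained with."""
    mode = getattr(model, "norm_mode", None)
    if mode == "dataset":
        return (images_nchw - model.input_mean) / model.input_std
    if mode == "per_image":
        return per_image_normalize_np(images_nchw)
    return images_nchw


def predict_logits(model: TinyConvNet, images_nchw: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    outs = []
    for i in range(0, len(images_nchw), batch_size):
        x = apply_input_transform(model, images_nchw[i:i + batch_size])
        outs.append(model(Tensor(x)).data)
    return np.concatenate(outs, axis=0)


def predict_labels(model: TinyConvNet, images_nchw: np.ndarray) -> np.ndarray:
    return predict_logits(model, images_nchw).argmax(axis=1)


def train_classifier(model: TinyConvNet, manifest_dir_or_arrays, epochs: int,
                     seed: int, lr: float = 3e-3, weight_decay: float = 1e-5,
                     batch_size: int = 32, holdout_fraction: float = 0.25,
                     normalize: str | None = "dataset",
                     background_jitter: float = 0.1):
    """Adam-train a tiny classifier; returns (model, holdout_accuracy).

    Accepts either a dataset directory (with manifest.csv) or an
    (images NHWC, masks, labels) tuple. The holdout split is stratified
    and derived from `seed`.

    `normalize` selects the per-channel input normalization baked into
    the model: "dataset" (training-set channel mean/sd, the convention
    for pretrained-backbone pipelines), "per_image" (each image's own
    channel statistics) or None. The fitted transform is stored on the
    model and applied by `predict_logits` and by the attack engine.

    `background_jitter` augments each training image with a random
    constant shift of the pixels *outside* the lesion mask (uniform in
    ±jitter). The class signal lives inside the mask, so this teaches
    the model to base its decision on the lesion rather than on
    background intensity — the attention pattern real dermoscopy
    classifiers exhibit. Set 0 to disable (e.g. if masks are absent).
    """
    if isinstance(manifest_dir_or_arrays, (str, Path)):
        images, masks, labels = load_manifest_arrays(manifest_dir_or_arrays)
    else:
        images, masks, labels = manifest_dir_or_arrays
    if len(np.unique(labels)) < 2:
        raise ValueError("manifest must contain at least 2 classes")

    x = to_nchw(images)
    model.norm_mode = normalize
    if normalize == "dataset":
        model.input_mean = x.mean(axis=(0, 2, 3), keepdims=True)
        model.input_std = x.std(axis=(0, 2, 3), keepdims=True)
    bg = None
    if background_jitter > 0:
        if masks is None:
            raise ValueError("background_jitter requires lesion masks")
        bg = (1.0 - np.asarray(masks, dtype=np.float64))[:, None, :, :]

    rng = np.random.default_rng(seed)
    # stratified holdout
    test_idx = []
    for c in np.unique(labels):
        idx_c = np.flatnonzero(labels == c)
        idx_c = rng.permutation(idx_c)
        test_idx.extend(idx_c[: max(1, int(round(holdout_fraction * len(idx_c))))])
    test_idx = np.array(sorted(test_idx))
    train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)

    opt = ad.Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    for _ in range(epochs):
        order = rng.permutation(train_idx)
        for i in range(0, len(order), batch_size):
            batch = order[i:i + batch_size]
            xb = x[batch]
            if bg is not None:
                delta = rng.uniform(-background_jitter, background_jitter,
                                    size=(len(batch), 1, 1, 1))
                xb = np.clip(xb + delta * bg[batch], 0.0, 1.0)
            logits = model(Tensor(apply_input_transform(model, xb)))
            loss = ad.cross_entropy(logits, labels[batch])
            grads = ad.grad(loss, model.parameters())
            opt.step(grads)

    preds = predict_labels(model, x[test_idx])
    acc = float((preds == labels[test_idx]).mean())
    return model, acc
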