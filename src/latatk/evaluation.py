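"""Attack strength (ASR), concealment (SSIM) and CAM heatmap export.

ASR counts, over the FULL adversarial set, the samples that the
surrogate F classified correctly AND whose adversarial version fools the
target H:

    ASR = 100 · |{i : F(x_i)=y_i  and  H(x_adv,i)≠y_i}| / N

(the alternative convention of conditioning the denominator on F-correct
samples is available behind a flag).  SSIM defaults to single global
statistics per channel, averaged across channels; the conventional
windowed mean-SSIM is available as `mode="windowed"`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine, fixtures, losses
from ._autodiff import Tensor


@dataclass
class SSIMParams:
    c1: float = 0.01 ** 2      # (0.01·L)^2 with dynamic range L = 1
    c2: float = 0.03 ** 2
    mode: str = "global"       # "global" or "windowed"

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stabilisers must be positive")
        if self.mode not in ("global", "windowed"):
            raise ValueError("mode must be 'global' or 'windowed'")


def _ssim_single(a: np.ndarray, b: np.ndarray, p: SSIMParams) -> float:
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + p.c1) * (2 * cov + p.c2)
        / ((mu_a ** 2 + mu_b ** 2 + p.c1) * (var_a + var_b + p.c2))
    )


def ssim(a: np.ndarray, b: np.ndarray, params: SSIMParams | None = None) -> float:
    """Structural similarity in [-1,1]; channels averaged after
    per-channel SSIM; equals 1.0 exactly iff a == b."""
    p = params or SSIMParams()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("image grids differ")
    if a.ndim == 2:
        a, b = a[..., None], b[..., None]
    if p.mode == "windowed":
        from skimage.metrics import structural_similarity
        return float(structural_similarity(
            a, b, data_range=1.0, channel_axis=-1, gaussian_weights=True,
            K1=np.sqrt(p.c1), K2=np.sqrt(p.c2)))
    return float(np.mean([
        _ssim_single(a[..., c], b[..., c], p) for c in range(a.shape[-1])
    ]))


def attack_success_rate(F, H, originals: np.ndarray, adversarials: np.ndarray,
                        labels: np.ndarray,
                        denominator: str = "all") -> float:
    """Percent of adversarial samples fooling H among those F got right.

    originals/adversarials: (N,H,W,3); `denominator` is "all" (the full
    adversarial set, the printed formula) or "f_correct".
    """
    labels = np.asarray(labels)
    if not (len(originals) == len(adversarials) == len(labels)):
        raise ValueError("originals/adversarials/labels lengths differ")
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    f_correct = _predict(F, originals) == labels
    fooled = _predict(H, adversarials) != labels
    num = float(np.sum(f_correct & fooled))
    den = float(np.sum(f_correct)) if denominator == "f_correct" else float(len(labels))
    if den == 0:
        return 0.0
    return 100.0 * num / den


def _predict(model, images_nhwc: np.ndarray) -> np.ndarray:
    return fixtures.predict_labels(model, fixtures.to_nchw(images_nhwc))


# ---------------------------------------------------------------------------
# CAM heatmap export
# ---------------------------------------------------------------------------

def export_cam_heatmap(model, image: np.ndarray, label: int, layer_name: str,
                       out_path, alpha: float = 0.5, cmap: str = "jet"):
    """Min-max normalised CAM, upsampled to the image grid, rendered with
    a red-hot colormap and alpha-blended over the image; written as PNG."""
    from matplotlib import colormaps
    from scipy.ndimage import zoom

    x = fixtures.to_nchw(np.asarray(image, dtype=np.float64))
    x = fixtures.apply_input_transform(model, x)
    cam = losses.gradcam(model, Tensor(x), [label], layer_name).data[0]
    lo, hi = cam.min(), cam.max()
    norm = (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)
    H, W = image.shape[:2]
    up = zoom(norm, (H / cam.shape[0], W / cam.shape[1]), order=1)
    up = np.clip(up, 0.0, 1.0)
    overlay = colormaps[cmap](up)[..., :3]
    blend = (1 - alpha * up[..., None]) * image + alpha * up[..., None] * overlay
    fixtures.save_image(out_path, np.clip(blend, 0, 1))
    return out_path


# ---------------------------------------------------------------------------
# transfer evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    pairs: pd.DataFrame        # surrogate_id, target_id, asr, mean_ssim
    avg_asr: float             # mean ASR over the surrogate's target rows
    per_sample: pd.DataFrame   # f_correct, fooled flags per target, ssim

    def write(self, out_dir, per_sample: bool = True) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(out_dir / "report.csv", index=False)
        summary = {
            "avg_asr": self.avg_asr,
            "pairs": self.pairs.to_dict(orient="records"),
        }
        (out_dir / "report.json").write_text(json.dumps(summary, indent=2))
        if per_sample:
            self.per_sample.to_csv(out_dir / "per_sample.csv", index=False)


def evaluate_transfer(G, mask_source, surrogate, targets: dict,
                      manifest_dir_or_arrays, cfg,
                      surrogate_id: str = "surrogate") -> EvalReport:
    """Craft adversarials once; ASR per surrogate→target plus an Ensemble
    row (per-sample mean of the targets' fooling indicators, counted with
    the same rule), and mean SSIM over (x, x_adv) pairs.

    `targets` maps target id -> classifier.
    """
    if not targets:
        raise ValueError("empty target list")
    if isinstance(manifest_dir_or_arrays, (str, Path)):
        images, gt_masks, labels = fixtures.load_manifest_arrays(manifest_dir_or_arrays)
    else:
        images, gt_masks, labels = manifest_dir_or_arrays

    samples = engine.craft(G, mask_source, (images, gt_masks, labels), cfg)
    advs = np.stack([s.image for s in samples])
    return evaluate_samples(surrogate, targets, images, advs, labels,
                            surrogate_id=surrogate_id)


def evaluate_samples(surrogate, targets: dict, images: np.ndarray,
                     advs: np.ndarray, labels: np.ndarray,
                     surrogate_id: str = "surrogate",
                     ssim_params: SSIMParams | None = None) -> EvalReport:
    """ASR/SSIM report from already-crafted adversarials."""
    labels = np.asarray(labels)
    f_correct = _predict(surrogate, images) == labels
    ssims = np.array([ssim(img, adv, ssim_params)
                      for img, adv in zip(images, advs)])

    per_sample = pd.DataFrame({"index": np.arange(len(labels)),
                               "f_correct": f_correct, "ssim": ssims})
    rows = []
    fool_mat = {}
    for tid, H in targets.items():
        fooled = _predict(H, advs) != labels
        fool_mat[tid] = fooled
        per_sample[f"fooled_{tid}"] = fooled
        rows.append({
            "surrogate_id": surrogate_id,
            "target_id": tid,
            "asr": 100.0 * float(np.sum(f_correct & fooled)) / len(labels),
            "mean_ssim": float(ssims.mean()),
        })
    if len(targets) > 1:
        ens = np.mean(np.stack(list(fool_mat.values())), axis=0)
        rows.append({
            "surrogate_id": surrogate_id,
            "target_id": "Ensemble",
            "asr": 100.0 * float(np.sum(f_correct * ens)) / len(labels),
            "mean_ssim": float(ssims.mean()),
        })
    pairs = pd.DataFrame(rows)
    target_rows = pairs[pairs["target_id"] != "Ensemble"]
    return EvalReport(pairs=pairs, avg_asr=float(target_rows["asr"].mean()),
                      per_sample=per_sample)
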