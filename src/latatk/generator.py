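"""The perturbation generator G: an encoder-decoder ConvNet with skip
connections whose Tanh head emits a perturbation field in [-1, 1].

The raw Tanh output is *not* the final perturbation η: the attack engine
scales it by ε and restricts it to the lesion mask.  Keeping those steps
out of G preserves the clean [-1, 1] output contract for any weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


@dataclass
class GeneratorConfig:
    depth: int = 3              # encoder/decoder stages; 3 keeps a >=8x8 bottleneck at 64 px
    base_channels: int = 4
    skip_connections: bool = True   # debug flag; architecture contract keeps shapes either way
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


class Generator(ad.Module):
    """Encoder: 3x3 conv + ReLU, 2x2 max pool per stage.  Decoder: 2x2
    transposed conv upsampling, encoder features concatenated in, 3x3 conv
    refinement.  Head: 1x1 conv + Tanh."""

    def __init__(self, config: GeneratorConfig, in_channels: int = 3):
        rng = np.random.default_rng(config.seed)
        self.config = config
        d, bc = config.depth, config.base_channels
        chans = [bc * 2 ** i for i in range(d + 1)]
        self.enc = [
            ad.Conv2d(in_channels if i == 0 else chans[i - 1], chans[i], k=3, pad=1, rng=rng)
            for i in range(d)
        ]
        self.bottleneck = ad.Conv2d(chans[d - 1], chans[d], k=3, pad=1, rng=rng)
        self.ups = [ad.ConvTranspose2x2(chans[i + 1], chans[i], rng) for i in reversed(range(d))]
        skip_mult = 2 if config.skip_connections else 1
        self.dec = [
            ad.Conv2d(skip_mult * chans[i], chans[i], k=3, pad=1, rng=rng)
            for i in reversed(range(d))
        ]
        self.head = ad.Conv2d(chans[0], in_channels, k=1, pad=0, rng=rng)
        # zero-initialised head: the untrained generator emits a zero
        # perturbation field, so training starts from the clean image
        # rather than from random texture the LBP term must first undo
        self.head.w.data = np.zeros_like(self.head.w.data)
        self.in_channels = in_channels

    def __call__(self, x) -> Tensor:
        """x: NCHW Tensor/array -> perturbation field in [-1,1], same shape."""
        t = ad.as_tensor(x)
        N, C, H, W = t.shape
        f = 2 ** self.config.depth
        if C != self.in_channels:
            raise ValueError(f"generator built for {self.in_channels} channels, got {C}")
        if H % f or W % f:
            raise ValueError(
                f"input size {H}x{W} is not divisible by 2^depth = {f}")
        skips = []
        for conv in self.enc:
            t = ad.relu(conv(t))
            skips.append(t)
            t = ad.maxpool2x2(t)
        t = ad.relu(self.bottleneck(t))
        for up, conv, skip in zip(self.ups, self.dec, reversed(skips)):
            t = up(t)
            if self.config.skip_connections:
                t = ad.concat([skip, t], axis=1)
            t = ad.relu(conv(t))
        return ad.tanh(self.head(t))


def build_generator(config: GeneratorConfig | None = None,
                    in_channels: int = 3) -> Generator:
    return Generator(config or GeneratorConfig(), in_channels=in_channels)


def generate_perturbation(G: Generator, image: np.ndarray) -> np.ndarray:
    """Raw perturbation field for one (H,W,3) image: (H,W,3) in [-1,1].

    Applies the input transform stored on G by attack training (if any)."""
    from . import engine, fixtures
    x = fixtures.to_nchw(np.asarray(image, dtype=np.float64))
    out = G(Tensor(engine.generator_input_np(G, x))).data
    return fixtures.to_nhwc(out)[0]


# ---------------------------------------------------------------------------
# checkpoints: compressed parameter archive with a JSON config header
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: ad.Module, config=None, extra: dict | None = None):
    """Single-file .npz: parameters + JSON header (config + extras)."""
    header = {"class": type(model).__name__}
    if config is not None:
        header["config"] = asdict(config)
    if extra:
        header["extra"] = extra
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint_header(path) -> dict:
    with np.load(path) as z:
        return json.loads(bytes(z["__header__"]).decode())


def save_generator(path, G: Generator) -> None:
    """Checkpoint a generator together with its frozen input transform."""
    extra = {"in_channels": G.in_channels,
             "input_transform": getattr(G, "input_transform", None)}
    if extra["input_transform"] == "dataset":
        extra["input_mean"] = np.asarray(G.input_mean).ravel().tolist()
        extra["input_std"] = np.asarray(G.input_std).ravel().tolist()
    save_checkpoint(path, G, config=G.config, extra=extra)


def load_generator(path) -> Generator:
    header = load_checkpoint_header(path)
    if header.get("class") != "Generator":
        raise ValueError(f"{path} is not a generator checkpoint")
    cfg = GeneratorConfig(**header["config"])
    extra = header.get("extra", {})
    G = build_generator(cfg, in_channels=extra.get("in_channels", 3))
    with np.load(path) as z:
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    G.load_state_dict(state)
    G.input_transform = extra.get("input_transform")
    if G.input_transform == "dataset":
        G.input_mean = np.array(extra["input_mean"]).reshape(1, 3, 1, 1)
        G.input_std = np.array(extra["input_std"]).reshape(1, 3, 1, 1)
    return G


def load_module_state(path, model: ad.Module):
    header = load_checkpoint_header(path)
    with np.load(path) as z:
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    return header
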