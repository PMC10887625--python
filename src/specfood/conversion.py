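"""RGB-to-narrow-band image conversion network.

An encoder-decoder CNN in the U-net style maps a 3-channel RGB image to
the single-channel image a narrow-band (UV/NIR) capture would have
produced.  The default layout uses 3x3 same-padded convolutions with
channel depths 3-16-32-64-128-256-256-128-64-32-16-1, 2x2 max pooling on
the way down, nearest-neighbour upsampling with concatenated skip
connections on the way up, and a sigmoid output so predictions stay in
[0, 1].  Training minimises the mean squared error between predicted and
actual band images by plain mini-batch SGD; one conversion model is
trained per target wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn

__all__ = [
    "DEFAULT_DEPTH_PROFILE",
    "SMALL_DEPTH_PROFILE",
    "TrainConfig",
    "ImagePair",
    "ConversionModel",
    "build_conversion_net",
    "train_conversion",
    "predict_band",
    "predict_stacks",
]

#: Channel depths of the full-size converter (4 pooling stages).
DEFAULT_DEPTH_PROFILE: tuple[int, ...] = (3, 16, 32, 64, 128, 256, 256, 128, 64, 32, 16, 1)

#: A light two-pool profile for small synthetic scenes.
SMALL_DEPTH_PROFILE: tuple[int, ...] = (3, 8, 16, 32, 32, 16, 8, 1)


@dataclass
class TrainConfig:
    """SGD settings: learning rate (the update is W <- W - lr * grad E),
    mini-batch size, epoch count and the RNG seed."""

    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    momentum: float = 0.0  # off by default: plain SGD

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ImagePair:
    """One training example: RGB input (HxWx3) and band target (HxW)."""

    x: np.ndarray
    y: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        if self.x.ndim != 3 or self.x.shape[2] != 3:
            raise ValueError("x must be HxWx3")
        if self.y.shape != self.x.shape[:2]:
            raise ValueError("y spatial size must match x")


class ConversionModel:
    """Kernel set realising the RGB -> band mapping F(W, X)."""

    kernel_size = (3, 3)
    pooling = (2, 2)

    def __init__(self, depth_profile: Sequence[int], seed: int,
                 target_band: int | None = None) -> None:
        profile = tuple(int(c) for c in depth_profile)
        if profile[0] != 3 or profile[-1] != 1:
            raise ValueError("depth profile must start at 3 and end at 1")
        inner = profile[1:-1]
        if len(inner) % 2 or inner != inner[::-1]:
            raise ValueError("encoder/decoder stages must be symmetric")
        self.depth_profile = profile
        self.target_band = target_band
        self.seed = int(seed)
        m = len(inner) // 2
        enc_ch = inner[:m]          # e.g. (16, 32, 64, 128, 256)
        dec_ch = inner[m:]          # e.g. (256, 128, 64, 32, 16)
        self.n_pools = len(enc_ch) - 1

        rng = np.random.default_rng(seed)
        self.enc: list[tuple[_nn.Conv2D, _nn.ReLU, _nn.MaxPool2]] = []
        prev = 3
        for ch in enc_ch[:-1]:
            self.enc.append((_nn.Conv2D(prev, ch, rng), _nn.ReLU(), _nn.MaxPool2()))
            prev = ch
        self.bconv1, self.brelu1 = _nn.Conv2D(prev, enc_ch[-1], rng), _nn.ReLU()
        self.bconv2, self.brelu2 = _nn.Conv2D(enc_ch[-1], dec_ch[0], rng), _nn.ReLU()
        self.dec: list[tuple[_nn.Upsample2, _nn.Conv2D, _nn.ReLU, int, int]] = []
        prev = dec_ch[0]
        skip_ch = list(enc_ch[:-1])  # channel count of each stored skip
        for ch, sc in zip(dec_ch[1:], reversed(skip_ch)):
            self.dec.append(
                (_nn.Upsample2(), _nn.Conv2D(prev + sc, ch, rng), _nn.ReLU(),
                 prev, sc)
            )
            prev = ch
        self.final = _nn.Conv2D(prev, 1, rng)
        self.out_act = _nn.Sigmoid()

    # -- plumbing -----------------------------------------------------------
    def _layers(self) -> list[_nn.Layer]:
        layers: list[_nn.Layer] = []
        for conv, _, _ in self.enc:
            layers.append(conv)
        layers += [self.bconv1, self.bconv2]
        for _, conv, _, _, _ in self.dec:
            layers.append(conv)
        layers.append(self.final)
        return layers

    def _check_size(self, h: int, w: int) -> None:
        d = 2**self.n_pools
        if h % d or w % d:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by {d} "
                f"(2^{self.n_pools} pooling stages)"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) float32 -> (N, 1, H, W) in (0, 1)."""
        self._check_size(x.shape[2], x.shape[3])
        skips = []
        h = x
        for conv, relu, pool in self.enc:
            h = relu.forward(conv.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.brelu1.forward(self.bconv1.forward(h))
        h = self.brelu2.forward(self.bconv2.forward(h))
        for (up, conv, relu, _, _), skip in zip(self.dec, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=1)
            h = relu.forward(conv.forward(h))
        return self.out_act.forward(self.final.forward(h))

    def backward(self, g: np.ndarray) -> None:
        g = self.final.backward(self.out_act.backward(g))
        skip_grads = []
        for up, conv, relu, c_main, _ in reversed(self.dec):
            g = conv.backward(relu.backward(g))
            skip_grads.append(g[:, c_main:])
            g = up.backward(np.ascontiguousarray(g[:, :c_main]))
        g = self.bconv2.backward(self.brelu2.backward(g))
        g = self.bconv1.backward(self.brelu1.backward(g))
        # skip_grads is ordered shallow-to-deep; encoder unwinds deep-to-shallow.
        for (conv, relu, pool), gs in zip(reversed(self.enc), reversed(skip_grads)):
            g = pool.backward(g) + gs
            g = conv.backward(relu.backward(g))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self._layers()):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        with open(Path(path), "wb") as fh:  # keep the exact .ckpt name
            np.savez(
                fh,
                depth_profile=np.asarray(self.depth_profile),
                target_band=np.asarray(-1 if self.target_band is None
                                       else self.target_band),
                seed=np.asarray(self.seed),
                **arrays,
            )

    @classmethod
    def load(cls, path: str | Path) -> "ConversionModel":
        with np.load(Path(path)) as data:
            band = int(data["target_band"])
            model = cls(
                depth_profile=tuple(int(c) for c in data["depth_profile"]),
                seed=int(data["seed"]),
                target_band=None if band < 0 else band,
            )
            for i, layer in enumerate(model._layers()):
                layer.W[...] = data[f"W{i}"]
                layer.b[...] = data[f"b{i}"]
        return model


def build_conversion_net(
    depth_profile: Sequence[int] = DEFAULT_DEPTH_PROFILE,
    seed: int = 0,
    target_band: int | None = None,
) -> ConversionModel:
    """Construct a conversion network with deterministic initial weights."""
    return ConversionModel(depth_profile, seed, target_band)


def train_conversion(
    model: ConversionModel,
    pairs: Sequence[ImagePair],
    config: TrainConfig,
) -> tuple[ConversionModel, list[float]]:
    """Train in place by mini-batch SGD on the MSE objective.

    Returns the model and one epoch-mean MSE (per pixel) per epoch,
    accumulated over the epoch's mini-batches.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    shapes = {p.x.shape for p in pairs}
    if len(shapes) > 1:
        raise ValueError(f"all pairs must share one spatial size, got {shapes}")

    X = np.stack([p.x for p in pairs]).transpose(0, 3, 1, 2).astype(np.float32)
    Y = np.stack([p.y for p in pairs])[:, None].astype(np.float32)
    n = len(pairs)
    rng = np.random.default_rng(config.seed)
    opt = _nn.SGD(model._layers(), lr=config.learning_rate,
                  momentum=config.momentum)

    history: list[float] = []
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            out = model.forward(X[idx])
            loss, grad = _nn.mse_loss(out, Y[idx])
            model.backward(grad)
            opt.step()
            total += loss * len(idx)
        history.append(total / n)
    return model, history


def predict_band(model: ConversionModel, rgb: np.ndarray) -> np.ndarray:
    """Predict the single-band image for one RGB image (HxWx3 in [0, 1])."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {rgb.shape}")
    x = rgb.transpose(2, 0, 1)[None].astype(np.float32)
    out = model.forward(x)[0, 0]
    return np.clip(out.astype(np.float64), 0.0, 1.0)


def predict_stacks(models, stacks):
    """Replace actual band images with model predictions from each scene's RGB.

    ``models`` maps wavelength (nm) -> trained ConversionModel.  Returns new
    stacks whose band entries for those wavelengths are predictions; other
    entries are dropped so the result mirrors an RGB-only acquisition.
    """
    from .spectral_scene import SpectralStack

    out = []
    for s in stacks:
        images: dict[object, np.ndarray] = {"RGB": s.images["RGB"]}
        for band, model in models.items():
            images[int(band)] = predict_band(model, s.images["RGB"])
        out.append(SpectralStack(images=images, height=s.height,
                                 width=s.width, pose=s.pose, seed=s.seed))
    return out
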