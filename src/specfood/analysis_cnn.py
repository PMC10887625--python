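"""Food classification and caloric estimation from stacked band images.

The analysis network consumes a 64x64 multi-plane stack — the 3 RGB planes
plus one plane per selected wavelength, actual or predicted — and ends in
either a softmax head trained with cross-entropy (classification) or a
single linear output trained directly with the mean absolute percentage
error (caloric estimation).  Zero-calorie targets must be floored to
5 kcal upstream (``dataset_io.floor_kcal``) since a relative error is
undefined at zero.

The trunk is deliberately simple: three 3x3 conv + ReLU + 2x2 max-pool
stages (16-32-64 channels) and one dense ReLU layer of 128 units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize as _resize

from . import _nn
from .spectral_scene import SpectralStack

__all__ = [
    "ANALYSIS_SIZE",
    "AnalysisConfig",
    "AnalysisModel",
    "reduce_image",
    "stack_inputs",
    "train_classifier",
    "train_estimator",
    "predict",
]

#: Side length of the reduced analysis input.
ANALYSIS_SIZE: int = 64


@dataclass
class AnalysisConfig:
    """Training settings for the analysis CNN."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    dense_units: int = 128

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate < 0:
            raise ValueError("invalid training configuration")


def reduce_image(image: np.ndarray) -> np.ndarray:
    """Down-sample a band plane or RGB image to 64x64.

    Bilinear interpolation with antialiasing; the whole frame is kept (no
    cropping), and values stay within [0, 1].  A 64x64 input is returned
    unchanged.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < ANALYSIS_SIZE or w < ANALYSIS_SIZE:
        raise ValueError(f"input {h}x{w} smaller than {ANALYSIS_SIZE}")
    if (h, w) == (ANALYSIS_SIZE, ANALYSIS_SIZE):
        return image
    out_shape = (ANALYSIS_SIZE, ANALYSIS_SIZE) + image.shape[2:]
    out = _resize(image.astype(np.float64), out_shape, order=1,
                  anti_aliasing=True, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def stack_inputs(
    stacks: Sequence[SpectralStack], bands: Sequence[int]
) -> np.ndarray:
    """Build (N, 3+len(bands), 64, 64) analysis inputs from scene stacks.

    RGB planes come first, then one plane per wavelength in sorted order.
    Raises ``KeyError`` naming any band missing from a stack.
    """
    bands = sorted(int(b) for b in bands)
    out = []
    for s in stacks:
        planes = [reduce_image(s.images["RGB"]).transpose(2, 0, 1)]
        for b in bands:
            if b not in s.images:
                raise KeyError(f"band {b} nm missing from stack (seed {s.seed})")
            planes.append(reduce_image(s.images[b])[None])
        out.append(np.concatenate(planes, axis=0))
    return np.stack(out).astype(np.float32)


class AnalysisModel:
    """Trained analysis CNN with a classification or regression head."""

    def __init__(self, n_channels: int, head: str, n_targets: int,
                 config: AnalysisConfig) -> None:
        if head not in ("classification", "regression"):
            raise ValueError(f"unknown head {head!r}")
        self.head = head
        self.n_channels = n_channels
        self.n_targets = n_targets
        self.config = config
        self.loss_history: list[float] = []
        self.target_scale: float = 1.0  # regression targets are fit in units of their mean

        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.conv_channels
        size = ANALYSIS_SIZE // 8  # three 2x2 poolings
        self.layers: list[_nn.Layer] = [
            _nn.Conv2D(n_channels, c1, rng), _nn.ReLU(), _nn.MaxPool2(),
            _nn.Conv2D(c1, c2, rng), _nn.ReLU(), _nn.MaxPool2(),
            _nn.Conv2D(c2, c3, rng), _nn.ReLU(), _nn.MaxPool2(),
            _nn.Flatten(),
            _nn.Dense(size * size * c3, config.dense_units, rng), _nn.ReLU(),
            _nn.Dense(config.dense_units, n_targets, rng, scale=0.01),
        ]
        if head == "regression":
            # Start at the target mean (scale 1 after normalisation).
            self.layers[-1].b[...] = 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x - np.float32(0.5)  # centre [0,1] planes for conditioning
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.head != "classification":
            raise ValueError("probabilities only defined for classification")
        return _nn.softmax(self.forward(x.astype(np.float32)))


def _as_batch(inputs) -> np.ndarray:
    x = np.stack(list(inputs)) if not isinstance(inputs, np.ndarray) else inputs
    if x.ndim != 4:
        raise ValueError("inputs must be (N, C, 64, 64)")
    if x.shape[2] != ANALYSIS_SIZE or x.shape[3] != ANALYSIS_SIZE:
        raise ValueError(f"planes must be {ANALYSIS_SIZE}x{ANALYSIS_SIZE}")
    return x.astype(np.float32)


def _train(model: AnalysisModel, X: np.ndarray, y: np.ndarray,
           loss_fn, config: AnalysisConfig) -> AnalysisModel:
    n = len(X)
    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.SGD([l for l in model.layers if l.params()],
                  lr=config.learning_rate, momentum=config.momentum)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            out = model.forward(X[idx])
            loss, grad = loss_fn(out, y[idx])
            model.backward(grad)
            opt.step()
            total += loss * len(idx)
        model.loss_history.append(total / n)
    return model


def train_classifier(
    inputs, labels: Sequence[int], config: AnalysisConfig
) -> AnalysisModel:
    """Train the softmax/cross-entropy classifier; deterministic in seed."""
    X = _as_batch(inputs)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("labels length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n_targets = int(y.max()) + 1
    if y.min() < 0:
        raise ValueError("labels must be non-negative class indices")
    model = AnalysisModel(X.shape[1], "classification", n_targets, config)
    return _train(model, X, y, _nn.softmax_xent_loss, config)


def train_estimator(
    inputs, kcal_targets: Sequence[float], config: AnalysisConfig
) -> AnalysisModel:
    """Train the linear-head caloric estimator with the MAPE loss.

    Targets must already be positive (apply ``floor_kcal``); they are
    normalised by their mean internally, which leaves the relative loss
    unchanged but keeps gradient scales unit-free.
    """
    X = _as_batch(inputs)
    t = np.asarray(kcal_targets, dtype=np.float64)
    if len(t) != len(X):
        raise ValueError("targets length mismatch")
    if np.any(t <= 0):
        raise ValueError(
            "calorie targets must be positive; apply floor_kcal to zeros first"
        )
    model = AnalysisModel(X.shape[1], "regression", 1, config)
    model.target_scale = float(t.mean())
    tn = (t / model.target_scale).astype(np.float32)[:, None]

    def loss_fn(out, target):
        return _nn.mape_loss(out, target)

    return _train(model, X, tn, loss_fn, config)


def predict(model: AnalysisModel, input_: np.ndarray):
    """Class index (argmax of the probability vector) or kcal value."""
    x = np.asarray(input_, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1] != model.n_channels:
        raise ValueError(
            f"channel mismatch: model expects {model.n_channels}, got {x.shape[1]}"
        )
    out = model.forward(x)
    if model.head == "classification":
        return int(np.argmax(_nn.softmax(out)[0]))
    return float(out[0, 0] * model.target_scale)
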