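"""Canned synthetic experiments exercising the full pipeline.

These are the package's standing study conditions: scene scale, noise and
contrast follow the generator defaults, and problem sizes are chosen so a
single CPU core completes each experiment in minutes.  Both the test
suite and the acceptance script run these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis_cnn import AnalysisConfig, predict, stack_inputs, train_classifier
from .conversion import (
    SMALL_DEPTH_PROFILE,
    ImagePair,
    TrainConfig,
    build_conversion_net,
    predict_stacks,
    train_conversion,
)
from .dataset_io import split_train_val
from .metrics_report import psnr, ssim
from .spectral_scene import make_catalog, make_dataset, make_rgb_predictable_catalog

SCENE_SIZE = (64, 64)
NOISE_SD = 0.02
PLANTED_BAND = 850


@dataclass
class ConversionRecovery:
    """Held-out quality of a converter trained where the target band is an
    exact function of the RGB spectrum."""

    holdout_psnr_db: float
    holdout_ssim: float
    final_epoch_mse: float
    n_train: int
    n_test: int


def conversion_recovery(
    seed: int,
    *,
    n_classes: int = 4,
    n_per_class: int = 20,
    epochs: int = 100,
    learning_rate: float = 0.3,
    momentum: float = 0.9,
    size: tuple[int, int] = (32, 32),
) -> ConversionRecovery:
    """Train the converter on noiseless scenes whose 850 nm reflectance is a
    fixed linear combination of the RGB channels, and score held-out PSNR.

    The closed-form relationship means a perfect converter exists; held-out
    PSNR far above 30 dB indicates the network recovers it.
    """
    catalog = make_rgb_predictable_catalog(n_classes, (10, 400), seed,
                                           band=PLANTED_BAND)
    stacks, _ = make_dataset(catalog, n_per_class, [PLANTED_BAND], poses=4,
                             noise_sd=0.0, size=size, seed=seed + 1)
    test_stacks, _ = make_dataset(catalog, max(2, n_per_class // 4),
                                  [PLANTED_BAND], poses=4, noise_sd=0.0,
                                  size=size, seed=seed + 2)

    pairs = [ImagePair(s.images["RGB"], s.images[PLANTED_BAND], i)
             for i, s in enumerate(stacks)]
    model = build_conversion_net(SMALL_DEPTH_PROFILE, seed=seed,
                                 target_band=PLANTED_BAND)
    model, history = train_conversion(
        model, pairs,
        TrainConfig(learning_rate=learning_rate, momentum=momentum,
                    batch_size=16, epochs=epochs, seed=seed),
    )
    preds = predict_stacks({PLANTED_BAND: model}, test_stacks)
    scores = [psnr(t.images[PLANTED_BAND], p.images[PLANTED_BAND])
              for t, p in zip(test_stacks, preds)]
    ssims = [ssim(t.images[PLANTED_BAND], p.images[PLANTED_BAND])
             for t, p in zip(test_stacks, preds)]
    return ConversionRecovery(
        holdout_psnr_db=float(np.mean(scores)),
        holdout_ssim=float(np.mean(ssims)),
        final_epoch_mse=history[-1],
        n_train=len(pairs),
        n_test=len(test_stacks),
    )


@dataclass
class MonotonicityResult:
    """Held-out accuracies of RGB-only, RGB+actual-band and
    RGB+predicted-band classifiers, averaged over seeds."""

    rgb_only_acc: float
    rgb_band_acc: float
    rgb_predicted_acc: float
    per_seed: list[tuple[float, float, float]]
    conversion_psnr_db: float
    n_train: int
    n_test: int

    @property
    def band_gain(self) -> float:
        """Accuracy gained by adding the actual planted band (points)."""
        return self.rgb_band_acc - self.rgb_only_acc

    @property
    def substitution_gap(self) -> float:
        """Accuracy lost when predicted bands stand in for actual (points)."""
        return self.rgb_band_acc - self.rgb_predicted_acc


def band_information_monotonicity(
    seed: int,
    *,
    n_seeds: int = 5,
    n_per_class: int = 16,
    n_test_per_class: int = 10,
    cls_epochs: int = 40,
    conv_epochs: int = 30,
) -> MonotonicityResult:
    """Measure the classification value of a planted NIR band.

    A 4-class catalog contains one confusable pair: identical visible
    spectra, contrast 0.3 at the planted bands.  One dataset is generated;
    a converter for the planted band is trained on its training split and
    frozen; then for ``n_seeds`` classifier seeds (fresh initialisation and
    split) three classifiers are trained — RGB planes only, RGB + actual
    planted band, RGB + predicted planted band — and scored on a fresh
    held-out scene set.
    """
    catalog = make_catalog(4, 1, 0.3, (10, 400), seed,
                           planted_bands=(PLANTED_BAND, 970))
    stacks, records = make_dataset(catalog, n_per_class, [PLANTED_BAND],
                                   poses=4, noise_sd=NOISE_SD,
                                   size=SCENE_SIZE, seed=seed + 1)
    test_stacks, test_records = make_dataset(
        catalog, n_test_per_class, [PLANTED_BAND], poses=4,
        noise_sd=NOISE_SD, size=SCENE_SIZE, seed=seed + 2)
    labels = np.asarray([r.class_index for r in records])
    test_labels = np.asarray([r.class_index for r in test_records])

    # Converter: trained once on the training split, then frozen.
    idx_train, _ = split_train_val(list(range(len(stacks))), seed=seed,
                                   labels=labels)
    conv_pairs = [ImagePair(stacks[i].images["RGB"],
                            stacks[i].images[PLANTED_BAND], i)
                  for i in idx_train]
    conv = build_conversion_net(SMALL_DEPTH_PROFILE, seed=seed,
                                target_band=PLANTED_BAND)
    conv, _ = train_conversion(
        conv, conv_pairs,
        TrainConfig(learning_rate=0.3, momentum=0.9, batch_size=16,
                    epochs=conv_epochs, seed=seed),
    )
    pred_stacks = predict_stacks({PLANTED_BAND: conv}, stacks)
    pred_test = predict_stacks({PLANTED_BAND: conv}, test_stacks)
    conv_psnr = float(np.mean([
        psnr(t.images[PLANTED_BAND], p.images[PLANTED_BAND])
        for t, p in zip(test_stacks, pred_test)
    ]))

    conditions = {
        "rgb": (stack_inputs(stacks, []), stack_inputs(test_stacks, [])),
        "band": (stack_inputs(stacks, [PLANTED_BAND]),
                 stack_inputs(test_stacks, [PLANTED_BAND])),
        "pred": (stack_inputs(pred_stacks, [PLANTED_BAND]),
                 stack_inputs(pred_test, [PLANTED_BAND])),
    }

    per_seed = []
    for k in range(n_seeds):
        cfg_seed = seed + 100 + k
        accs = []
        for name in ("rgb", "band", "pred"):
            X, Xt = conditions[name]
            cfg = AnalysisConfig(epochs=cls_epochs, seed=cfg_seed)
            model = train_classifier(X, labels, cfg)
            pred = np.asarray([predict(model, x) for x in Xt])
            accs.append(float(100.0 * np.mean(pred == test_labels)))
        per_seed.append(tuple(accs))

    arr = np.asarray(per_seed)
    return MonotonicityResult(
        rgb_only_acc=float(arr[:, 0].mean()),
        rgb_band_acc=float(arr[:, 1].mean()),
        rgb_predicted_acc=float(arr[:, 2].mean()),
        per_seed=per_seed,
        conversion_psnr_db=conv_psnr,
        n_train=len(stacks),
        n_test=len(test_stacks),
    )
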