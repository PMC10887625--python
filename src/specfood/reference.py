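"""Published reference results bundled for benchmarking.

These are the experiment tables reported by the original multispectral
food-analysis study this package models: per-wavelength conversion quality
(PSNR/SSIM) of UV/NIR images predicted from RGB, and the wavelength
selection paths for food classification and caloric estimation using
actual versus predicted band images, on a 101-food corpus.  They serve as
fixed inputs for the secondary statistics recomputed by
``specfood.metrics_report`` (correlations, reductions, summary rows); the
underlying camera dataset itself is not redistributable.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CONVERSION_BANDS",
    "conversion_quality",
    "classification_actual",
    "classification_predicted",
    "estimation_actual",
    "estimation_predicted",
]

#: Wavelengths (nm) targeted for RGB-to-band conversion.
CONVERSION_BANDS: tuple[int, ...] = (385, 405, 810, 850, 870, 890, 910, 950, 970, 1020)

# Per-wavelength quality of band images predicted from RGB.
_CONVERSION_PSNR = {
    385: 34.28, 405: 31.05, 810: 30.18, 850: 29.71, 870: 30.15,
    890: 30.76, 910: 30.63, 950: 29.38, 970: 30.06, 1020: 29.87,
}
_CONVERSION_SSIM = {
    385: 0.863, 405: 0.774, 810: 0.912, 850: 0.871, 870: 0.906,
    890: 0.906, 910: 0.831, 950: 0.876, 970: 0.856, 1020: 0.851,
}

# Selection paths: (n_images, selected non-RGB wavelengths, score[, avg psnr, avg ssim]).
# n_images counts the RGB image plus one image per wavelength.
_CLS_ACTUAL = [
    (1, (), 86.30),
    (2, (970,), 96.62),
    (3, (910, 970), 98.60),
    (4, (405, 910, 970), 98.43),
    (5, (405, 910, 950, 970), 98.71),
    (6, (385, 405, 910, 950, 970), 99.06),
    (7, (385, 405, 890, 910, 950, 970), 99.23),
    (8, (385, 810, 850, 890, 910, 950, 970), 99.37),
    (9, (385, 810, 850, 870, 890, 910, 950, 970), 99.45),
    (10, (385, 810, 850, 870, 890, 910, 950, 970, 1020), 99.06),
    (11, (385, 405, 810, 850, 870, 890, 910, 950, 970, 1020), 99.15),
]
# Rows carry the published Avg. PSNR / Avg. SSIM columns verbatim: the
# published correlation analyses were computed from the printed columns,
# which occasionally differ in the last digit from a recomputation off the
# per-wavelength table.
_CLS_PREDICTED = [
    (1, (), 90.23, None, None),
    (2, (950,), 95.24, 29.38, 0.876),
    (3, (385, 870), 96.89, 32.22, 0.885),
    (4, (385, 870, 1020), 97.61, 31.43, 0.874),
    (5, (385, 810, 870, 1020), 96.59, 31.12, 0.883),
    (6, (385, 810, 850, 870, 970), 98.13, 30.88, 0.882),
    (7, (385, 405, 810, 850, 870, 1020), 97.91, 30.87, 0.863),
    (8, (385, 405, 810, 850, 870, 910, 1020), 97.85, 30.84, 0.858),
    (9, (385, 405, 810, 850, 870, 910, 970, 1020), 98.16, 30.74, 0.858),
    (10, (385, 405, 810, 850, 870, 890, 910, 950, 970), 97.77, 30.69, 0.866),
    (11, (385, 405, 810, 850, 870, 890, 910, 950, 970, 1020), 98.24, 30.61, 0.865),
]
_EST_ACTUAL = [
    (1, (), 28.65),
    (2, (970,), 21.74),
    (3, (385, 1020), 18.54),
    (4, (385, 970, 1020), 18.30),
    (5, (385, 850, 970, 1020), 14.57),
    (6, (385, 850, 890, 970, 1020), 14.29),
    (7, (385, 405, 850, 910, 970, 1020), 12.63),
    (8, (385, 405, 850, 910, 950, 970, 1020), 11.67),
    (9, (385, 405, 850, 870, 910, 950, 970, 1020), 15.00),
    (10, (385, 405, 810, 850, 870, 910, 950, 970, 1020), 12.68),
    (11, (385, 405, 810, 850, 870, 890, 910, 950, 970, 1020), 21.42),
]
_EST_PREDICTED = [
    (1, (), 32.28, None, None),
    (2, (970,), 20.16, 30.06, 0.856),
    (3, (385, 970), 17.59, 32.17, 0.859),
    (4, (385, 405, 970), 16.65, 31.80, 0.831),
    (5, (385, 405, 850, 970), 18.19, 31.28, 0.841),
    (6, (385, 405, 850, 890, 970), 15.96, 31.17, 0.854),
    (7, (385, 850, 870, 890, 970, 1020), 16.21, 30.81, 0.876),
    (8, (385, 405, 850, 870, 890, 970, 1020), 17.05, 30.84, 0.861),
    (9, (385, 405, 850, 870, 890, 950, 970, 1020), 17.41, 30.66, 0.863),
    (10, (385, 405, 810, 850, 870, 890, 910, 950, 1020), 12.13, 30.60, 0.868),
    (11, (385, 405, 810, 850, 870, 890, 910, 950, 970, 1020), 18.71, 30.61, 0.865),
]

# RGB-only baselines from other architectures reported alongside the paths.
RGB_ONLY_BASELINES = {
    "classification": {"VGG16": 85.54, "ResNet152+ANN": 87.23, "WI-HSNN": 88.04},
    "estimation": {"VGG16": 27.95},
}


def conversion_quality() -> pd.DataFrame:
    """Per-wavelength PSNR (dB) and SSIM of predicted band images."""
    return pd.DataFrame(
        {
            "wavelength": list(CONVERSION_BANDS),
            "psnr": [_CONVERSION_PSNR[b] for b in CONVERSION_BANDS],
            "ssim": [_CONVERSION_SSIM[b] for b in CONVERSION_BANDS],
        }
    )


def _path_frame(rows, with_quality: bool) -> pd.DataFrame:
    out = {
        "n_images": [r[0] for r in rows],
        "bands": [r[1] for r in rows],
        "score": [r[2] for r in rows],
    }
    if with_quality:
        out["avg_psnr"] = [float("nan") if r[3] is None else r[3] for r in rows]
        out["avg_ssim"] = [float("nan") if r[4] is None else r[4] for r in rows]
    return pd.DataFrame(out)


def classification_actual() -> pd.DataFrame:
    """Classification accuracy (%) per selected set, actual band images."""
    return _path_frame(_CLS_ACTUAL, with_quality=False)


def classification_predicted() -> pd.DataFrame:
    """Classification accuracy (%) per selected set, predicted band images."""
    return _path_frame(_CLS_PREDICTED, with_quality=True)


def estimation_actual() -> pd.DataFrame:
    """Caloric-estimation MAPE per selected set, actual band images."""
    return _path_frame(_EST_ACTUAL, with_quality=False)


def estimation_predicted() -> pd.DataFrame:
    """Caloric-estimation MAPE per selected set, predicted band images."""
    return _path_frame(_EST_PREDICTED, with_quality=True)
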