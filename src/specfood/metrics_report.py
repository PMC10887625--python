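"""Quantitative metrics for multispectral food analysis.

Image-fidelity metrics (PSNR, SSIM) score how well a band image predicted
from RGB approximates the actually captured narrow-band image; MAPE scores
caloric estimation; accuracy scores classification.  Secondary statistics
(Pearson correlation, sample standard deviation, relative reductions,
per-selection PSNR/SSIM averages) summarise selection paths the way the
experiment tables do.  ``build_report`` renders a directory of CSV tables
plus a markdown summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage.metrics import structural_similarity as _skimage_ssim

__all__ = [
    "EvalTable",
    "mape",
    "psnr",
    "ssim",
    "pearson_r",
    "sample_std",
    "relative_reduction",
    "selection_quality_summary",
    "build_report",
]


def mape(true_kcal: Sequence[float], pred_kcal: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent.

    ``100 * mean_i |M_i - M^_i| / M_i`` where ``M_i`` is the true calorie
    value (floored away from zero upstream) and ``M^_i`` the estimate.
    """
    true = np.asarray(true_kcal, dtype=float)
    pred = np.asarray(pred_kcal, dtype=float)
    if true.shape != pred.shape:
        raise ValueError(f"length mismatch: {true.shape} vs {pred.shape}")
    if true.size == 0:
        raise ValueError("empty input")
    if np.any(true <= 0):
        raise ValueError(
            "true calorie values must be positive; apply the 5 kcal floor "
            "(floor_kcal) to zero-calorie items before computing MAPE"
        )
    return float(100.0 * np.mean(np.abs(true - pred) / true))


def psnr(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return float(10.0 * math.log10(max_val**2 / mse))


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    max_val: float = 1.0,
    sigma: float = 1.5,
    win_size: int = 11,
    K1: float = 0.01,
    K2: float = 0.03,
) -> float:
    """Mean structural similarity with a Gaussian window.

    Defaults follow the reference formulation: 11x11 Gaussian window with
    sigma 1.5, stabilisers K1=0.01 and K2=0.03, dynamic range ``max_val``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape[:2]) < win_size:
        raise ValueError(
            f"window ({win_size}) larger than image {a.shape[:2]}"
        )
    return float(
        _skimage_ssim(
            a,
            b,
            win_size=win_size,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            K1=K1,
            K2=K2,
            data_range=max_val,
            channel_axis=-1 if a.ndim == 3 else None,
        )
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(_stats.pearsonr(x, y).statistic)


def sample_std(x: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return float(np.std(x, ddof=1))


def relative_reduction(before: float, after: float) -> float:
    """Percent reduction from ``before`` to ``after``: 100*(before-after)/before."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return float(100.0 * (before - after) / before)


def selection_quality_summary(
    selected_bands: Iterable[object],
    per_band_psnr: Mapping[int, float],
    per_band_ssim: Mapping[int, float],
) -> tuple[float, float]:
    """Unweighted mean PSNR and SSIM over the selected non-RGB bands."""
    bands = [int(b) for b in selected_bands if b != "RGB"]
    if not bands:
        raise ValueError("no non-RGB bands selected")
    missing = [b for b in bands if b not in per_band_psnr or b not in per_band_ssim]
    if missing:
        raise KeyError(f"missing conversion metrics for bands {missing}")
    avg_psnr = float(np.mean([per_band_psnr[b] for b in bands]))
    avg_ssim = float(np.mean([per_band_ssim[b] for b in bands]))
    return avg_psnr, avg_ssim


@dataclass
class EvalTable:
    """One experiment table: selection rows for one task.

    ``kind`` is ``"classification"``, ``"estimation"`` or ``"conversion"``;
    ``rows`` is a DataFrame whose columns depend on the kind (``n_images``,
    ``bands``, ``score``, optionally ``avg_psnr`` / ``avg_ssim``).
    """

    kind: str
    rows: pd.DataFrame
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("classification", "estimation", "conversion"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        num = self.rows.select_dtypes(include=[np.number])
        if not np.all(np.isfinite(num.to_numpy(dtype=float, na_value=np.nan))
                      | num.isna().to_numpy()):
            raise ValueError("non-finite metric values in table")


def _pair_gap(tables: list[EvalTable], col: str, best: str) -> float | None:
    scores = [t.rows[col].max() if best == "max" else t.rows[col].min()
              for t in tables]
    if len(scores) != 2:
        return None
    return float(abs(scores[0] - scores[1]))


def build_report(
    eval_tables: Sequence[EvalTable],
    out_dir: str | Path | None = None,
) -> str:
    """Render evaluation tables to CSV plus a markdown summary.

    Classification table pairs (actual vs predicted bands) get a
    max-accuracy difference line; estimation pairs a min-MAPE difference
    line.  Tables with >= 3 rows and conversion-quality columns get
    score-vs-PSNR/SSIM correlations.  Returns the markdown text; when
    ``out_dir`` is given, also writes ``<name>.csv`` per table and
    ``report.md``.
    """
    tables = list(eval_tables)
    if not tables:
        raise ValueError("no tables to report")

    lines: list[str] = ["# Spectral selection report", ""]
    for i, t in enumerate(tables):
        name = t.name or f"table_{i}_{t.kind}"
        lines.append(f"## {name} ({t.kind})")
        lines.append("")
        lines.append(t.rows.to_csv(index=False).strip())
        lines.append("")
        score_col = "score" if "score" in t.rows.columns else None
        if score_col and len(t.rows) >= 3:
            n = t.rows["n_images"] if "n_images" in t.rows.columns else None
            if n is not None and n.nunique() > 1 and t.rows[score_col].nunique() > 1:
                r = pearson_r(n, t.rows[score_col])
                lines.append(f"- score vs n_images correlation: {r:.4f}")
            for col, label in (("avg_psnr", "PSNR"), ("avg_ssim", "SSIM")):
                if col in t.rows.columns:
                    sub = t.rows.dropna(subset=[col])
                    if len(sub) >= 3 and sub[score_col].nunique() > 1 and sub[col].nunique() > 1:
                        r = pearson_r(sub[score_col], sub[col])
                        lines.append(f"- score vs avg {label} correlation: {r:.4f}")
            lines.append("")

    cls = [t for t in tables if t.kind == "classification"]
    est = [t for t in tables if t.kind == "estimation"]
    if len(cls) == 2:
        gap = _pair_gap(cls, "score", "max")
        lines.append(f"- max-accuracy difference (actual vs predicted): {gap:.2f}")
    if len(est) == 2:
        gap = _pair_gap(est, "score", "min")
        lines.append(f"- min-MAPE difference (actual vs predicted): {gap:.2f}")
    for t in est + cls:
        s = t.rows["score"]
        if len(s) >= 2 and s.iloc[0] > 0:
            best = s.max() if t.kind == "classification" else s.min()
            if t.kind == "estimation":
                red = relative_reduction(float(s.iloc[0]), float(s.iloc[1])) \
                    if len(s) > 1 else 0.0
                lines.append(
                    f"- {t.name or t.kind}: one-band MAPE reduction "
                    f"{red:.2f}% (from {s.iloc[0]:.2f} to {s.iloc[1]:.2f})"
                )
    text = "\n".join(lines) + "\n"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(tables):
            name = t.name or f"table_{i}_{t.kind}"
            t.rows.to_csv(out / f"{name}.csv", index=False)
        (out / "report.md").write_text(text)
    return text
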