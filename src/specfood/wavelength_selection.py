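"""Piecewise (stepwise add/remove) search over wavelength subsets.

Training the analysis CNN for every subset of ten candidate wavelengths is
prohibitive, so the band set is grown incrementally: at each cardinality
the single best wavelength is added (sequential forward step), then any
wavelength whose removal strictly improves on the best set already known
at the smaller cardinality is dropped again (floating backward steps).
The RGB image is an implicit member of every set and is never removed.
Every evaluated set is cached and recorded, and the best evaluated set per
cardinality is reported — the row structure of the selection tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .analysis_cnn import AnalysisConfig, predict, stack_inputs, train_classifier, train_estimator
from .dataset_io import floor_kcal, split_train_val
from .spectral_scene import CONVERSION_BANDS

__all__ = [
    "WavelengthSet",
    "SelectionStep",
    "SelectionPath",
    "piecewise_select",
    "evaluate_band_set",
]


@dataclass(frozen=True)
class WavelengthSet:
    """A set of narrow-band wavelengths; the RGB image is always implied."""

    bands: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.bands) - set(CONVERSION_BANDS)
        if bad:
            raise ValueError(f"unsupported wavelengths {sorted(bad)}")

    @classmethod
    def of(cls, *bands: int) -> "WavelengthSet":
        return cls(frozenset(int(b) for b in bands))

    def sorted(self) -> tuple[int, ...]:
        return tuple(sorted(self.bands))

    @property
    def n_images(self) -> int:
        """RGB counts as one image, plus one per wavelength."""
        return 1 + len(self.bands)

    def add(self, band: int) -> "WavelengthSet":
        return WavelengthSet(self.bands | {int(band)})

    def remove(self, band: int) -> "WavelengthSet":
        return WavelengthSet(self.bands - {int(band)})

    def __iter__(self):
        return iter(self.sorted())

    def __len__(self) -> int:
        return len(self.bands)

    def __str__(self) -> str:
        return "+".join(["RGB", *map(str, self.sorted())])


@dataclass(frozen=True)
class SelectionStep:
    bands: tuple[int, ...]
    score: float
    action: str  # "add" or "remove"


@dataclass
class SelectionPath:
    """Record of a piecewise selection run."""

    steps: list[SelectionStep]
    evaluations: dict[tuple[int, ...], float]
    best_per_size: dict[int, tuple[tuple[int, ...], float]]
    objective: str

    @property
    def best(self) -> tuple[tuple[int, ...], float]:
        """Overall best evaluated set under the objective."""
        sign = 1.0 if self.objective == "maximize" else -1.0
        key = max(self.best_per_size,
                  key=lambda k: sign * self.best_per_size[k][1])
        return self.best_per_size[key]

    def to_frame(self) -> pd.DataFrame:
        """Per-cardinality best rows, table style (n_images counts RGB)."""
        rows = []
        for size in sorted(self.best_per_size):
            bands, score = self.best_per_size[size]
            rows.append({"n_images": 1 + size, "bands": bands, "score": score})
        return pd.DataFrame(rows)


def piecewise_select(
    candidates: Iterable[int],
    evaluate: Callable[[WavelengthSet], float],
    objective: str = "maximize",
    max_size: int | None = None,
) -> SelectionPath:
    """Sequential forward floating selection over wavelength subsets.

    ``evaluate`` must be deterministic.  Forward steps continue to
    ``max_size`` even without improvement (every cardinality is recorded);
    a forward step that cannot strictly change the score (an exact tie)
    stops the search.  Ties between candidates are broken toward the
    smaller wavelength.
    """
    cand = sorted({int(b) for b in candidates})
    if not cand:
        raise ValueError("no candidate wavelengths")
    bad = set(cand) - set(CONVERSION_BANDS)
    if bad:
        raise ValueError(f"unsupported wavelengths {sorted(bad)}")
    if max_size is None:
        max_size = len(cand)
    if max_size > len(cand):
        raise ValueError(f"max_size {max_size} exceeds {len(cand)} candidates")
    sign = {"maximize": 1.0, "minimize": -1.0}[objective]

    cache: dict[tuple[int, ...], float] = {}

    def score_of(ws: WavelengthSet) -> float:
        key = ws.sorted()
        if key not in cache:
            cache[key] = float(evaluate(ws))
        return cache[key]

    best_per_size: dict[int, tuple[tuple[int, ...], float]] = {}

    def note(ws: WavelengthSet, s: float) -> None:
        size = len(ws)
        prev = best_per_size.get(size)
        if prev is None or sign * s > sign * prev[1] \
                or (s == prev[1] and ws.sorted() < prev[0]):
            best_per_size[size] = (ws.sorted(), s)

    steps: list[SelectionStep] = []
    current = WavelengthSet()
    cur_score = score_of(current)
    note(current, cur_score)

    while len(current) < max_size:
        # Forward: add the single best wavelength (ties -> smaller nm).
        options = [b for b in cand if b not in current.bands]
        scored = [(score_of(current.add(b)), b) for b in options]
        for s, b in scored:
            note(current.add(b), s)
        best_s, best_b = max(scored, key=lambda t: (sign * t[0], -t[1]))
        if best_s == cur_score:
            break  # no addition on exact ties
        current, cur_score = current.add(best_b), best_s
        steps.append(SelectionStep(current.sorted(), cur_score, "add"))

        # Floating backward: drop any band whose removal strictly improves
        # on the best set known at the smaller cardinality.
        while len(current) > 1:
            prior = best_per_size.get(len(current) - 1)
            rem = [(score_of(current.remove(b)), b) for b in current]
            for s, b in rem:
                note(current.remove(b), s)
            r_s, r_b = max(rem, key=lambda t: (sign * t[0], -t[1]))
            if prior is None or sign * r_s > sign * prior[1]:
                current, cur_score = current.remove(r_b), r_s
                steps.append(SelectionStep(current.sorted(), cur_score, "remove"))
            else:
                break

    return SelectionPath(steps=steps, evaluations=dict(cache),
                         best_per_size=best_per_size, objective=objective)


def evaluate_band_set(
    band_set: WavelengthSet | Sequence[int],
    dataset,
    task: str,
    config: AnalysisConfig,
) -> float:
    """Train the analysis CNN on one band set and score it on validation.

    ``dataset`` is a ``(stacks, records)`` pair; ``task`` is ``"classify"``
    (returns accuracy in percent) or ``"estimate"`` (returns MAPE in
    percent).  The split is stratified per class and, like training,
    deterministic in ``config.seed``.
    """
    if task not in ("classify", "estimate"):
        raise ValueError(f"unknown task {task!r}")
    stacks, records = dataset
    bands = list(band_set)
    inputs = stack_inputs(stacks, bands)  # KeyError names a missing band
    labels = np.asarray([r.class_index for r in records])

    idx_train, idx_val = split_train_val(
        list(range(len(stacks))), seed=config.seed, labels=labels
    )
    Xtr, Xva = inputs[idx_train], inputs[idx_val]

    if task == "classify":
        model = train_classifier(Xtr, labels[idx_train], config)
        pred = np.asarray([predict(model, x) for x in Xva])
        return float(100.0 * np.mean(pred == labels[idx_val]))

    kcal = np.asarray([floor_kcal(r.kcal) for r in records])
    model = train_estimator(Xtr, kcal[idx_train], config)
    pred = np.asarray([predict(model, x) for x in Xva])
    from .metrics_report import mape

    return mape(kcal[idx_val], pred)
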