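"""Dataset persistence, the train/validation split and the calorie floor.

A dataset on disk is one directory per scene (``scene_00000/`` ...) holding
``RGB.tiff`` (16-bit, 3-channel; optionally ``RGB.png`` 8-bit) and one
``band_<nm>.tiff`` (16-bit grayscale) per wavelength, plus a top-level
``manifest.csv`` and, when a catalog is supplied, ``catalog.json``.  Pixel
values in memory are floats in [0, 1]; quantisation to the sensor's 16-bit
depth happens here and only here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .spectral_scene import FoodCatalog, FoodRecord, SpectralStack

__all__ = [
    "Manifest",
    "DatasetIOError",
    "write_dataset",
    "read_dataset",
    "split_train_val",
    "floor_kcal",
    "KCAL_FLOOR",
]

#: Minimum calorie value substituted for zero-calorie items so that the
#: relative (MAPE) loss stays defined.
KCAL_FLOOR: float = 5.0


class DatasetIOError(IOError):
    """Raised for missing or malformed dataset files."""


@dataclass
class Manifest:
    """Tabular index of a dataset directory (one row per scene)."""

    rows: pd.DataFrame
    directory: Path

    def __len__(self) -> int:
        return len(self.rows)


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 65535.0).astype(np.uint16)


def _from_uint16(arr: np.ndarray) -> np.ndarray:
    return arr.astype(np.float64) / 65535.0


def write_dataset(
    stacks: Sequence[SpectralStack],
    records: Sequence[FoodRecord],
    directory: str | Path,
    *,
    catalog: FoodCatalog | None = None,
    rgb_format: str = "tiff",
) -> Manifest:
    """Write scenes and records to ``directory`` and return the manifest.

    ``rgb_format="tiff"`` (default) stores RGB at the full 16-bit depth so
    a write/read round trip preserves every pixel to 1/65535;
    ``rgb_format="png"`` stores 8-bit RGB for viewing convenience.
    """
    if len(stacks) != len(records):
        raise ValueError("stacks and records must have the same length")
    if rgb_format not in ("tiff", "png"):
        raise ValueError("rgb_format must be 'tiff' or 'png'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, (stack, rec) in enumerate(zip(stacks, records)):
        scene = f"scene_{i:05d}"
        scene_dir = directory / scene
        scene_dir.mkdir(exist_ok=True)
        rgb_name = f"RGB.{rgb_format}"
        rgb = stack.images["RGB"]
        if rgb_format == "tiff":
            tifffile.imwrite(scene_dir / rgb_name, _to_uint16(rgb))
        else:
            iio.imwrite(scene_dir / rgb_name,
                        np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))
        row = {
            "scene_id": scene,
            "class_index": rec.class_index,
            "class_name": rec.class_name,
            "kcal": rec.kcal,
            "portion_scale": rec.portion_scale,
            "pose": stack.pose,
            "seed": stack.seed,
            "rgb_path": f"{scene}/{rgb_name}",
        }
        for band in stack.bands:
            name = f"band_{band}.tiff"
            tifffile.imwrite(scene_dir / name, _to_uint16(stack.images[band]))
            row[f"band_{band}_path"] = f"{scene}/{name}"
        rows.append(row)

    frame = pd.DataFrame(rows)
    frame.to_csv(directory / "manifest.csv", index=False)
    if catalog is not None:
        (directory / "catalog.json").write_text(
            json.dumps(catalog.to_dict(), indent=1)
        )
    return Manifest(rows=frame, directory=directory)


def read_dataset(
    directory: str | Path,
) -> tuple[list[SpectralStack], list[FoodRecord]]:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises :class:`DatasetIOError` naming the offending manifest row when a
    referenced image file is missing or a field is malformed.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise DatasetIOError(f"no manifest.csv in {directory}")
    frame = pd.read_csv(manifest_path)

    band_cols = [c for c in frame.columns
                 if c.startswith("band_") and c.endswith("_path")]
    stacks: list[SpectralStack] = []
    records: list[FoodRecord] = []
    for idx, row in frame.iterrows():
        scene = row.get("scene_id", f"row {idx}")
        try:
            kcal = float(row["kcal"])
        except (TypeError, ValueError) as exc:
            raise DatasetIOError(
                f"{scene}: unparseable kcal value {row['kcal']!r}"
            ) from exc
        images: dict[object, np.ndarray] = {}
        rgb_path = directory / str(row["rgb_path"])
        if not rgb_path.exists():
            raise DatasetIOError(f"{scene}: missing image {rgb_path.name}")
        if rgb_path.suffix == ".png":
            images["RGB"] = iio.imread(rgb_path).astype(np.float64) / 255.0
        else:
            images["RGB"] = _from_uint16(tifffile.imread(rgb_path))
        for col in band_cols:
            if pd.isna(row.get(col)):
                continue
            band = int(col[len("band_"):-len("_path")])
            path = directory / str(row[col])
            if not path.exists():
                raise DatasetIOError(f"{scene}: missing image {path.name}")
            images[band] = _from_uint16(tifffile.imread(path))
        H, W = images["RGB"].shape[:2]
        stacks.append(
            SpectralStack(images=images, height=H, width=W,
                          pose=int(row["pose"]), seed=int(row["seed"]))
        )
        records.append(
            FoodRecord(
                class_index=int(row["class_index"]),
                class_name=str(row["class_name"]),
                kcal=kcal,
                portion_scale=float(row.get("portion_scale", 1.0)),
            )
        )
    return stacks, records


def split_train_val(
    items: Sequence,
    seed: int,
    *,
    labels: Sequence[int] | None = None,
) -> tuple[list, list]:
    """Partition items into training and validation sets at a 10:1 ratio.

    The validation share is ``round(n / 11)`` (at least 1), which makes
    |val|/|train| as close to 1/10 as integer counts allow — e.g. 110 items
    split 100/10.  When ``labels`` are given the split is stratified per
    class by largest-remainder allocation.  Deterministic in ``seed``.
    """
    n = len(items)
    if n < 11:
        raise ValueError(f"need at least 11 items to split 10:1, got {n}")
    rng = np.random.default_rng(seed)
    n_val = max(1, round(n / 11))

    if labels is None:
        order = rng.permutation(n)
        val_idx = set(order[:n_val].tolist())
    else:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels length mismatch")
        classes = np.unique(labels)
        quota = {c: n_val * np.sum(labels == c) / n for c in classes}
        counts = {c: int(np.floor(quota[c])) for c in classes}
        short = n_val - sum(counts.values())
        # Largest remainders get the leftover validation slots.
        for c in sorted(classes, key=lambda c: quota[c] - counts[c],
                        reverse=True)[:short]:
            counts[c] += 1
        val_idx = set()
        for c in classes:
            members = np.flatnonzero(labels == c)
            take = min(counts[c], len(members))
            val_idx.update(rng.permutation(members)[:take].tolist())

    train = [items[i] for i in range(n) if i not in val_idx]
    val = [items[i] for i in range(n) if i in val_idx]
    return train, val


def floor_kcal(value: float) -> float:
    """Replace a zero calorie value with the 5 kcal floor; pass others through."""
    if value < 0:
        raise ValueError("kcal must be >= 0")
    return KCAL_FLOOR if value == 0 else float(value)
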