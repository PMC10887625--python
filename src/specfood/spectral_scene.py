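"""Synthetic multispectral food-scene generator.

Emulates a multi-pose narrow-band acquisition rig: each scene is one food
blob on a neutral tray, imaged once under white light (RGB) and once per
narrow-band LED wavelength in the 385-1020 nm range.  Per-class reflectance
spectra drive pixel values; "confusable" class pairs share their visible
spectrum exactly (so white-light RGB images are identical in distribution)
but differ by a planted contrast ``delta`` at chosen UV/NIR wavelengths —
the coffee versus coffee-with-sugar situation that motivates multispectral
food analysis.  Calorie labels are kcal-density times a portion-area proxy,
so caloric estimation requires both identity and size.

All images are float arrays in [0, 1]; 16-bit sensor depth is applied only
at file I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "CONVERSION_BANDS",
    "BACKGROUND_REFLECTANCE",
    "Spectrum",
    "FoodClassSpec",
    "FoodCatalog",
    "SpectralStack",
    "FoodRecord",
    "make_catalog",
    "make_rgb_predictable_catalog",
    "render_band",
    "render_rgb",
    "make_dataset",
    "rgb_response_curves",
    "rgb_triple",
]

#: Narrow-band LED wavelengths (nm) supported for band rendering/conversion.
CONVERSION_BANDS: tuple[int, ...] = (385, 405, 810, 850, 870, 890, 910, 950, 970, 1020)

#: Uniform tray reflectance, identical at every band.
BACKGROUND_REFLECTANCE: float = 0.15

_VISIBLE_EDGE = 700.0  # nm; RGB sensor response is zero at and above this

# Spectrum knot grid: visible knots for the RGB integrals plus the NIR bands.
_VIS_KNOTS = np.arange(385.0, 701.0, 21.0)
_NIR_KNOTS = np.array([760.0, 810.0, 850.0, 870.0, 890.0, 910.0, 950.0, 970.0, 1020.0])
_KNOTS = np.concatenate([_VIS_KNOTS, _NIR_KNOTS])

_RESP_GRID = np.arange(385.0, 700.0, 5.0)


def rgb_response_curves() -> tuple[np.ndarray, np.ndarray]:
    """Fixed visible-band sensor response curves.

    Three Gaussian responses centred at 460/540/620 nm, truncated to
    wavelengths below 700 nm and each normalised to unit mass, so a
    constant unit spectrum integrates to channel value 1.0.  Returns
    ``(grid, responses)`` with ``responses`` of shape (3, len(grid)).
    """
    centers = np.array([460.0, 540.0, 620.0])
    sigma = 35.0
    resp = np.exp(-0.5 * ((_RESP_GRID[None, :] - centers[:, None]) / sigma) ** 2)
    resp /= resp.sum(axis=1, keepdims=True)
    return _RESP_GRID.copy(), resp


_GRID, _RESP = rgb_response_curves()


@dataclass(frozen=True)
class Spectrum:
    """Piecewise-linear reflectance spectrum over 385-1020 nm."""

    wavelengths: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("reflectance values must lie in [0, 1]")
        if len(self.wavelengths) != len(self.values):
            raise ValueError("knot length mismatch")

    def __call__(self, wavelength_nm: float | np.ndarray) -> float | np.ndarray:
        out = np.interp(wavelength_nm, self.wavelengths, self.values)
        return float(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric blob descriptor: ranges for centre jitter, radius and
    eccentricity, sampled per scene."""

    center_jitter: float = 0.06     # fraction of image size
    radius_range: tuple[float, float] = (0.20, 0.30)  # fraction of min(H, W)
    eccentricity_range: tuple[float, float] = (0.0, 0.5)


@dataclass(frozen=True)
class FoodClassSpec:
    """One food class: label, caloric density and reflectance spectrum."""

    name: str
    kcal_density: float  # kcal per reference portion area
    spectrum: Spectrum
    shape: ShapeSpec = field(default_factory=ShapeSpec)

    def __post_init__(self) -> None:
        if self.kcal_density < 0:
            raise ValueError("kcal_density must be >= 0")


@dataclass(frozen=True)
class FoodCatalog:
    """Ordered food classes with planted UV/NIR contrast structure."""

    classes: tuple[FoodClassSpec, ...]
    confusable_pairs: tuple[tuple[int, int], ...]
    planted_bands: tuple[int, ...]
    nir_contrast: float

    def __post_init__(self) -> None:
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        for a, b in self.confusable_pairs:
            sa, sb = self.classes[a].spectrum, self.classes[b].spectrum
            vis = np.asarray([w for w in sa.wavelengths if w < _VISIBLE_EDGE])
            if not np.array_equal(sa(vis), sb(vis)):
                raise ValueError(f"pair ({a},{b}) differs below {_VISIBLE_EDGE} nm")
            for lam in self.planted_bands:
                gap = abs(float(sa(lam)) - float(sb(lam)))
                if not np.isclose(gap, self.nir_contrast):
                    raise ValueError(
                        f"pair ({a},{b}) contrast {gap:.4f} at {lam} nm "
                        f"!= planted {self.nir_contrast}"
                    )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_dict(self) -> dict:
        return {
            "classes": [
                {
                    "name": c.name,
                    "kcal_density": c.kcal_density,
                    "spectrum": {
                        "wavelengths": list(c.spectrum.wavelengths),
                        "values": list(c.spectrum.values),
                    },
                    "shape": {
                        "center_jitter": c.shape.center_jitter,
                        "radius_range": list(c.shape.radius_range),
                        "eccentricity_range": list(c.shape.eccentricity_range),
                    },
                }
                for c in self.classes
            ],
            "confusable_pairs": [list(p) for p in self.confusable_pairs],
            "planted_bands": list(self.planted_bands),
            "nir_contrast": self.nir_contrast,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FoodCatalog":
        classes = tuple(
            FoodClassSpec(
                name=c["name"],
                kcal_density=c["kcal_density"],
                spectrum=Spectrum(
                    tuple(c["spectrum"]["wavelengths"]),
                    tuple(c["spectrum"]["values"]),
                ),
                shape=ShapeSpec(
                    center_jitter=c["shape"]["center_jitter"],
                    radius_range=tuple(c["shape"]["radius_range"]),
                    eccentricity_range=tuple(c["shape"]["eccentricity_range"]),
                ),
            )
            for c in d["classes"]
        )
        return cls(
            classes=classes,
            confusable_pairs=tuple(tuple(p) for p in d["confusable_pairs"]),
            planted_bands=tuple(d["planted_bands"]),
            nir_contrast=d["nir_contrast"],
        )


@dataclass
class SpectralStack:
    """One scene's images keyed by band ('RGB' or wavelength in nm)."""

    images: dict[object, np.ndarray]
    height: int
    width: int
    pose: int
    seed: int

    def __post_init__(self) -> None:
        for key, img in self.images.items():
            if key == "RGB":
                if img.shape != (self.height, self.width, 3):
                    raise ValueError("RGB entry must be HxWx3")
            else:
                if img.shape != (self.height, self.width):
                    raise ValueError(f"band {key} entry must be HxW")

    @property
    def bands(self) -> list[int]:
        return sorted(k for k in self.images if k != "RGB")


@dataclass(frozen=True)
class FoodRecord:
    """Ground truth for one scene: class identity and calorie value."""

    class_index: int
    class_name: str
    kcal: float
    portion_scale: float

    def __post_init__(self) -> None:
        if self.kcal < 0:
            raise ValueError("kcal must be >= 0")
        if self.portion_scale <= 0:
            raise ValueError("portion_scale must be > 0")


def _smooth_curve(rng: np.random.Generator, knots: np.ndarray,
                  lo: float, hi: float) -> np.ndarray:
    """Smooth random reflectance values at the given knots."""
    n_ctrl = 4
    ctrl_x = np.linspace(knots[0], knots[-1], n_ctrl)
    ctrl_y = rng.uniform(lo, hi, size=n_ctrl)
    return np.interp(knots, ctrl_x, ctrl_y)


def make_catalog(
    n_classes: int,
    n_confusable_pairs: int,
    nir_contrast: float,
    kcal_range: tuple[float, float],
    seed: int,
    *,
    planted_bands: Sequence[int] = (850, 970),
) -> FoodCatalog:
    """Build a random food catalog with planted confusable pairs.

    Classes ``(0,1), (2,3), ...`` form the confusable pairs: identical
    reflectance below 700 nm, a contrast of exactly ``nir_contrast`` at each
    planted band.  kcal densities are drawn uniformly from ``kcal_range``.
    Deterministic in ``seed``.
    """
    if n_classes < 2 * n_confusable_pairs:
        raise ValueError("n_classes must be >= 2 * n_confusable_pairs")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not (0 < nir_contrast <= 1):
        raise ValueError("nir_contrast must be in (0, 1]")
    bad = [b for b in planted_bands if b not in CONVERSION_BANDS or b <= _VISIBLE_EDGE]
    if bad:
        raise ValueError(f"planted bands must be NIR conversion bands, got {bad}")

    rng = np.random.default_rng(seed)
    planted = tuple(int(b) for b in planted_bands)
    vis_mask = _KNOTS < _VISIBLE_EDGE
    planted_idx = [int(np.where(_KNOTS == b)[0][0]) for b in planted]

    classes: list[FoodClassSpec] = []
    densities = rng.uniform(kcal_range[0], kcal_range[1], size=n_classes)
    i = 0
    pair_id = 0
    while i < n_classes:
        values = _smooth_curve(rng, _KNOTS, 0.25, 0.85)
        # Keep headroom at planted bands so +delta never clips.
        values[planted_idx] = np.clip(values[planted_idx], 0.05, 0.95 - nir_contrast)
        base = FoodClassSpec(
            name=f"food_{i:02d}",
            kcal_density=float(densities[i]),
            spectrum=Spectrum(tuple(_KNOTS), tuple(np.clip(values, 0, 1))),
        )
        classes.append(base)
        if pair_id < n_confusable_pairs:
            twin = values.copy()
            # Same visible spectrum; shifted by exactly delta at planted bands.
            twin[planted_idx] = values[planted_idx] + nir_contrast
            # Other NIR knots kept equal: the pair differs only where planted.
            classes.append(
                FoodClassSpec(
                    name=f"food_{i:02d}_twin",
                    kcal_density=float(densities[i + 1]),
                    spectrum=Spectrum(tuple(_KNOTS), tuple(np.clip(twin, 0, 1))),
                )
            )
            assert np.array_equal(
                np.asarray(classes[-1].spectrum.values)[vis_mask],
                np.asarray(base.spectrum.values)[vis_mask],
            )
            pair_id += 1
            i += 2
        else:
            i += 1

    pairs = tuple((2 * k, 2 * k + 1) for k in range(n_confusable_pairs))
    return FoodCatalog(
        classes=tuple(classes[:n_classes]),
        confusable_pairs=pairs,
        planted_bands=planted,
        nir_contrast=float(nir_contrast),
    )


def make_rgb_predictable_catalog(
    n_classes: int,
    kcal_range: tuple[float, float],
    seed: int,
    *,
    band: int = 850,
    weights: tuple[float, float, float] = (0.25, 0.45, 0.30),
) -> FoodCatalog:
    """Catalog whose reflectance at ``band`` is an exact linear function of
    the RGB channel values (weights sum to 1, so the tray background maps
    consistently too).  Used to probe conversion-model recovery: the target
    band image equals the same fixed linear combination of the RGB planes
    at every pixel.
    """
    if abs(sum(weights) - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    if band not in CONVERSION_BANDS or band <= _VISIBLE_EDGE:
        raise ValueError(f"band must be an NIR conversion band, got {band}")
    rng = np.random.default_rng(seed)
    band_idx = int(np.where(_KNOTS == band)[0][0])
    w = np.asarray(weights)

    classes = []
    densities = rng.uniform(kcal_range[0], kcal_range[1], size=n_classes)
    for i in range(n_classes):
        values = _smooth_curve(rng, _KNOTS, 0.2, 0.9)
        spec = Spectrum(tuple(_KNOTS), tuple(np.clip(values, 0, 1)))
        values[band_idx] = float(np.dot(w, rgb_triple(spec)))
        classes.append(
            FoodClassSpec(
                name=f"food_{i:02d}",
                kcal_density=float(densities[i]),
                spectrum=Spectrum(tuple(_KNOTS), tuple(np.clip(values, 0, 1))),
            )
        )
    return FoodCatalog(
        classes=tuple(classes),
        confusable_pairs=(),
        planted_bands=(band,),
        nir_contrast=1.0,
    )


def rgb_triple(spec: Spectrum | Callable) -> np.ndarray:
    """Integrate a spectrum against the three sensor response curves."""
    s = np.asarray(spec(_GRID))
    return _RESP @ s


def _scene_geometry(
    spec: FoodClassSpec, pose: int, size: tuple[int, int], seed: int,
    shading: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Food mask and illumination shading for one (seed, pose) scene.

    Both depend only on (class shape spec, pose, size, seed) so every band
    of a scene — and both members of a confusable pair rendered with
    matched pose/seed — share identical geometry.
    """
    H, W = size
    rng = np.random.default_rng([seed, pose, 7919])
    sh = spec.shape
    cy = H * (0.5 + rng.uniform(-sh.center_jitter, sh.center_jitter))
    cx = W * (0.5 + rng.uniform(-sh.center_jitter, sh.center_jitter))
    r = rng.uniform(*sh.radius_range) * min(H, W)
    ecc = rng.uniform(*sh.eccentricity_range)
    ry, rx = r * (1 + ecc / 2), r * (1 - ecc / 2)
    theta = (pose * np.pi / 4) + rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = (yy - cy), (xx - cx)
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / rx
    v = (-st * dx + ct * dy) / ry
    mask = (u**2 + v**2) <= 1.0

    if shading == "flat":
        shade = np.ones((H, W))
    elif shading == "radial":
        # Radial cosine falloff from the pose-shifted illumination centre.
        icy = H * (0.5 + 0.05 * np.sin(pose * np.pi / 4))
        icx = W * (0.5 + 0.05 * np.cos(pose * np.pi / 4))
        rr = np.hypot(yy - icy, xx - icx) / (0.5 * np.hypot(H, W))
        shade = np.cos(np.clip(rr, 0, 1) * (np.pi / 4))
    else:
        raise ValueError(f"unknown shading model {shading!r}")
    return mask, shade


def _check_render_args(wavelength: float | None, noise_sd: float) -> None:
    if wavelength is not None and not (385 <= wavelength <= 1020):
        raise ValueError(f"wavelength {wavelength} nm outside [385, 1020]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")


def render_band(
    spec: FoodClassSpec,
    wavelength: float,
    pose: int,
    noise_sd: float,
    size: tuple[int, int],
    seed: int,
    *,
    background: float = BACKGROUND_REFLECTANCE,
    shading: str = "radial",
) -> np.ndarray:
    """Render one narrow-band image: food = spectrum(lambda) * shading (+noise),
    tray background at a fixed reflectance.  Deterministic in seed."""
    _check_render_args(wavelength, noise_sd)
    H, W = size
    mask, shade = _scene_geometry(spec, pose, size, seed, shading)
    img = np.full((H, W), float(background))
    img[mask] = float(spec.spectrum(wavelength)) * shade[mask]
    if noise_sd > 0:
        rng = np.random.default_rng([seed, pose, int(round(wavelength * 10))])
        img = img + rng.normal(0.0, noise_sd, size=(H, W))
    return np.clip(img, 0.0, 1.0)


def render_rgb(
    spec: FoodClassSpec,
    pose: int,
    noise_sd: float,
    size: tuple[int, int],
    seed: int,
    *,
    background: float = BACKGROUND_REFLECTANCE,
    shading: str = "radial",
) -> np.ndarray:
    """Render the white-light RGB image (HxWx3).

    Each channel integrates the reflectance spectrum against one visible
    sensor response curve (support strictly below 700 nm), so confusable
    pair members with matched geometry are pixel-identical without noise.
    """
    _check_render_args(None, noise_sd)
    H, W = size
    mask, shade = _scene_geometry(spec, pose, size, seed, shading)
    tri = rgb_triple(spec.spectrum)
    img = np.full((H, W, 3), float(background))
    img[mask, :] = shade[mask, None] * tri[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng([seed, pose, 3])
        img = img + rng.normal(0.0, noise_sd, size=(H, W, 3))
    return np.clip(img, 0.0, 1.0)


def make_dataset(
    catalog: FoodCatalog,
    n_per_class: int,
    band_list: Sequence[int],
    poses: int,
    noise_sd: float,
    size: tuple[int, int],
    seed: int,
    *,
    shading: str = "radial",
    reference_area_frac: float = 0.2,
) -> tuple[list[SpectralStack], list[FoodRecord]]:
    """Generate ``n_classes * n_per_class`` scenes.

    Each stack holds the RGB entry plus one entry per requested band; each
    record's kcal is ``kcal_density * (food-pixel count / reference area)``
    where the reference area is ``reference_area_frac * H * W``.
    Deterministic in ``seed``; scene seeds are derived per (class, repeat).
    """
    if len(band_list) == 0:
        raise ValueError("band_list must not be empty")
    bad = [b for b in band_list if b not in CONVERSION_BANDS]
    if bad:
        raise ValueError(f"unsupported bands {bad}; choose from {CONVERSION_BANDS}")
    if poses < 1:
        raise ValueError("poses must be >= 1")

    H, W = size
    ref_area = reference_area_frac * H * W
    stacks: list[SpectralStack] = []
    records: list[FoodRecord] = []
    for ci, spec in enumerate(catalog.classes):
        for j in range(n_per_class):
            ss = np.random.SeedSequence([int(seed), ci, j])
            scene_seed = int(ss.generate_state(1)[0] % (2**31))
            pose = j % poses
            images: dict[object, np.ndarray] = {
                "RGB": render_rgb(spec, pose, noise_sd, size, scene_seed,
                                  shading=shading)
            }
            for b in band_list:
                images[int(b)] = render_band(spec, b, pose, noise_sd, size,
                                             scene_seed, shading=shading)
            mask, _ = _scene_geometry(spec, pose, size, scene_seed, shading)
            portion = float(mask.sum()) / ref_area
            stacks.append(SpectralStack(images=images, height=H, width=W,
                                        pose=pose, seed=scene_seed))
            records.append(
                FoodRecord(
                    class_index=ci,
                    class_name=spec.name,
                    kcal=float(spec.kcal_density * portion),
                    portion_scale=portion,
                )
            )
    return stacks, records
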