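"""Simulator contracts: planted spectral structure, determinism, rendering."""

import numpy as np
import pytest

from specfood.spectral_scene import (
    CONVERSION_BANDS,
    BACKGROUND_REFLECTANCE,
    FoodRecord,
    Spectrum,
    _scene_geometry,
    make_catalog,
    make_dataset,
    make_rgb_predictable_catalog,
    render_band,
    render_rgb,
    rgb_triple,
)


class TestMakeCatalog:
    def test_pair_structure(self, catalog):
        a, b = (catalog.classes[i] for i in catalog.confusable_pairs[0])
        vis = np.arange(385, 700, 5.0)
        assert np.array_equal(a.spectrum(vis), b.spectrum(vis))
        for lam in catalog.planted_bands:
            assert abs(a.spectrum(lam) - b.spectrum(lam)) == pytest.approx(0.3)

    def test_determinism(self):
        c1 = make_catalog(4, 1, 0.3, (10, 400), seed=1)
        c2 = make_catalog(4, 1, 0.3, (10, 400), seed=1)
        assert c1.to_dict() == c2.to_dict()
        c3 = make_catalog(4, 1, 0.3, (10, 400), seed=2)
        assert c1.to_dict() != c3.to_dict()

    def test_spectra_bounded(self, catalog):
        lam = np.linspace(385, 1020, 200)
        for c in catalog.classes:
            v = c.spectrum(lam)
            assert np.all((v >= 0) & (v <= 1))

    @pytest.mark.parametrize(
        "args", [(2, 2, 0.3), (3, 1, 0.0), (3, 1, 1.5), (1, 0, 0.3)]
    )
    def test_invalid_arguments(self, args):
        n, p, d = args
        with pytest.raises(ValueError):
            make_catalog(n, p, d, (10, 400), seed=0)


class TestRenderBand:
    def test_noiseless_flat_shading_is_spectrum_value(self, catalog):
        spec = catalog.classes[0]
        lam = 850
        img = render_band(spec, lam, 0, 0.0, (48, 48), seed=9, shading="flat")
        mask, _ = _scene_geometry(spec, 0, (48, 48), 9, "flat")
        assert np.allclose(img[mask], spec.spectrum(lam))
        assert np.allclose(img[~mask], BACKGROUND_REFLECTANCE)

    def test_determinism_and_noise(self, catalog):
        spec = catalog.classes[2]
        a = render_band(spec, 970, 1, 0.05, (32, 32), seed=4)
        b = render_band(spec, 970, 1, 0.05, (32, 32), seed=4)
        c = render_band(spec, 970, 1, 0.05, (32, 32), seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert a.min() >= 0 and a.max() <= 1

    def test_wavelength_out_of_range(self, catalog):
        with pytest.raises(ValueError, match="wavelength"):
            render_band(catalog.classes[0], 300, 0, 0.0, (32, 32), seed=0)


class TestRenderRgb:
    def test_confusable_pair_identical_noiseless(self, catalog):
        a, b = (catalog.classes[i] for i in catalog.confusable_pairs[0])
        for seed in range(20):
            ra = render_rgb(a, seed % 4, 0.0, (32, 32), seed)
            rb = render_rgb(b, seed % 4, 0.0, (32, 32), seed)
            assert np.abs(ra - rb).max() == 0.0

    def test_unit_spectrum_gives_unit_channels(self):
        from specfood.spectral_scene import _KNOTS, FoodClassSpec

        flat = FoodClassSpec(
            name="white", kcal_density=1.0,
            spectrum=Spectrum(tuple(_KNOTS), tuple(np.ones(len(_KNOTS)))),
        )
        img = render_rgb(flat, 0, 0.0, (32, 32), seed=1, shading="flat")
        mask, _ = _scene_geometry(flat, 0, (32, 32), 1, "flat")
        assert np.allclose(img[mask], 1.0)

    def test_planted_band_separates_pair(self, catalog):
        a, b = (catalog.classes[i] for i in catalog.confusable_pairs[0])
        lam = catalog.planted_bands[0]
        diffs = []
        for seed in range(10):
            ba = render_band(a, lam, 0, 0.0, (32, 32), seed)
            bb = render_band(b, lam, 0, 0.0, (32, 32), seed)
            mask, _ = _scene_geometry(a, 0, (32, 32), seed, "radial")
            diffs.append(np.abs(ba - bb)[mask].mean())
        assert np.mean(diffs) >= catalog.nir_contrast / 2


class TestMakeDataset:
    def test_counts_and_keys(self, small_dataset):
        stacks, records = small_dataset
        assert len(stacks) == len(records) == 20
        for s in stacks:
            assert set(s.images) == {"RGB", 850, 970}
            assert s.images["RGB"].shape == (64, 64, 3)
            assert s.images[850].shape == (64, 64)

    def test_kcal_scales_with_portion(self, small_dataset):
        _, records = small_dataset
        by_class = {}
        for r in records:
            by_class.setdefault(r.class_index, []).append(r)
        for rs in by_class.values():
            dens = {r.kcal / r.portion_scale for r in rs}
            assert max(dens) - min(dens) < 1e-9  # kcal ∝ portion area

    def test_determinism_and_seed_separation(self, catalog):
        s1, r1 = make_dataset(catalog, 2, [850], 2, 0.02, (32, 32), seed=5)
        s2, r2 = make_dataset(catalog, 2, [850], 2, 0.02, (32, 32), seed=5)
        s3, _ = make_dataset(catalog, 2, [850], 2, 0.02, (32, 32), seed=6)
        assert all(np.array_equal(a.images["RGB"], b.images["RGB"])
                   for a, b in zip(s1, s2))
        assert r1 == r2
        assert not np.array_equal(s1[0].images["RGB"], s3[0].images["RGB"])
        assert [r.class_index for r in r1] == [r.class_index for r in r2]

    def test_band_validation(self, catalog):
        with pytest.raises(ValueError):
            make_dataset(catalog, 1, [], 1, 0.0, (32, 32), seed=0)
        with pytest.raises(ValueError):
            make_dataset(catalog, 1, [700], 1, 0.0, (32, 32), seed=0)


class TestLinearBandCatalog:
    def test_band_is_exact_linear_map_of_rgb(self):
        cat = make_rgb_predictable_catalog(3, (10, 400), seed=2, band=850)
        w = np.array([0.25, 0.45, 0.30])
        for spec in cat.classes:
            assert spec.spectrum(850) == pytest.approx(
                float(w @ rgb_triple(spec.spectrum)), abs=1e-12
            )
        # pixel-level: band image equals w . RGB image everywhere
        spec = cat.classes[0]
        rgb = render_rgb(spec, 0, 0.0, (32, 32), seed=3)
        band = render_band(spec, 850, 0, 0.0, (32, 32), seed=3)
        assert np.allclose(band, rgb @ w, atol=1e-12)


class TestFoodRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            FoodRecord(0, "x", kcal=-1.0, portion_scale=1.0)
        with pytest.raises(ValueError):
            FoodRecord(0, "x", kcal=1.0, portion_scale=0.0)
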