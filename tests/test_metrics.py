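"""Metric definitions against independent brute-force oracles and the
published reference tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfood import reference
from specfood.metrics_report import (
    EvalTable,
    build_report,
    mape,
    pearson_r,
    psnr,
    relative_reduction,
    sample_std,
    selection_quality_summary,
    ssim,
)


def ssim_bruteforce(a, b, max_val=1.0, sigma=1.5, win=11, K1=0.01, K2=0.03):
    """Naive double-loop SSIM: normalised Gaussian window, weighted
    (non-sample) moments, border cropped to valid windows."""
    r = win // 2
    ax = np.arange(win) - r
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    k /= k.sum()
    C1, C2 = (K1 * max_val) ** 2, (K2 * max_val) ** 2
    H, W = a.shape
    vals = []
    for i in range(r, H - r):
        for j in range(r, W - r):
            wa = a[i - r:i + r + 1, j - r:j + r + 1]
            wb = b[i - r:i + r + 1, j - r:j + r + 1]
            mua, mub = (k * wa).sum(), (k * wb).sum()
            va = (k * wa * wa).sum() - mua**2
            vb = (k * wb * wb).sum() - mub**2
            cab = (k * wa * wb).sum() - mua * mub
            vals.append(
                ((2 * mua * mub + C1) * (2 * cab + C2))
                / ((mua**2 + mub**2 + C1) * (va + vb + C2))
            )
    return float(np.mean(vals))


class TestMape:
    @pytest.mark.parametrize(
        "true,pred,expected",
        [([50.0], [60.0], 20.0), ([5.0], [0.0], 100.0), ([80.0, 40.0], [80.0, 40.0], 0.0)],
    )
    def test_worked_examples(self, true, pred, expected):
        assert mape(true, pred) == pytest.approx(expected)

    def test_rejects_nonpositive_truth(self):
        with pytest.raises(ValueError, match="floor"):
            mape([0.0, 10.0], [5.0, 10.0])

    @given(
        st.lists(st.floats(1.0, 1e3), min_size=1, max_size=20),
        st.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, true, c):
        rng = np.random.default_rng(0)
        pred = np.asarray(true) * rng.uniform(0.5, 1.5, len(true))
        a = mape(true, pred)
        b = mape(np.asarray(true) * c, pred * c)
        assert a == pytest.approx(b, rel=1e-9)


class TestPsnr:
    def test_identical_images_are_infinite(self, rng):
        a = rng.random((16, 16))
        assert math.isinf(psnr(a, a.copy()))

    def test_uniform_difference(self):
        a = np.zeros((8, 8))
        assert psnr(a, a + 0.1) == pytest.approx(20.0)

    def test_symmetry_and_shape_check(self, rng):
        a, b = rng.random((12, 12)), rng.random((12, 12))
        assert psnr(a, b) == pytest.approx(psnr(b, a))
        with pytest.raises(ValueError):
            psnr(a, b[:6])


class TestSsim:
    def test_identical_images(self, rng):
        a = rng.random((32, 32))
        assert ssim(a, a.copy()) == pytest.approx(1.0)

    def test_inverted_high_contrast_pattern_scores_low(self):
        rng = np.random.default_rng(7)
        a = (rng.random((32, 32)) > 0.5).astype(float)
        assert ssim(a, 1.0 - a) < 0.5

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = rng.random((32, 32))
            b = np.clip(a + rng.normal(0, rng.uniform(0.02, 0.3), (32, 32)), 0, 1)
            assert ssim(a, b) == pytest.approx(ssim_bruteforce(a, b), abs=1e-8)

    def test_window_must_fit(self, rng):
        with pytest.raises(ValueError, match="window"):
            ssim(rng.random((8, 8)), rng.random((8, 8)))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(deadline=None, max_examples=50)
    def test_affine_invariance(self, slope, intercept):
        rng = np.random.default_rng(3)
        x = rng.random(15)
        y = rng.random(15)
        r0 = pearson_r(x, y)
        r1 = pearson_r(slope * x + intercept, y)
        assert r0 == pytest.approx(r1, abs=1e-9)


class TestSummaryStats:
    def test_sample_std_uses_n_minus_1(self):
        x = [1.0, 2.0, 3.0]
        assert sample_std(x) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sample_std([4.0])

    def test_constant_list_is_zero(self):
        assert sample_std([2.5] * 6) == 0.0

    def test_relative_reduction(self):
        assert relative_reduction(40.0, 30.0) == pytest.approx(25.0)
        assert relative_reduction(7.0, 7.0) == 0.0
        with pytest.raises(ValueError):
            relative_reduction(0.0, 1.0)


class TestSelectionQualitySummary:
    def test_single_band_passthrough(self):
        ref = reference.conversion_quality().set_index("wavelength")
        p, s = selection_quality_summary([950], ref["psnr"], ref["ssim"])
        assert p == pytest.approx(29.38)
        assert s == pytest.approx(0.876)

    def test_rgb_excluded_and_missing_band_raises(self):
        ref = reference.conversion_quality().set_index("wavelength")
        p, _ = selection_quality_summary(["RGB", 385, 870], ref["psnr"], ref["ssim"])
        assert p == pytest.approx((34.28 + 30.15) / 2)
        with pytest.raises(KeyError):
            selection_quality_summary([850], {}, {})


class TestBuildReport:
    def test_paired_tables_produce_gap_lines(self):
        cls_a = EvalTable("classification", reference.classification_actual(),
                          name="cls_actual")
        cls_p = EvalTable("classification", reference.classification_predicted(),
                          name="cls_predicted")
        est_a = EvalTable("estimation", reference.estimation_actual(),
                          name="est_actual")
        est_p = EvalTable("estimation", reference.estimation_predicted(),
                          name="est_predicted")
        text = build_report([cls_a, cls_p, est_a, est_p])
        assert "max-accuracy difference" in text
        assert "1.21" in text
        assert "min-MAPE difference" in text
        assert "0.46" in text

    def test_writes_csvs(self, tmp_path):
        t = EvalTable("conversion", reference.conversion_quality(), name="conv")
        build_report([t], out_dir=tmp_path)
        assert (tmp_path / "conv.csv").exists()
        assert (tmp_path / "report.md").exists()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_report([])
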