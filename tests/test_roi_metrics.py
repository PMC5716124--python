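"""ROI metric tests: brute-force per-pixel oracle equivalence, frozen
arithmetic examples, and invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from cbctiq.roi_metrics import (
    CircleROI,
    RingROI,
    aggregate_slices,
    cnr,
    noise_metric,
    roi_mask,
    roi_stats,
    standard_water_rois,
    uniformity,
)


def brute_force_stats(image, mask):
    """Independent oracle: plain-Python per-pixel mean and sample SD."""
    vals = [float(image[i, j]) for i in range(image.shape[0])
            for j in range(image.shape[1]) if mask[i, j]]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var), n


def exact_region(mask, mean, sd, rng):
    """Fill a masked region with exact sample mean and sample SD."""
    n = int(mask.sum())
    pattern = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    if n % 2:
        pattern[-1] = 0.0
    pattern -= pattern.mean()
    pattern /= pattern.std(ddof=1)
    return mean + sd * pattern


class TestMasks:
    def test_circle_area_analytic(self):
        m = roi_mask(CircleROI((0, 0), 25.0), (128, 128), 1.0)
        analytic = math.pi * 12.5**2
        assert abs(int(m.sum()) - analytic) / analytic < 0.02

    def test_ring_area_analytic(self):
        m = roi_mask(RingROI((0, 0), 40.0, 10.0), (128, 128), 1.0)
        analytic = math.pi * (30.0**2 - 20.0**2)
        assert abs(int(m.sum()) - analytic) / analytic < 0.02

    def test_standard_water_set_geometry(self):
        rois = standard_water_rois()
        shape, pix = (256, 256), 274.0 / 256
        masks = {k: roi_mask(r, shape, pix) for k, r in rois.items()}
        # disjointness of centre and periphery; air outside the phantom
        assert not (masks["center"] & masks["periphery"]).any()
        X, Y = np.meshgrid(*[(np.arange(256) - 127.5) * pix] * 2)
        r = np.hypot(X, Y)
        assert r[masks["air"]].min() > 110.0
        assert r[masks["water"]].max() < 110.0

    def test_zero_thickness_ring_rejected(self):
        with pytest.raises(ValueError):
            RingROI((0, 0), 10.0, 0.0)

    def test_roi_outside_reconstruction_circle_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            roi_mask(CircleROI((120.0, 0.0), 30.0), (128, 128), 1.0)

    def test_tiny_roi_statistics_refused(self):
        img = np.ones((64, 64))
        m = roi_mask(CircleROI((0, 0), 3.0), (64, 64), 1.0)
        with pytest.raises(ValueError, match="pixels"):
            roi_stats(img, m)


class TestBruteForceOracle:
    def test_metrics_match_per_pixel_recomputation(self):
        # random 16x16 images and masks; implementations must agree with the
        # plain-Python oracle to 1e-12 relative
        rng = np.random.default_rng(5)
        for _ in range(10):
            img = rng.normal(100.0, 5.0, size=(16, 16))
            masks = []
            for _ in range(4):
                m = rng.random((16, 16)) < 0.5
                while m.sum() < 25:
                    m |= rng.random((16, 16)) < 0.5
                masks.append(m)
            mc, mp, mw, ma = masks
            img_w = img.copy()
            img_w[ma] -= 60.0  # ensure positive water-air contrast

            means, sds = {}, {}
            for key, m in zip("cpwa", masks):
                mean, sd, _ = brute_force_stats(img_w, m)
                means[key], sds[key] = mean, sd

            expect_uni = (1 - abs(means["c"] - means["p"]) / (means["w"] - means["a"])) * 100
            expect_noise = sds["w"] / (means["w"] - means["a"]) * 100
            expect_cnr = abs(means["c"] - means["p"]) / (0.5 * (sds["c"] + sds["p"]))

            assert uniformity(img_w, mc, mp, mw, ma) == pytest.approx(expect_uni, rel=1e-12)
            assert noise_metric(img_w, mw, ma) == pytest.approx(expect_noise, rel=1e-12)
            assert cnr(img_w, mc, mp) == pytest.approx(expect_cnr, rel=1e-12)


class TestUniformity:
    def _masks(self):
        m = np.zeros((40, 40), dtype=bool)
        blocks = {}
        for k, (r0, c0) in zip("cpwa", [(0, 0), (0, 20), (20, 0), (20, 20)]):
            b = m.copy()
            b[r0 : r0 + 10, c0 : c0 + 10] = True
            blocks[k] = b
        return blocks

    def test_frozen_arithmetic_example(self):
        # means: centre 90, periphery 100, water 95, air 5 -> 88.889
        b = self._masks()
        img = np.zeros((40, 40))
        img[b["c"]], img[b["p"]], img[b["w"]], img[b["a"]] = 90, 100, 95, 5
        val = uniformity(img, b["c"], b["p"], b["w"], b["a"])
        assert val == pytest.approx(88.888888888, abs=1e-6)

    def test_uniform_slice_scores_100(self):
        b = self._masks()
        img = np.full((40, 40), 7.0)
        img[b["a"]] = 0.0
        assert uniformity(img, b["c"], b["p"], b["w"], b["a"]) == pytest.approx(100.0)

    def test_zero_contrast_rejected(self):
        b = self._masks()
        img = np.ones((40, 40))
        with pytest.raises(ValueError, match="contrast"):
            uniformity(img, b["c"], b["p"], b["w"], b["a"])


class TestNoise:
    def test_frozen_arithmetic_example(self):
        # water SD exactly 2 around mean 105, air mean 5 -> 2.0
        rng = np.random.default_rng(0)
        img = np.zeros((40, 40))
        wm = np.zeros((40, 40), dtype=bool)
        wm[:20, :20] = True
        am = np.zeros((40, 40), dtype=bool)
        am[20:, 20:] = True
        img[wm] = exact_region(wm, 105.0, 2.0, rng)
        img[am] = 5.0
        assert noise_metric(img, wm, am) == pytest.approx(2.0, rel=1e-12)

    def test_constant_water_is_zero_noise(self):
        img = np.zeros((40, 40))
        wm = np.zeros((40, 40), dtype=bool)
        wm[:20] = True
        am = ~wm
        img[wm] = 10.0
        assert noise_metric(img, wm, am) == 0.0

    @hsettings(derandomize=True, max_examples=25)
    @given(gain=st.floats(0.1, 50), offset=st.floats(-100, 100))
    def test_invariant_under_linear_rescale(self, gain, offset):
        rng = np.random.default_rng(2)
        img = rng.normal(50, 3, size=(30, 30))
        wm = np.zeros((30, 30), dtype=bool)
        wm[:15] = True
        am = ~wm
        img[am] -= 40
        v1 = noise_metric(img, wm, am)
        v2 = noise_metric(gain * img + offset, wm, am)
        assert v2 == pytest.approx(v1, rel=1e-9)


class TestCNR:
    def _regions(self):
        im = np.zeros((40, 40), dtype=bool)
        im[:20, :20] = True
        bm = np.zeros((40, 40), dtype=bool)
        bm[20:, 20:] = True
        return im, bm

    def test_frozen_arithmetic_example(self):
        # means 120/100, SDs 4/6 -> CNR = 20 / 5 = 4.0
        rng = np.random.default_rng(1)
        im, bm = self._regions()
        img = np.zeros((40, 40))
        img[im] = exact_region(im, 120.0, 4.0, rng)
        img[bm] = exact_region(bm, 100.0, 6.0, rng)
        assert cnr(img, im, bm) == pytest.approx(4.0, rel=1e-12)

    def test_equal_means_zero(self):
        rng = np.random.default_rng(3)
        im, bm = self._regions()
        img = np.zeros((40, 40))
        img[im] = exact_region(im, 50.0, 2.0, rng)
        img[bm] = exact_region(bm, 50.0, 2.0, rng)
        assert cnr(img, im, bm) == pytest.approx(0.0, abs=1e-10)

    def test_offset_invariance(self):
        rng = np.random.default_rng(4)
        im, bm = self._regions()
        img = rng.normal(100, 4, (40, 40))
        assert cnr(img + 37.0, im, bm) == pytest.approx(cnr(img, im, bm), rel=1e-9)

    def test_noiseless_unequal_means_flagged(self):
        im, bm = self._regions()
        img = np.zeros((40, 40))
        img[im] = 2.0
        with pytest.raises(ValueError, match="noiseless"):
            cnr(img, im, bm)


class TestAggregation:
    def test_identical_slices_zero_sd(self):
        m = aggregate_slices([4.2] * 6)
        assert m.mean == pytest.approx(4.2)
        assert m.sd == 0.0

    def test_frozen_hand_arithmetic(self):
        m = aggregate_slices([1, 2, 3, 4, 5, 6])
        assert m.mean == pytest.approx(3.5)
        assert m.sd == pytest.approx(1.8708286934, abs=1e-9)

    def test_single_slice_degenerate(self):
        with pytest.warns(UserWarning, match="SD undefined"):
            m = aggregate_slices([2.0], n_slices=1)
        assert (m.mean, m.sd) == (2.0, 0.0)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            aggregate_slices([1.0, 2.0], n_slices=6)
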