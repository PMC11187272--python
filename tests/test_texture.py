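"""Texture module: gray–gradient co-occurrence traits vs naive oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from soyield.segmentation import PlantImage, PlantMask
from soyield.texture import (
    GGCM,
    TEXTURE_KEYS,
    build_ggcm,
    gradient_magnitude,
    quantize_pair,
    side_texture,
    texture_features,
    texture_traits,
    to_intensity,
)

from conftest import random_view
from oracles import naive_ggcm, naive_texture_pipeline, naive_traits


def constant_view(value=(30, 60, 90), h=32, w=32):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = value
    return PlantImage(img), PlantMask(np.ones((h, w), dtype=bool))


class TestIntensity:
    def test_channel_mean(self):
        img, mask = constant_view((30, 60, 90))
        assert np.allclose(to_intensity(img, mask), 60.0)

    def test_gray_input_identity(self):
        img, mask = constant_view((77, 77, 77))
        assert np.allclose(to_intensity(img, mask), 77.0)

    def test_matches_naive_loop(self, rng):
        img, mask = random_view(rng)
        gray = to_intensity(img, mask)
        naive = img.pixels.astype(float).sum(axis=2) / 3.0
        assert np.allclose(gray, naive, atol=1e-12)


class TestGradient:
    def test_constant_is_zero(self):
        assert np.allclose(gradient_magnitude(np.full((8, 8), 5.0)), 0.0)

    def test_step_edge_sobel_magnitude(self):
        h = 10.0
        img = np.zeros((9, 9))
        img[:, 5:] = h
        grad = gradient_magnitude(img)
        # interior columns adjacent to the step see the full 4h response
        assert np.allclose(grad[2:-2, 4], 4 * h)
        assert np.allclose(grad[2:-2, 5], 4 * h)
        assert np.allclose(grad[2:-2, 2], 0.0)

    def test_rotation_preserves_magnitudes(self, rng):
        img = rng.random((16, 16))
        a = np.sort(gradient_magnitude(img).ravel())
        b = np.sort(gradient_magnitude(np.rot90(img)).ravel())
        assert np.allclose(a, b)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.zeros((2, 5)))


class TestQuantize:
    def test_full_range_occupies_all_levels(self):
        gray = np.arange(256, dtype=float).reshape(16, 16)
        mask = PlantMask(np.ones((16, 16), dtype=bool))
        pair = quantize_pair(gray, np.zeros_like(gray), mask)
        assert set(np.unique(pair.grayQ[mask.pixels])) == set(range(1, 17))

    def test_constant_maps_to_level_one(self):
        mask = PlantMask(np.ones((8, 8), dtype=bool))
        pair = quantize_pair(np.full((8, 8), 3.0), np.full((8, 8), 9.0), mask)
        assert (pair.grayQ[mask.pixels] == 1).all()
        assert (pair.gradQ[mask.pixels] == 1).all()

    def test_count_conservation(self, rng):
        img, mask = random_view(rng)
        gray = to_intensity(img, mask)
        pair = quantize_pair(gray, gradient_magnitude(gray), mask)
        ggcm = build_ggcm(pair)
        assert ggcm.H.sum() == mask.foreground_count
        assert abs(ggcm.p.sum() - 1.0) < 1e-9


class TestGGCM:
    def test_constant_image_single_cell(self):
        img, mask = constant_view()
        gray = to_intensity(img, mask)
        ggcm = build_ggcm(quantize_pair(gray, gradient_magnitude(gray), mask))
        assert ggcm.H[0, 0] == mask.foreground_count
        assert ggcm.p[0, 0] == 1.0
        assert ggcm.H.sum() == ggcm.H[0, 0]

    def test_toy_counting(self):
        from soyield.texture import GrayGradientPair

        grayQ = np.array([[1, 1], [2, 1]])
        gradQ = np.array([[1, 2], [1, 1]])
        mask = PlantMask(np.ones((2, 2), dtype=bool))
        ggcm = build_ggcm(GrayGradientPair(grayQ=grayQ, gradQ=gradQ, mask=mask))
        assert ggcm.H[0, 0] == 2 and ggcm.H[0, 1] == 1 and ggcm.H[1, 0] == 1
        assert np.allclose(
            [ggcm.p[0, 0], ggcm.p[0, 1], ggcm.p[1, 0]], [0.5, 0.25, 0.25]
        )

    def test_matches_naive_tally(self, rng):
        img, mask = random_view(rng)
        gray = to_intensity(img, mask)
        pair = quantize_pair(gray, gradient_magnitude(gray), mask)
        H_naive, n = naive_ggcm(pair.grayQ, pair.gradQ, mask.pixels)
        ggcm = build_ggcm(pair)
        assert (ggcm.H == np.asarray(H_naive)).all()
        assert n == ggcm.n_pixels


class TestTraits:
    def test_constant_image_degenerate_values(self):
        img, mask = constant_view()
        feats = texture_features(img, mask)
        assert feats["T3"] == 1.0
        assert feats["T5"] == feats["T6"] == feats["T7"] == 0.0
        assert feats["T8"] == 0.0
        assert feats["T9"] == 1.0
        assert feats["Hhist"] == 0.0
        assert feats["T10"] == 0.0  # degenerate marginals flagged as 0

    def test_toy_three_cell_hand_arithmetic(self):
        H = np.zeros((16, 16), dtype=np.int64)
        H[0, 0], H[0, 1], H[1, 0] = 2, 1, 1
        ggcm = GGCM(H=H, p=H / 4, n_pixels=4)
        feats = texture_traits(ggcm, np.array([0.0, 0.0, 255.0, 255.0]))
        assert feats["T3"] == pytest.approx(0.375)
        assert feats["T8"] == pytest.approx(0.5)
        assert feats["T9"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(25))
    def test_full_bank_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img, mask = random_view(rng)
        feats = texture_features(img, mask)
        expected = naive_texture_pipeline(img.pixels, mask.pixels)
        for key in TEXTURE_KEYS:
            assert feats[key] == pytest.approx(expected[key], abs=1e-9), key

    def test_invariant_bounds(self, rng):
        for _ in range(20):
            img, mask = random_view(rng)
            f = texture_features(img, mask)
            assert 1 / 256 - 1e-12 <= f["T3"] <= 1.0
            assert f["T7"] <= np.log(256) + 1e-9
            assert 0 < f["T9"] <= 1.0 + 1e-12
            assert abs(f["T10"]) <= 1 + 1e-9
            assert f["T5"] >= 0 and f["T6"] >= 0 and f["sigma1"] >= 0 and f["sigma2"] >= 0

    def test_t8_t9_move_oppositely(self):
        t8s, t9s = [], []
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            img, mask = random_view(rng)
            f = texture_features(img, mask)
            t8s.append(f["T8"])
            t9s.append(f["T9"])
        rho = spearmanr(t8s, t9s).statistic
        assert rho < 0

    def test_gradient_traits_shift_invariant(self, rng):
        img, mask = random_view(rng)
        px = np.clip(img.pixels.astype(int), 0, 200).astype(np.uint8)  # headroom
        shifted = PlantImage(px + np.uint8(50))
        f0 = texture_features(PlantImage(px), mask)
        f1 = texture_features(shifted, mask)
        for key in ("T1", "T2", "mu2", "T5", "sigma2"):
            assert f0[key] == pytest.approx(f1[key], rel=1e-9), key


class TestSideAverage:
    def test_identity_and_permutation(self, rng):
        img, mask = random_view(rng)
        f = texture_features(img, mask)
        avg = side_texture([f] * 6)
        for k in TEXTURE_KEYS:
            assert avg[k] == pytest.approx(f[k], rel=1e-12)
        views = []
        for s in range(6):
            i, m = random_view(np.random.default_rng(s))
            views.append(texture_features(i, m))
        a = side_texture(views)
        b = side_texture(views[::-1])
        for k in TEXTURE_KEYS:
            assert a[k] == pytest.approx(b[k])

    def test_mean_matches_naive_loop(self):
        views = []
        for s in range(6):
            i, m = random_view(np.random.default_rng(50 + s))
            views.append(texture_features(i, m))
        avg = side_texture(views)
        for k in TEXTURE_KEYS:
            assert avg[k] == pytest.approx(sum(v[k] for v in views) / 6)

    def test_wrong_view_count_rejected(self, rng):
        img, mask = random_view(rng)
        f = texture_features(img, mask)
        with pytest.raises(ValueError):
            side_texture([f] * 5)
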