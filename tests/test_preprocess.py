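"""Hair removal chain: grayscale, black top-hat, detection, inpainting."""

import numpy as np
import pytest

from lesionseg import fixtures as fx
from lesionseg import preprocess as pp


def brute_force_closing(x: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Sliding-window dilation followed by erosion, symmetric padding."""
    k = se.shape[0] // 2
    xp = np.pad(x.astype(np.int32), k, mode="symmetric")
    h, w = x.shape

    def dilate(a):
        out = np.empty((h, w), dtype=np.int32)
        ap = np.pad(a, k, mode="symmetric")
        for i in range(h):
            for j in range(w):
                out[i, j] = ap[i:i + se.shape[0], j:j + se.shape[1]][se].max()
        return out

    def erode(a):
        out = np.empty((h, w), dtype=np.int32)
        ap = np.pad(a, k, mode="symmetric")
        for i in range(h):
            for j in range(w):
                out[i, j] = ap[i:i + se.shape[0], j:j + se.shape[1]][se].min()
        return out

    return erode(dilate(x.astype(np.int32)))


class TestToGrayscale:
    def test_equal_channels_identity(self):
        img = np.full((4, 4, 3), 137, dtype=np.uint8)
        np.testing.assert_array_equal(pp.to_grayscale(img), 137)

    def test_white_stays_white(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        np.testing.assert_array_equal(pp.to_grayscale(img), 255)

    def test_pure_red_bt601(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 255
        np.testing.assert_array_equal(pp.to_grayscale(img), 76)

    def test_wrong_channels_rejected(self):
        with pytest.raises(ValueError):
            pp.to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestBlackTophat:
    def test_constant_image_zero(self):
        x = np.full((16, 16), 120, dtype=np.uint8)
        se = pp.make_structuring_element("rect", 5)
        np.testing.assert_array_equal(pp.black_tophat(x, se), 0)

    def test_dark_line_response(self):
        """A 1-px dark line on a bright field responds at full contrast."""
        x = np.full((32, 32), 200, dtype=np.uint8)
        x[16, :] = 50
        se = pp.make_structuring_element("rect", 5)
        bth = pp.black_tophat(x, se)
        np.testing.assert_array_equal(bth[16, :], 150)
        np.testing.assert_array_equal(bth[:10, :], 0)

    @pytest.mark.parametrize("shape", ["rect", "disk", "cross"])
    def test_matches_brute_force_oracle(self, shape, rng):
        se = pp.make_structuring_element(shape, 5)
        for _ in range(5):
            x = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
            expected = np.clip(
                brute_force_closing(x, se) - x.astype(np.int32), 0, 255)
            np.testing.assert_array_equal(pp.black_tophat(x, se), expected)

    def test_se_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            pp.black_tophat(np.zeros((4, 4), dtype=np.uint8),
                            np.ones((9, 9), dtype=bool))


class TestDetectHairMask:
    def test_constant_image_empty_mask(self):
        x = np.full((32, 32), 150, dtype=np.uint8)
        assert pp.detect_hair_mask(x, pp.HairRemovalParams()).sum() == 0

    def test_unattainable_threshold_empty(self, hairy_spec):
        s = fx.generate_lesion_sample(hairy_spec, 1)
        params = pp.HairRemovalParams(threshold=254)
        m = pp.detect_hair_mask(pp.to_grayscale(s.image), params)
        assert m.sum() == 0

    def test_covers_synthetic_hair_footprint(self, hairy_spec):
        s = fx.generate_lesion_sample(hairy_spec, 3)
        m = pp.detect_hair_mask(pp.to_grayscale(s.image),
                                pp.HairRemovalParams())
        hair = s.hair_mask.astype(bool)
        coverage = (m.astype(bool) & hair).sum() / hair.sum()
        assert coverage >= 0.90

    def test_threshold_monotonicity(self, hairy_spec):
        """Raising the threshold never grows the detected mask."""
        for seed in range(50):
            g = pp.to_grayscale(fx.generate_lesion_sample(hairy_spec, seed).image)
            lo = pp.detect_hair_mask(g, pp.HairRemovalParams(threshold=10))
            hi = pp.detect_hair_mask(g, pp.HairRemovalParams(threshold=30))
            assert not (hi.astype(bool) & ~lo.astype(bool)).any()

    @pytest.mark.parametrize("bad", [
        dict(se_size=4), dict(se_size=1), dict(threshold=0),
        dict(threshold=255), dict(inpaint_radius=0), dict(se_shape="ball"),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            pp.HairRemovalParams(**bad).validate()


class TestInpaint:
    def test_empty_mask_identity(self, sample):
        out = pp.inpaint(sample.image, np.zeros(sample.mask.shape, dtype=np.uint8))
        np.testing.assert_array_equal(out, sample.image)

    def test_constant_image_stays_constant(self):
        img = np.full((32, 32, 3), 99, dtype=np.uint8)
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[10:20, 10:20] = 1
        np.testing.assert_array_equal(pp.inpaint(img, mask), 99)

    def test_unmasked_pixels_unchanged(self, hairy_spec):
        s = fx.generate_lesion_sample(hairy_spec, 2)
        mask = s.hair_mask
        out = pp.inpaint(s.image, mask)
        outside = ~mask.astype(bool)
        np.testing.assert_array_equal(out[outside], s.image[outside])

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError):
            pp.inpaint(np.zeros((8, 8, 3), dtype=np.uint8),
                       np.ones((8, 8), dtype=np.uint8))

    def test_reduces_error_to_hairless_reference(self, hairy_spec):
        s = fx.generate_lesion_sample(hairy_spec, 9)
        ref = fx.hairless_render(hairy_spec, 9).image.astype(float)
        before = np.abs(s.image.astype(float) - ref).mean()
        out = pp.inpaint(s.image, s.hair_mask)
        after = np.abs(out.astype(float) - ref).mean()
        assert after < before


class TestRemoveHair:
    def test_hairless_near_identity(self):
        spec = fx.SynthSpec(image_size=(256, 256), hair_count_range=(0, 0))
        s = fx.generate_lesion_sample(spec, 7)
        out = pp.remove_hair(s.image)
        changed = (out != s.image).any(axis=-1).mean()
        assert changed <= 0.001

    def test_reduces_mae_to_hairless_reference(self, hairy_spec):
        for seed in range(5):
            s = fx.generate_lesion_sample(hairy_spec, seed)
            ref = fx.hairless_render(hairy_spec, seed).image.astype(float)
            before = np.abs(s.image.astype(float) - ref).mean()
            after = np.abs(pp.remove_hair(s.image).astype(float) - ref).mean()
            assert after < before

    def test_idempotent_in_effect(self, hairy_spec):
        s = fx.generate_lesion_sample(hairy_spec, 11)
        once = pp.remove_hair(s.image)
        twice = pp.remove_hair(once)
        mae = np.abs(once.astype(float) - twice.astype(float)).mean()
        assert mae < 1.0

    def test_never_touches_ground_truth_mask(self, hairy_spec):
        s = fx.generate_lesion_sample(hairy_spec, 4)
        cleaned = pp.clean_sample(s)
        np.testing.assert_array_equal(cleaned.mask, s.mask)


class TestResizeNN:
    def test_resize_to_own_size_identity(self, sample):
        out = pp.resize_nn(sample, sample.image.shape[0])
        np.testing.assert_array_equal(out.image, sample.image)
        np.testing.assert_array_equal(out.mask, sample.mask)

    def test_checkerboard_downscale_no_blend(self):
        board = np.indices((16, 16)).sum(axis=0) % 2
        img = np.stack([board * 255] * 3, axis=-1).astype(np.uint8)
        s = fx.LesionSample(image=img, mask=board.astype(np.uint8), sample_id="cb")
        out = pp.resize_nn(s, 8).image
        assert set(np.unique(out)) <= {0, 255}

    def test_mask_stays_binary_after_any_resize(self, sample):
        for size in (16, 48, 100):
            out = pp.resize_nn(sample, size)
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_too_small_target_rejected(self, sample):
        with pytest.raises(ValueError):
            pp.resize_nn(sample, 4)
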