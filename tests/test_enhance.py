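"""ACER enhancement: surround kernel, SSR, ACE, and their composition."""

import numpy as np
import pytest

from bronchoscore.enhance import (
    EnhanceParams,
    ace_decompose,
    ace_enhance,
    acer,
    gaussian_surround,
    ssr_retinex,
)


def brute_force_ssr(img: np.ndarray, delta: float, size: int) -> np.ndarray:
    """Nested-loop reference for the log-domain center-surround reflectance."""
    kernel = gaussian_surround(delta, size)
    half = size // 2
    padded = np.pad(img, half, mode="symmetric")
    surround = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = padded[i : i + size, j : j + size]
            surround[i, j] = float(np.sum(window * kernel))
    return np.log(img + 1.0) - np.log(surround + 1.0)


class TestGaussianSurround:
    def test_normalized_and_unimodal(self):
        k = gaussian_surround(1.0, 3)
        assert abs(k.sum() - 1.0) < 1e-12
        assert k[1, 1] == k.max()

    def test_radial_symmetry(self):
        k = gaussian_surround(2.5, 9)
        assert np.allclose(k, k.T)
        assert np.allclose(k, k[::-1, ::-1])

    def test_closed_form_ratio(self):
        # before normalization the entries are exp(-(x^2+y^2)/(2 d^2)); the
        # ratio center/(offset 2,0) survives normalization
        k = gaussian_surround(2.0, 13)
        ratio = k[6, 6] / k[6, 8]
        assert ratio == pytest.approx(np.exp(4.0 / (2.0 * 4.0)), rel=1e-9)

    @pytest.mark.parametrize("size", [2, 4, 1])
    def test_even_or_tiny_size_rejected(self, size):
        with pytest.raises(ValueError):
            gaussian_surround(1.0, size)


class TestSSR:
    def test_constant_image_maps_to_midpoint(self):
        out = ssr_retinex(np.full((24, 24), 88.0))
        assert np.allclose(out, 127.5)

    def test_output_within_range(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        out = ssr_retinex(img, EnhanceParams(delta=3.0))
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_impulse_brighter_than_background(self):
        img = np.full((32, 32), 10.0)
        img[16, 16] = 250.0
        r = ssr_retinex(img, EnhanceParams(delta=2.0), rescale=False)
        assert r[16, 16] > r[2, 2]

    def test_matches_nested_loop_reference(self):
        params = EnhanceParams(delta=2.0)
        for seed in range(20):
            img = np.random.default_rng(seed).uniform(0, 255, (32, 32))
            mine = ssr_retinex(img, params, rescale=False)
            ref = brute_force_ssr(img, 2.0, 13)
            assert np.abs(mine - ref).max() < 1e-6

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            ssr_retinex(np.full((16, 16), -1.0))

    def test_nonfinite_rejected(self):
        img = np.ones((16, 16))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            ssr_retinex(img)

    def test_approximate_gain_invariance(self, rng):
        """Multiplying the input by a constant barely moves the reflectance.

        The log-ratio cancels a global gain exactly for eps = 0; with the
        small eps offset the residual effect is bounded.
        """
        img = rng.uniform(50, 200, (32, 32))
        p = EnhanceParams(delta=3.0)
        r1 = ssr_retinex(img, p, rescale=False)
        r2 = ssr_retinex(img * 2.0, p, rescale=False)
        assert np.abs(r1 - r2).max() < 0.02


class TestACE:
    def test_decomposition_is_exact(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        low, high = ace_decompose(img, 5.0)
        assert np.allclose(low + high, img, atol=1e-12)

    def test_constant_has_zero_highpass(self):
        _, high = ace_decompose(np.full((20, 20), 42.0), 3.0)
        assert np.allclose(high, 0.0)

    def test_checkerboard_low_is_mean(self):
        img = np.indices((32, 32)).sum(axis=0) % 2 * 100.0
        low, high = ace_decompose(img, 50.0)
        assert np.allclose(low, img.mean(), atol=1.0)
        assert np.allclose(high, img - img.mean(), atol=1.0)

    def test_gain_ceiling_one_is_identity(self, rng):
        img = rng.uniform(10, 240, (32, 32))
        out = ace_enhance(img, EnhanceParams(cg_max=1.0))
        assert np.allclose(out, img, atol=1e-9)

    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 123.0)
        assert np.allclose(ace_enhance(img), img)

    def test_amplifies_low_contrast_ramp(self):
        img = np.tile(np.linspace(100, 110, 16), (16, 1))
        out = ace_enhance(img, EnhanceParams(cg_max=4.0, ace_window=5, lowpass_sigma=2.0))
        assert out.std() >= img.std()

    def test_additive_offset_equivariance(self, rng):
        """The ACE gain depends only on contrasts, so a DC shift passes through."""
        img = rng.uniform(20, 120, (32, 32))
        p = EnhanceParams(cg_max=3.0)
        assert np.allclose(ace_enhance(img + 50.0, p), ace_enhance(img, p) + 50.0, atol=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EnhanceParams(ace_window=4)
        with pytest.raises(ValueError):
            EnhanceParams(cg_max=0.5)
        with pytest.raises(ValueError):
            EnhanceParams(delta=-1.0)


class TestACER:
    def test_constant_input_constant_output(self):
        out = acer(np.full((32, 32), 7.0))
        assert np.allclose(out, 127.5)

    def test_shape_preserved(self, rng):
        img = rng.uniform(0, 255, (40, 56))
        assert np.asarray(acer(img, EnhanceParams(delta=4.0))).shape == (40, 56)

    def test_composition_order_ace_then_ssr(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        p = EnhanceParams(delta=4.0)
        assert np.allclose(acer(img, p), ssr_retinex(ace_enhance(img, p), p))

    def test_lung_field_contrast_increases_on_phantom(self, small_phantom):
        lung = small_phantom.lobe_mask.labels > 0
        img = small_phantom.image.pixels
        out = np.asarray(acer(img, EnhanceParams(delta=12.0)))
        assert out[lung].std() > img[lung].std()

    def test_three_channel_input_processed_per_channel(self, rng):
        chan = rng.uniform(0, 255, (32, 32))
        stacked = np.stack([chan] * 3, axis=-1)
        out = acer(stacked, EnhanceParams(delta=4.0))
        assert out.shape == (32, 32, 3)
        assert np.allclose(out[..., 0], out[..., 2])
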