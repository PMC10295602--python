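"""Enhancement chain: grayscale, bilateral, CLAHE, gamma — each stage a
[0,1] -> [0,1] map with the documented fixed points and contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from vesselseg.preprocess import (
    PreprocessConfig,
    bilateral_filter,
    clahe,
    gamma_correct,
    preprocess_pipeline,
    to_grayscale,
)
from vesselseg.synthetic import VesselSimConfig, generate_sample


def bilateral_oracle(img: np.ndarray, win: int, sigma_color: float, sigma_space: float) -> np.ndarray:
    """Direct double-loop window sum: weights = spatial x range Gaussian."""
    r = win // 2
    pad = np.pad(img, r, mode="edge")
    ii, jj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    spatial = np.exp(-(ii**2 + jj**2) / (2 * sigma_space**2))
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = pad[i : i + win, j : j + win]
            w = spatial * np.exp(-((window - img[i, j]) ** 2) / (2 * sigma_color**2))
            out[i, j] = (w * window).sum() / w.sum()
    return out


class TestGrayscale:
    def test_gray_input_unchanged(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(to_grayscale(img), img)

    def test_luminance_weights_sum_to_one(self):
        img = np.ones((4, 4, 3))
        assert np.allclose(to_grayscale(img, "luminance"), 1.0)

    def test_luminance_hand_value(self):
        img = np.array([[[0.2, 0.6, 0.4]]])
        expected = 0.299 * 0.2 + 0.587 * 0.6 + 0.114 * 0.4  # = 0.4576
        assert abs(to_grayscale(img, "luminance")[0, 0] - expected) < 1e-12
        assert abs(expected - 0.4576) < 1e-12

    def test_green_channel(self):
        img = np.zeros((2, 2, 3))
        img[..., 1] = 0.7
        assert np.allclose(to_grayscale(img, "green_channel"), 0.7)

    def test_bad_channel_count(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2)))


class TestBilateral:
    def test_constant_fixed_point(self):
        cfg = PreprocessConfig()
        img = np.full((20, 20), 0.37)
        assert np.allclose(bilateral_filter(img, cfg), img, atol=1e-10)

    def test_impulse_attenuated(self):
        # at a wide range kernel the filter behaves like a smoother and
        # must pull the isolated peak down
        cfg = PreprocessConfig(bilateral_sigma_color=1.0)
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        assert bilateral_filter(img, cfg).max() < 1.0

    def test_output_within_window_extrema(self, rng):
        cfg = PreprocessConfig(bilateral_diameter=5)
        img = rng.random((24, 24))
        out = bilateral_filter(img, cfg)
        r = 2
        pad = np.pad(img, r, mode="edge")
        for i in range(24):
            for j in range(24):
                win = pad[i : i + 5, j : j + 5]
                assert win.min() - 1e-9 <= out[i, j] <= win.max() + 1e-9

    def test_step_edge_preserved_vs_gaussian(self):
        """On an ideal 0|1 step, the bilateral keeps the edge (magnitude
        >= 0.8 at sigma_color = 0.1) while a plain Gaussian of equal
        spatial sigma blurs it; both behaviours confirmed against the
        double-loop oracle."""
        cfg = PreprocessConfig(bilateral_diameter=9, bilateral_sigma_color=0.1,
                               bilateral_sigma_space=5.0)
        step = np.zeros((16, 16))
        step[:, 8:] = 1.0
        edge = lambda a: float(a[:, 8].mean() - a[:, 7].mean())
        filtered = bilateral_filter(step, cfg)
        oracle = bilateral_oracle(step, 9, 0.1, 5.0)
        blurred = gaussian_filter(step, sigma=5.0, mode="nearest")
        assert edge(filtered) >= 0.8
        assert edge(oracle) >= 0.8
        assert edge(blurred) < edge(filtered)
        assert edge(blurred) < edge(oracle)


class TestClahe:
    def test_constant_maps_to_constant(self):
        cfg = PreprocessConfig(clahe_tile_grid=(4, 4))
        out = clahe(np.full((32, 32), 0.5), cfg)
        assert np.ptp(out) < 1e-12

    def test_contrast_increases_on_low_contrast_vessels(self):
        sim = VesselSimConfig(image_size=(64, 64), vessel_contrast=0.1, noise_sigma=0.01, seed=5)
        img = generate_sample(sim, 0).image
        out = clahe(img, PreprocessConfig(clahe_tile_grid=(4, 4)))
        assert out.std() > img.std()

    def test_range_contract_on_random_images(self, rng):
        cfg = PreprocessConfig(clahe_tile_grid=(2, 2))
        for _ in range(50):
            out = clahe(rng.random((20, 20)), cfg)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_tile_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="tile grid"):
            clahe(np.zeros((4, 4)), PreprocessConfig(clahe_tile_grid=(8, 8)))

    def test_agrees_qualitatively_with_skimage(self):
        """Independent CLAHE (skimage) and ours both enhance the same
        structures: their outputs correlate strongly on a vessel image."""
        from skimage.exposure import equalize_adapthist

        sim = VesselSimConfig(image_size=(64, 64), vessel_contrast=0.15, seed=3)
        img = generate_sample(sim, 0).image
        ours = clahe(img, PreprocessConfig(clahe_tile_grid=(4, 4)))
        ref = equalize_adapthist(img, kernel_size=16, clip_limit=0.01)
        corr = np.corrcoef(ours.ravel(), ref.ravel())[0, 1]
        assert corr > 0.9


class TestGamma:
    def test_identity_at_one(self, rng):
        img = rng.random((8, 8))
        assert np.allclose(gamma_correct(img, 1.0), img)

    def test_closed_form(self):
        assert gamma_correct(np.array([[0.25]]), 2.0)[0, 0] == pytest.approx(0.0625)

    def test_sqrt_brightens(self, rng):
        img = rng.random((8, 8))
        assert (gamma_correct(img, 0.5) >= img - 1e-12).all()

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_correct(np.zeros((2, 2)), 0.0)

    @given(st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_inputs_stay_monotone(self, gamma):
        ramp = np.linspace(0, 1, 64).reshape(1, -1)
        out = gamma_correct(ramp, gamma)
        assert (np.diff(out[0]) >= 0).all()


class TestPipeline:
    def test_disabled_reduces_to_grayscale(self, rng):
        cfg = PreprocessConfig(enabled=False)
        img = rng.random((16, 16, 3))
        assert np.array_equal(preprocess_pipeline(img, cfg), to_grayscale(img, "luminance"))

    def test_constant_rgb_stays_constant(self):
        cfg = PreprocessConfig(clahe_tile_grid=(2, 2))
        out = preprocess_pipeline(np.full((32, 32, 3), 0.6), cfg)
        assert np.ptp(out) < 1e-9

    def test_deterministic(self, vessel_sample):
        cfg = PreprocessConfig(clahe_tile_grid=(4, 4))
        a = preprocess_pipeline(vessel_sample.image, cfg)
        b = preprocess_pipeline(vessel_sample.image, cfg)
        assert np.array_equal(a, b)

    def test_every_stage_stays_in_unit_interval(self, vessel_sample):
        cfg = PreprocessConfig(clahe_tile_grid=(4, 4))
        out = preprocess_pipeline(vessel_sample.image, cfg)
        assert out.min() >= 0.0 and out.max() <= 1.0
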