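"""Decorrelation-stretch enhancement: channel statistics and whitening."""

import numpy as np
import pytest

from spikesight import channel_stats, contrast_stretch, decorrelation_stretch


def oracle_stretch(img, target_sd=50.0, recenter=127.5, delta_rel=1e-12):
    """Independent whitening oracle via explicit 3x3 eigen-algebra.

    Covariance accumulated in loops, eigenpairs from np.linalg.eig (not
    eigh), transform applied pixel by pixel.
    """
    flat = img.reshape(-1, 3)
    mu = sum(p for p in flat) / len(flat)
    cov = np.zeros((3, 3))
    for p in flat:
        d = p - mu
        cov += np.outer(d, d)
    cov /= len(flat)
    evals, evecs = np.linalg.eig(cov)
    evals = evals.real
    evecs = evecs.real
    delta = delta_rel * evals.max()
    D = np.diag(1.0 / np.sqrt(evals + delta))
    T = evecs @ D @ evecs.T  # symmetric: eigen-sign conventions cancel
    out = np.array([T @ (p - mu) for p in flat]) * target_sd + recenter
    return out.reshape(img.shape)


class TestChannelStats:
    def test_two_pixel_black_white(self):
        img = np.array([[[0.0, 0.0, 0.0]], [[255.0, 255.0, 255.0]]])
        st = channel_stats(img)
        assert np.allclose(st.means, 127.5)
        assert np.allclose(st.covariance, 16256.25)

    def test_constant_image_has_zero_covariance(self):
        st = channel_stats(np.full((5, 4, 3), 33.0))
        assert np.allclose(st.covariance, 0.0)
        assert np.allclose(st.eigenvalues, 0.0)

    def test_single_pixel_valid_empty_rejected(self):
        st = channel_stats(np.full((1, 1, 3), 9.0))
        assert np.allclose(st.covariance, 0.0)
        with pytest.raises(ValueError):
            channel_stats(np.zeros((0, 3, 3)))

    def test_independent_channels_nearly_uncorrelated(self):
        rng = np.random.default_rng(0)
        img = rng.normal(128, 20, size=(1000, 1000, 3))
        st = channel_stats(img)
        sd = np.sqrt(np.diag(st.covariance))
        corr = st.covariance / np.outer(sd, sd)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.01)

    def test_eigen_structure(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (16, 16, 3)) @ rng.uniform(0.2, 1, (3, 3))
        st = channel_stats(np.clip(img, 0, 255))
        assert np.all(np.diff(st.eigenvalues) <= 0)  # descending
        assert np.allclose(st.eigenvectors.T @ st.eigenvectors, np.eye(3), atol=1e-8)
        recon = st.eigenvectors @ np.diag(st.eigenvalues) @ st.eigenvectors.T
        assert np.allclose(recon, st.covariance, atol=1e-8)
        for j in range(3):
            col = st.eigenvectors[:, j]
            assert col[np.argmax(np.abs(col))] > 0  # fixed sign convention


class TestDecorrelationStretch:
    def test_uncorrelated_equal_variance_reduces_to_standardization(self):
        # construct channels whose empirical covariance is exactly 400 * I
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(64 * 64, 3))
        raw -= raw.mean(0)
        evals, evecs = np.linalg.eigh(raw.T @ raw / raw.shape[0])
        white = raw @ evecs @ np.diag(1 / np.sqrt(evals)) @ evecs.T
        img = (128 + 20 * white).reshape(64, 64, 3)
        out = decorrelation_stretch(img, target_sd=50.0, clip=False)
        expect = (img - 128.0) * (50.0 / 20.0) + 127.5
        assert np.allclose(out, expect, atol=1e-6)

    def test_constant_image_maps_to_recenter(self):
        out = decorrelation_stretch(np.full((8, 8, 3), 77.0))
        assert np.allclose(out, 127.5)

    def test_four_pixel_output_covariance_is_isotropic(self):
        img = np.array([[10.0, 20.0, 30.0], [40.0, 60.0, 80.0],
                        [90.0, 50.0, 120.0], [200.0, 180.0, 140.0]]
                       ).reshape(2, 2, 3)
        out = decorrelation_stretch(img, target_sd=50.0, clip=False)
        cov = np.cov(out.reshape(-1, 3).T, ddof=0)
        assert np.abs(cov - 2500.0 * np.eye(3)).max() / 2500.0 < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_tiny_images(self, seed):
        rng = np.random.default_rng(seed)
        img = np.clip(rng.uniform(0, 255, (4, 4, 3))
                      @ np.array([[1, .7, .5], [0, .6, .4], [0, 0, .3]]), 0, 255)
        out = decorrelation_stretch(img, clip=False)
        assert np.allclose(out, oracle_stretch(img), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_whitening_property(self, seed):
        rng = np.random.default_rng(seed)
        mix = rng.uniform(-1, 1, (3, 3)) + 2 * np.eye(3)
        img = rng.normal(0, 25, (48, 48, 3)) @ mix + 120
        out = decorrelation_stretch(img, target_sd=40.0, clip=False)
        cov = np.cov(out.reshape(-1, 3).T, ddof=0)
        assert np.abs(cov - 1600.0 * np.eye(3)).max() / 1600.0 < 1e-6

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        img = np.clip(rng.normal(120, 30, (16, 16, 3))
                      @ np.array([[1, .8, .2], [0, .5, .4], [0, 0, .6]]), 0, 255)
        perm = [2, 0, 1]
        out_perm = decorrelation_stretch(img[..., perm], clip=False)
        out = decorrelation_stretch(img, clip=False)
        assert np.allclose(out_perm, out[..., perm], atol=1e-8)

    def test_idempotent_up_to_affine(self):
        rng = np.random.default_rng(4)
        img = rng.normal(128, 15, (32, 32, 3)) @ (np.eye(3) + 0.3)
        once = decorrelation_stretch(img, clip=False)
        twice = decorrelation_stretch(once, clip=False)
        # second pass sees an already-white image: per-channel affine map
        for c in range(3):
            coef = np.polyfit(once[..., c].ravel(), twice[..., c].ravel(), 1)
            resid = twice[..., c] - np.polyval(coef, once[..., c])
            assert np.abs(resid).max() < 1e-6 * np.abs(twice[..., c]).max()

    def test_nan_rejected_and_bad_target_sd(self):
        img = np.zeros((4, 4, 3))
        img[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            decorrelation_stretch(img)
        with pytest.raises(ValueError):
            decorrelation_stretch(np.zeros((4, 4, 3)), target_sd=0.0)

    def test_correlation_matrix_mode_also_whitens(self):
        rng = np.random.default_rng(5)
        img = rng.normal(0, 20, (32, 32, 3)) @ (np.eye(3) + 0.5) + 120
        out = decorrelation_stretch(img, matrix="correlation", clip=False)
        cov = np.cov(out.reshape(-1, 3).T, ddof=0)
        corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.abs(corr - np.eye(3)).max() < 1e-6


class TestContrastStretch:
    def test_full_range_identity(self):
        img = np.stack([np.linspace(0, 255, 256)] * 3, -1).reshape(16, 16, 3)
        out = contrast_stretch(img, 0, 100)
        assert np.allclose(out, img)

    def test_linear_map_of_narrow_band(self):
        ch = np.linspace(100, 150, 64).reshape(8, 8)
        img = np.stack([ch] * 3, -1)
        out = contrast_stretch(img, 0, 100)
        assert np.isclose(out.min(), 0) and np.isclose(out.max(), 255)
        # interior points map linearly
        assert np.allclose(out[..., 0], (ch - 100) * 255 / 50, atol=1e-9)

    def test_constant_channel_unchanged(self):
        img = np.full((4, 4, 3), 42.0)
        assert np.allclose(contrast_stretch(img), img)

    def test_bad_percentiles(self):
        with pytest.raises(ValueError):
            contrast_stretch(np.zeros((4, 4, 3)), 50, 50)
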