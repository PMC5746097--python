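"""Wavelet decomposition, thresholding and denoising.

The Haar (db1) oracles use the explicit 2x2 block formulas: for a block
[[a, b], [c, d]] the single-level subband coefficients under periodized
boundaries are A=(a+b+c+d)/2, H=(a+b-c-d)/2, V=(a-b+c-d)/2, D=(a-b-c+d)/2.
"""

import numpy as np
import pytest

from apoploc import (
    WaveletDenoiser,
    WaveletSpec,
    birge_massart_thresholds,
    decompose,
    default_threshold,
    denoise_matrix,
    denoise_rows_1d,
    make_noise_fixture,
    reconstruct,
)
from apoploc.denoise import (
    SUPPORTED_FAMILIES,
    WaveletLevelError,
    apply_threshold,
    denoise_array,
    denoise_row_1d,
    hard_threshold,
    soft_threshold,
)
from apoploc.fusion import FeatureMatrix

ORTHOGONAL = [f for f in SUPPORTED_FAMILIES if not f.startswith("bior")]


def haar_blocks(X):
    """Independent single-level Haar subbands via explicit 2x2 block sums."""
    a, b = X[0::2, 0::2], X[0::2, 1::2]
    c, d = X[1::2, 0::2], X[1::2, 1::2]
    return (a + b + c + d) / 2, (a + b - c - d) / 2, (a - b + c - d) / 2, (
        a - b - c + d
    ) / 2


class TestDecompose:
    def test_zero_matrix_gives_zero_subbands(self):
        pyr = decompose(np.zeros((32, 32)), WaveletSpec(family="db4", level=3))
        assert np.all(pyr.approximation == 0)
        for bands in pyr.details:
            for band in bands:
                assert np.all(band == 0)

    @pytest.mark.parametrize("family", ORTHOGONAL)
    def test_parseval_orthogonal_families(self, family, rng):
        """Energy conservation for orthonormal filters (periodized, dyadic)."""
        X = rng.normal(size=(64, 64))
        spec = WaveletSpec(family=family, level=3, extension="periodization")
        pyr = decompose(X, spec)
        energy = (pyr.approximation**2).sum() + pyr.detail_energy()
        assert energy == pytest.approx((X**2).sum(), rel=1e-6)

    def test_haar_ramp_matches_block_oracle(self):
        X = np.outer(np.arange(16, dtype=float), np.ones(16)) + np.arange(16)
        spec = WaveletSpec(family="db1", level=1, extension="periodization")
        pyr = decompose(X, spec)
        A, H, V, D = haar_blocks(X)
        np.testing.assert_allclose(pyr.approximation, A, atol=1e-10)
        np.testing.assert_allclose(pyr.details[0][0], H, atol=1e-10)
        np.testing.assert_allclose(pyr.details[0][1], V, atol=1e-10)
        np.testing.assert_allclose(pyr.details[0][2], D, atol=1e-10)

    def test_level_too_deep_is_error(self):
        with pytest.raises(WaveletLevelError, match="maximum"):
            decompose(np.zeros((8, 8)), WaveletSpec(family="db1", level=4))

    def test_nonfinite_input_is_error(self):
        X = np.zeros((16, 16))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            decompose(X, WaveletSpec(family="db1", level=1))


class TestReconstruct:
    @pytest.mark.parametrize("family", SUPPORTED_FAMILIES)
    @pytest.mark.parametrize("level", [3, 4, 5])
    def test_perfect_reconstruction_317x255(self, family, level, rng):
        """No-threshold round trip on the benchmark matrix geometry."""
        X = rng.normal(size=(317, 255))
        spec = WaveletSpec(family=family, level=level)
        pyr = decompose(X, spec)
        back = reconstruct(pyr, spec, X.shape)
        assert np.abs(back - X).max() < 1e-8

    def test_zero_pyramid_reconstructs_zero(self):
        spec = WaveletSpec(family="db4", level=2)
        pyr = decompose(np.zeros((32, 32)), spec)
        np.testing.assert_allclose(reconstruct(pyr, spec, (32, 32)), 0.0)

    def test_single_coefficient_haar_basis_image(self):
        spec = WaveletSpec(family="db1", level=1, extension="periodization")
        pyr = decompose(np.zeros((4, 4)), spec)
        pyr.details[0][2][0, 0] = 1.0  # one diagonal coefficient
        img = reconstruct(pyr, spec, (4, 4))
        expected = np.zeros((4, 4))
        expected[:2, :2] = np.array([[0.5, -0.5], [-0.5, 0.5]])
        np.testing.assert_allclose(img, expected, atol=1e-12)


class TestDefaultThreshold:
    def test_zero_matrix_threshold_zero(self):
        pyr = decompose(np.zeros((32, 32)), WaveletSpec(level=2, family="db1"))
        with pytest.warns(UserWarning, match="all zero"):
            assert default_threshold(pyr, 32 * 32) == 0.0

    def test_recovers_unit_noise_scale(self):
        """MAD estimate of sigma from pure N(0,1) input stays near 1."""
        sigmas = []
        for seed in range(10):
            X = np.random.default_rng(seed).standard_normal((64, 64))
            pyr = decompose(X, WaveletSpec(family="db8", level=2))
            thr = default_threshold(pyr, X.size)
            sigmas.append(thr / np.sqrt(2 * np.log(X.size)))
        assert all(0.8 <= s <= 1.2 for s in sigmas)

    def test_homogeneous_in_scale(self, rng):
        X = rng.normal(size=(64, 64))
        spec = WaveletSpec(family="db4", level=2)
        t1 = default_threshold(decompose(X, spec), X.size)
        t3 = default_threshold(decompose(3.0 * X, spec), X.size)
        assert t3 == pytest.approx(3.0 * t1, rel=1e-12)


class TestBirgeMassart:
    def test_alpha_must_exceed_one(self, rng):
        pyr = decompose(rng.normal(size=(16, 16)), WaveletSpec(family="db1", level=2))
        with pytest.raises(ValueError, match="alpha"):
            birge_massart_thresholds(pyr, alpha=1.0)

    def test_generous_budget_gives_zero_thresholds(self, rng):
        # alpha close to 1 keeps the budget above the shrinking subband
        # counts at coarse levels
        pyr = decompose(rng.normal(size=(64, 64)), WaveletSpec(family="db1", level=3))
        thr = birge_massart_thresholds(pyr, alpha=1.001)
        assert thr[(3, "H")] == 0.0  # coarsest: budget 1024/2^1.001 > 64 coeffs

    def test_keep_largest_semantics(self):
        X = np.zeros((8, 8))
        spec = WaveletSpec(family="db1", level=1, extension="periodization")
        pyr = decompose(X, spec)
        pyr.details[0][0][1, 1] = 5.0  # single nonzero H coefficient
        thr = birge_massart_thresholds(pyr, alpha=1.5)
        # budget >= 1 at the finest level, so the coefficient survives both modes
        assert thr[(1, "H")] == 0.0
        out = apply_threshold(pyr, thr, mode="hard")
        assert out.details[0][0][1, 1] == 5.0

    def test_sort_and_select_oracle(self, rng):
        X = rng.normal(size=(8, 8))
        pyr = decompose(X, WaveletSpec(family="db1", level=2))
        J, M = 2, pyr.finest_diagonal().size
        got = birge_massart_thresholds(pyr, alpha=1.5)
        for t in (1, 2):
            budget = int(M / (J + 2 - t) ** 1.5)
            for name, band in zip("HVD", pyr.details[t - 1]):
                mags = sorted(np.abs(band).ravel(), reverse=True)
                expected = 0.0 if budget >= len(mags) else mags[budget]
                assert got[(t, name)] == pytest.approx(expected, abs=1e-14)


class TestApplyThreshold:
    def test_soft_definition(self):
        assert soft_threshold(np.array(3.0), 1.0) == 2.0
        assert soft_threshold(np.array(-0.5), 1.0) == 0.0
        assert soft_threshold(np.array(-3.0), 1.0) == -2.0

    def test_hard_definition(self):
        assert hard_threshold(np.array(3.0), 1.0) == 3.0
        assert hard_threshold(np.array(0.5), 1.0) == 0.0

    def test_zero_threshold_is_identity(self, rng):
        pyr = decompose(rng.normal(size=(32, 32)), WaveletSpec(family="db4", level=2))
        out = apply_threshold(pyr, 0.0, mode="soft")
        for b_out, b_in in zip(out.details[0], pyr.details[0]):
            np.testing.assert_array_equal(b_out, b_in)

    def test_negative_threshold_is_error(self, rng):
        pyr = decompose(rng.normal(size=(16, 16)), WaveletSpec(family="db1", level=1))
        with pytest.raises(ValueError):
            apply_threshold(pyr, -0.1)

    def test_scalar_loop_oracle(self, rng):
        pyr = decompose(rng.normal(size=(16, 16)), WaveletSpec(family="db1", level=1))
        for mode in ("soft", "hard"):
            out = apply_threshold(pyr, 0.7, mode=mode)
            for b_out, b_in in zip(out.details[0], pyr.details[0]):
                for x_out, x in zip(b_out.ravel(), b_in.ravel()):
                    if mode == "soft":
                        exp = np.sign(x) * max(abs(x) - 0.7, 0.0)
                    else:
                        exp = x if abs(x) > 0.7 else 0.0
                    assert x_out == pytest.approx(exp, abs=1e-15)

    def test_approximation_untouched_and_energy_nonincreasing(self, rng):
        pyr = decompose(rng.normal(size=(32, 32)), WaveletSpec(family="sym3", level=2))
        out = apply_threshold(pyr, 0.5, mode="soft")
        np.testing.assert_array_equal(out.approximation, pyr.approximation)
        assert out.detail_energy() <= pyr.detail_energy()

    def test_larger_threshold_never_grows_coefficients(self, rng):
        pyr = decompose(rng.normal(size=(32, 32)), WaveletSpec(family="db4", level=2))
        small = apply_threshold(pyr, 0.3, mode="soft")
        large = apply_threshold(pyr, 0.9, mode="soft")
        for bs, bl in zip(small.details, large.details):
            for s, l in zip(bs, bl):
                assert (np.abs(l) <= np.abs(s) + 1e-15).all()


class TestDenoise:
    def test_reduces_mse_on_noisy_low_rank(self):
        """2-D denoising beats the noisy observation in >= 9/10 seeds."""
        spec = WaveletSpec(family="db8", level=4, threshold_mode="soft")
        wins = 0
        for seed in range(10):
            clean, noisy = make_noise_fixture(317, 255, rank=3, sigma=0.5, seed=seed)
            denoised, _ = denoise_array(noisy, spec)
            if ((denoised - clean) ** 2).mean() < ((noisy - clean) ** 2).mean():
                wins += 1
        assert wins >= 9

    def test_paper_operating_point_preserves_shape(self, rng):
        X = FeatureMatrix(
            values=rng.normal(size=(317, 255)),
            row_ids=[f"r{i}" for i in range(317)],
            labels=["c"] * 317,
        )
        out = denoise_matrix(X, WaveletSpec(family="db8", level=4))
        assert out.values.shape == (317, 255)
        assert out.row_ids == X.row_ids
        assert "denoise" in out.params

    def test_zero_detail_threshold_is_identity(self):
        # constant matrix: no detail energy, threshold 0, output == input
        X = FeatureMatrix(
            values=np.full((64, 64), 2.5), row_ids=[f"r{i}" for i in range(64)],
            labels=["c"] * 64,
        )
        out = denoise_matrix(X, WaveletSpec(family="db4", level=2))
        assert np.abs(out.values - X.values).max() < 1e-8


class TestRowDenoise:
    def test_constant_row_unchanged(self):
        row = np.full(255, 3.0)
        out = denoise_row_1d(row, WaveletSpec(family="db8", level=4))
        assert np.abs(out - row).max() < 1e-8

    def test_noisy_sinusoid_mse_reduced(self):
        spec = WaveletSpec(family="db8", level=4)
        t = np.linspace(0, 4 * np.pi, 256)
        clean = np.sin(t)
        wins = 0
        for seed in range(10):
            noisy = clean + 0.3 * np.random.default_rng(seed).standard_normal(256)
            den = denoise_row_1d(noisy, spec)
            if ((den - clean) ** 2).mean() < ((noisy - clean) ** 2).mean():
                wins += 1
        assert wins >= 9

    def test_matrix_variant_matches_per_row(self, rng):
        X = FeatureMatrix(
            values=rng.normal(size=(5, 128)), row_ids=list("abcde"),
            labels=["c"] * 5,
        )
        spec = WaveletSpec(family="sym3", level=3)
        out = denoise_rows_1d(X, spec)
        for i in range(5):
            np.testing.assert_allclose(
                out.values[i], denoise_row_1d(X.values[i], spec), atol=1e-12
            )


class TestDenoiserEstimator:
    def test_fit_transform_matches_function(self, rng):
        X = rng.normal(size=(64, 64))
        den = WaveletDenoiser(family="db4", level=3)
        out = den.fit_transform(X)
        expected, thr = denoise_array(X, WaveletSpec(family="db4", level=3))
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert den.thresholds_ == pytest.approx(thr)

    def test_leak_free_requires_fit(self, rng):
        den = WaveletDenoiser()
        with pytest.raises(ValueError, match="fitted"):
            den.transform(rng.normal(size=(4, 64)), leak_free=True)

    def test_get_set_params(self):
        den = WaveletDenoiser()
        assert den.get_params()["family"] == "db8"
        den.set_params(level=3)
        assert den.level == 3
        with pytest.raises(ValueError):
            den.set_params(bogus=1)
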