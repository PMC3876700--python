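"""Hessian, eigenvalue and vesselness-measure unit and oracle tests."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from retivess.vesselness import (
    EigenPair,
    FrangiParams,
    eigenvalues_sym2x2,
    gaussian_derivative_kernel,
    hessian_at_scale,
    HessianField,
    multiscale_frangi_reference,
    vesselness,
)


class TestHessian:
    def test_constant_image_has_zero_hessian(self):
        h = hessian_at_scale(np.full((32, 32), 0.7), sigma=1.5)
        for f in (h.hxx, h.hxy, h.hyy):
            np.testing.assert_allclose(f, 0.0, atol=1e-12)

    @pytest.mark.parametrize("sigma", [1.0, 2.0])
    def test_quadratic_ramp_second_derivative(self, sigma):
        # f(x, y) = x^2 has d2f/dx2 = 2 everywhere; with sigma^2
        # gamma-normalization the response is 2*sigma^2 away from borders
        x = np.arange(64, dtype=float)
        img = np.tile(x**2, (64, 1))
        h = hessian_at_scale(img, sigma)
        r = int(np.ceil(4 * sigma)) + 1
        interior = (slice(r, -r), slice(r, -r))
        np.testing.assert_allclose(h.hxx[interior], 2 * sigma**2, rtol=0.01)
        np.testing.assert_allclose(h.hxy[interior], 0.0, atol=1e-8)
        np.testing.assert_allclose(h.hyy[interior], 0.0, atol=1e-8)

    def test_gaussian_ridge_most_negative_at_centerline(self):
        # horizontal bright ridge: hyy should be most negative on its crest
        y = np.arange(41, dtype=float)[:, None]
        img = np.exp(-((y - 20.0) ** 2) / (2 * 2.0**2)) * np.ones((1, 41))
        h = hessian_at_scale(img, 1.0)
        assert np.argmin(h.hyy[:, 20]) == 20

    def test_matches_dense_convolution_oracle(self, rng):
        # separable implementation == dense 2-D correlation with the
        # explicit outer-product kernels
        img = rng.random((48, 48))
        sigma = 1.7
        h = hessian_at_scale(img, sigma)
        g0 = gaussian_derivative_kernel(sigma, 0)
        g1 = gaussian_derivative_kernel(sigma, 1)
        g2 = gaussian_derivative_kernel(sigma, 2)
        dense_hxx = sigma**2 * ndi.correlate(img, np.outer(g0, g2), mode="reflect")
        dense_hyy = sigma**2 * ndi.correlate(img, np.outer(g2, g0), mode="reflect")
        dense_hxy = sigma**2 * ndi.correlate(img, np.outer(g1, g1), mode="reflect")
        np.testing.assert_allclose(h.hxx, dense_hxx, atol=1e-8)
        np.testing.assert_allclose(h.hyy, dense_hyy, atol=1e-8)
        np.testing.assert_allclose(h.hxy, dense_hxy, atol=1e-8)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((32, 32)), sigma=0.0)
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((4, 4)), sigma=2.0)


class TestEigenvalues:
    def test_diagonal_matrix(self):
        h = HessianField(hxx=np.array([[2.0]]), hxy=np.array([[0.0]]), hyy=np.array([[0.0]]))
        e = eigenvalues_sym2x2(h)
        assert e.lambda1[0, 0] == pytest.approx(0.0)
        assert e.lambda2[0, 0] == pytest.approx(2.0)

    def test_pure_shear_tie_takes_negative_as_lambda2(self):
        # eigenvalues {-1, +1}: the magnitude tie resolves to the more
        # negative value as lambda2 (ridge-favoring convention)
        h = HessianField(hxx=np.array([[0.0]]), hxy=np.array([[1.0]]), hyy=np.array([[0.0]]))
        e = eigenvalues_sym2x2(h)
        assert e.lambda1[0, 0] == pytest.approx(1.0)
        assert e.lambda2[0, 0] == pytest.approx(-1.0)

    def test_against_symmetric_eigensolver(self, rng):
        hxx, hxy, hyy = rng.normal(size=(3, 200))
        e = eigenvalues_sym2x2(
            HessianField(hxx=hxx, hxy=hxy, hyy=hyy)
        )
        for i in range(hxx.size):
            ref = np.linalg.eigvalsh([[hxx[i], hxy[i]], [hxy[i], hyy[i]]])
            got = sorted([e.lambda1[i], e.lambda2[i]])
            np.testing.assert_allclose(got, ref, atol=1e-10)
        # magnitude ordering
        assert np.all(np.abs(e.lambda1) <= np.abs(e.lambda2) + 1e-12)

    def test_trace_and_determinant_identities(self, rng):
        hxx, hxy, hyy = rng.normal(size=(3, 64, 64))
        e = eigenvalues_sym2x2(HessianField(hxx=hxx, hxy=hxy, hyy=hyy))
        np.testing.assert_allclose(e.lambda1 + e.lambda2, hxx + hyy, atol=1e-8)
        np.testing.assert_allclose(
            e.lambda1 * e.lambda2, hxx * hyy - hxy**2, atol=1e-8
        )


class TestVesselness:
    def test_positive_lambda2_scores_zero(self, rng):
        lam2 = rng.uniform(0.1, 2.0, size=(16, 16))
        lam1 = lam2 * rng.uniform(-1, 1, size=(16, 16))
        v = vesselness(EigenPair(lambda1=lam1, lambda2=lam2), FrangiParams(c=1.0))
        np.testing.assert_array_equal(v.v0, 0.0)

    def test_ideal_line_response(self):
        # lambda1=0, lambda2=-L, beta=0.5, c=L/2: R_B=0, S=L, so
        # V0 = 1 - exp(-2)
        L = 3.0
        e = EigenPair(lambda1=np.zeros((4, 4)), lambda2=np.full((4, 4), -L))
        v = vesselness(e, FrangiParams(beta=0.5, c=L / 2))
        np.testing.assert_allclose(v.v0, 1.0 - np.exp(-2.0), rtol=0, atol=1e-12)

    def test_ideal_blob_attenuated(self):
        # lambda1=lambda2=-L: R_B=1 attenuates by exp(-1/(2 beta^2)) = exp(-2)
        L = 3.0
        e = EigenPair(lambda1=np.full((4, 4), -L), lambda2=np.full((4, 4), -L))
        v = vesselness(e, FrangiParams(beta=0.5, c=L / np.sqrt(2)))
        s_term = 1.0 - np.exp(-2.0)  # S^2 = 2 L^2, 2 c^2 = L^2
        np.testing.assert_allclose(v.v0, np.exp(-2.0) * s_term, atol=1e-12)

    def test_auto_c_on_zero_field_gives_zeros(self):
        e = EigenPair(lambda1=np.zeros((8, 8)), lambda2=np.zeros((8, 8)))
        v = vesselness(e, FrangiParams(c="auto"))
        np.testing.assert_array_equal(v.v0, 0.0)

    def test_range_and_zero_set_invariants(self, rng):
        lam = rng.normal(size=(2, 32, 32))
        big = np.where(np.abs(lam[0]) >= np.abs(lam[1]), lam[0], lam[1])
        small = np.where(np.abs(lam[0]) >= np.abs(lam[1]), lam[1], lam[0])
        v = vesselness(EigenPair(lambda1=small, lambda2=big), FrangiParams())
        assert np.all(v.v0 >= 0) and np.all(v.v0 < 1)
        assert np.all(v.v0[big >= 0] == 0)

    def test_invariant_to_constant_offset(self, rng):
        img = rng.random((40, 40))
        p = FrangiParams(c=0.5)
        v1 = vesselness(eigenvalues_sym2x2(hessian_at_scale(img, 1.0)), p)
        v2 = vesselness(eigenvalues_sym2x2(hessian_at_scale(img + 5.0, 1.0)), p)
        np.testing.assert_allclose(v1.v0, v2.v0, atol=1e-10)

    def test_rot90_equivariance(self, rng):
        img = rng.random((40, 40))
        p = FrangiParams(c=0.5)
        v = vesselness(eigenvalues_sym2x2(hessian_at_scale(img, 1.0)), p).v0
        vr = vesselness(
            eigenvalues_sym2x2(hessian_at_scale(np.rot90(img), 1.0)), p
        ).v0
        np.testing.assert_allclose(vr, np.rot90(v), atol=1e-12)


class TestMultiscale:
    def test_single_scale_range_reduces_to_vesselness(self, rng):
        img = rng.random((40, 40))
        p = FrangiParams()
        ref = multiscale_frangi_reference(img, 1.0, 1.0, 1.0, p)
        single = vesselness(eigenvalues_sym2x2(hessian_at_scale(img, 1.0)), p)
        np.testing.assert_array_equal(ref.v0, single.v0)

    def test_matched_scale_for_ridge(self):
        # Gaussian ridge of width w=6 px (FWHM): the scale-normalized
        # response peaks near the theoretically matched sigma
        w = 6.0
        sig_r = w / (2 * np.sqrt(2 * np.log(2)))
        y = np.arange(81, dtype=float)[:, None]
        img = np.exp(-((y - 40.0) ** 2) / (2 * sig_r**2)) * np.ones((1, 81))
        p = FrangiParams(c=1.0)
        responses = []
        sigmas = np.arange(1.0, 8.0)
        for s in sigmas:
            v = vesselness(eigenvalues_sym2x2(hessian_at_scale(img, s)), p)
            responses.append(v.v0[40, 40])
        best = sigmas[int(np.argmax(responses))]
        matched = sig_r * np.sqrt(2)  # argmax of s^2/(s^2+sig_r^2)^(3/2) scaling
        assert abs(best - matched) <= 1.0

    def test_max_is_monotone_in_scale_set(self, rng):
        img = rng.random((40, 40))
        p = FrangiParams(c=0.5)
        sub = multiscale_frangi_reference(img, 1.0, 2.0, 1.0, p)
        sup = multiscale_frangi_reference(img, 1.0, 4.0, 1.0, p)
        assert np.all(sup.v0 >= sub.v0 - 1e-15)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            multiscale_frangi_reference(np.zeros((32, 32)), 2.0, 1.0)
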