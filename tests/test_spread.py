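"""Spread-function algebra: PSF, ring transform, GSF and joint profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.special import j0, j1, jn_zeros

from eisr import (
    build_scene,
    default_domain,
    figure_fixture,
    gsf,
    pair_profile,
    psf,
    reconstruct,
    ring_fourier_transform,
    two_cylinder_profile,
    two_point_profile,
    ScattererSpec,
)

from _oracles import (
    annulus_transform_profile,
    central_difference,
    central_second_difference,
)


class TestPSF:
    def test_unity_at_origin(self, cfg):
        assert psf(0.0, cfg) == pytest.approx(1.0)

    def test_first_zero_at_rayleigh_distance(self, cfg):
        x0 = jn_zeros(0, 1)[0] / cfg.wavenumber
        assert x0 == pytest.approx(0.3827, abs=5e-4)
        assert psf(x0, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_matches_angular_integral_representation(self, cfg):
        """The PSF amplitude is the angular average of exp(j k0 x cosθ)."""
        x = 0.25 * cfg.wavelength
        re = quad(lambda t: np.cos(cfg.wavenumber * x * np.cos(t)), 0, 2 * np.pi)[0]
        im = quad(lambda t: np.sin(cfg.wavenumber * x * np.cos(t)), 0, 2 * np.pi)[0]
        amplitude = (re + 1j * im) / (2 * np.pi)
        assert abs(amplitude.imag) < 1e-12
        assert psf(x, cfg) == pytest.approx(amplitude.real**2, rel=1e-10)


class TestRingTransform:
    def test_value_at_origin(self, cfg):
        k0 = cfg.wavenumber
        dR = 0.01
        assert ring_fourier_transform(k0 / (2 * np.pi), dR, 0.0) == pytest.approx(
            k0 * dR
        )

    def test_thick_annulus_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            ring_fourier_transform(1.0, 2.0, 0.0)

    def test_sign_change_at_bessel_root(self, cfg):
        k0 = cfg.wavenumber
        rho0 = jn_zeros(0, 1)[0] / k0
        lo = ring_fourier_transform(k0 / (2 * np.pi), 0.01, rho0 - 1e-3)
        hi = ring_fourier_transform(k0 / (2 * np.pi), 0.01, rho0 + 1e-3)
        assert lo > 0 > hi

    def test_matches_dense_discrete_transform(self, cfg):
        """Analytic thin-ring transform vs a brute-force pixel sum, to 1%."""
        R = cfg.wavenumber / (2 * np.pi)
        dR = R / 100
        rhos = np.linspace(0.0, 2.0 * cfg.wavelength, 81)
        dense = annulus_transform_profile(R, dR, rhos)
        analytic = ring_fourier_transform(R, dR, rhos)
        analytic = analytic / analytic[0]
        assert np.max(np.abs(dense - analytic)) < 0.01


class TestGSF:
    def test_single_cell_scene_recovers_psf(self, cfg):
        scene = build_scene(
            [ScattererSpec("point", (0.0, 0.0), 0.0, 1.1)], default_domain(), cfg
        )
        image = gsf(scene, cfg)
        iy, ix = np.unravel_index(np.argmax(scene.chi), scene.chi.shape)
        x = scene.domain.x_centers
        x0 = x[ix]
        reference = psf(x - x0, cfg)
        inside = np.abs(x - x0) <= 2.9 * cfg.wavelength
        np.testing.assert_allclose(
            image[iy, inside], reference[inside], atol=1e-10
        )

    def test_empty_scene_gives_zero_profile(self, cfg):
        scene = build_scene([], default_domain(), cfg)
        assert not np.any(gsf(scene, cfg))

    def test_matches_born_reconstruction_of_point(self):
        """GSF and the full BA pipeline agree on the point image, RMS ≤ 0.05."""
        scene, config, ring = figure_fixture("fig2")
        conv = gsf(scene, config)
        image = reconstruct(scene, ring, config)
        x, recon_prof = image.cross_section(0.0)
        iy, _ = np.unravel_index(np.argmax(scene.chi), scene.chi.shape)
        conv_prof = conv[iy, :]
        mask = np.abs(x) <= config.wavelength
        rms = np.sqrt(np.mean((conv_prof[mask] - recon_prof[mask]) ** 2))
        assert rms <= 0.05

    def test_two_cylinder_cross_section_close_to_interval_profile(self, cfg):
        """2-D disk convolution vs the 1-D interval reduction of it.

        The two are different models of the same image; their normalised
        cross-sections agree to ~1% RMS at the Sparrow separation, and the
        bound here records that measured discrepancy with margin.
        """
        d = 0.352
        specs = [
            ScattererSpec("cylinder", (-d / 2, 0.0), 0.1, 1.1),
            ScattererSpec("cylinder", (+d / 2, 0.0), 0.1, 1.1),
        ]
        scene = build_scene(specs, default_domain(), cfg)
        conv = gsf(scene, cfg)
        iy = np.argmin(np.abs(scene.domain.y_centers))
        x = scene.domain.x_centers
        conv_prof = conv[iy, :]
        profile = two_cylinder_profile(d, 0.1, 0.1, (1.0, 1.0), cfg)
        direct = profile(x)
        direct = direct / direct.max()
        conv_prof = conv_prof / conv_prof.max()
        mask = np.abs(x) <= cfg.wavelength
        rms = np.sqrt(np.mean((conv_prof[mask] - direct[mask]) ** 2))
        assert rms <= 0.05


class TestTwoPointProfile:
    @given(x=st.floats(-1.0, 1.0))
    def test_equal_weights_give_even_profile(self, cfg, x):
        profile = two_point_profile(0.3, (1.0, 1.0), cfg)
        assert profile(x) == pytest.approx(profile(-x), rel=1e-12, abs=1e-15)

    def test_curvature_vanishes_at_sparrow_separation(self, cfg):
        lam = cfg.wavelength
        profile = two_point_profile(0.344404 * lam, (1.0, 1.0), cfg)
        scale = abs(two_point_profile(0.3 * lam, (1.0, 1.0), cfg).second_derivative(0.0))
        assert abs(profile.second_derivative(0.0)) < 1e-4 * scale

    def test_is_sum_of_single_point_spread_functions(self, cfg):
        d, w1, w2 = 0.37, 0.4, 1.3
        profile = two_point_profile(d, (w1, w2), cfg)
        xs = np.linspace(-1, 1, 101)
        expected = w1 * psf(xs + d / 2, cfg) + w2 * psf(xs - d / 2, cfg)
        np.testing.assert_allclose(profile(xs), expected, rtol=1e-12)

    def test_analytic_derivatives_match_finite_differences(self, cfg):
        rng = np.random.default_rng(11)
        profile = two_point_profile(0.38, (0.1, 0.2), cfg)
        xs = rng.uniform(-0.8, 0.8, size=100)
        h = 1e-5 * cfg.wavelength
        fd1 = central_difference(profile, xs, h)
        fd2 = central_second_difference(profile, xs, h)
        an1 = profile.first_derivative(xs)
        an2 = profile.second_derivative(xs)
        scale1 = np.max(np.abs(an1))
        scale2 = np.max(np.abs(an2))
        assert np.max(np.abs(an1 - fd1)) / scale1 < 1e-5
        assert np.max(np.abs(an2 - fd2)) / scale2 < 1e-4

    def test_positivity(self, cfg):
        xs = np.linspace(-2, 2, 2001)
        for profile in (
            two_point_profile(0.3, (0.1, 0.2), cfg),
            two_cylinder_profile(0.4, 0.1, 0.15, (1.0, 1.0), cfg),
        ):
            assert np.all(profile(xs) >= 0)


class TestTwoCylinderProfile:
    def test_second_derivative_is_four_boundary_term_closed_form(self, cfg):
        """Equal pair: f'' must equal the explicit four-term J0·J1 expression."""
        k0 = cfg.wavenumber
        d, r = 0.36, 0.1
        profile = two_cylinder_profile(d, r, r, (1.0, 1.0), cfg)

        def four_term(x):
            t = lambda u: 2 * k0 * j0(k0 * u) * j1(k0 * u)
            return (
                t(x + d / 2 - r)
                - t(x + d / 2 + r)
                + t(x - d / 2 - r)
                - t(x - d / 2 + r)
            )

        xs = np.linspace(-0.5, 0.5, 41)
        np.testing.assert_allclose(
            profile.second_derivative(xs), four_term(xs), rtol=1e-12, atol=1e-12
        )

    def test_midpoint_parity_reduction(self, cfg):
        """At x = 0 the four terms collapse to 4k0 {J0J1(k0(d/2−r)) − J0J1(k0(d/2+r))}."""
        k0 = cfg.wavenumber
        for d, r in [(0.3, 0.05), (0.36, 0.1), (0.5, 0.15)]:
            profile = two_cylinder_profile(d, r, r, (1.0, 1.0), cfg)
            u, v = k0 * (d / 2 - r), k0 * (d / 2 + r)
            reduced = 4 * k0 * (j0(u) * j1(u) - j0(v) * j1(v))
            assert profile.second_derivative(0.0) == pytest.approx(reduced, rel=1e-12)

    def test_degenerate_radius_limit_recovers_point_profile(self, cfg):
        """As r → 0, the interval integrals (renormalised by 2r) → the PSFs."""
        r = 1e-5
        d = 0.37
        cyl = two_cylinder_profile(d, r, r, (1.0, 1.0), cfg)
        pts = two_point_profile(d, (1.0, 1.0), cfg)
        xs = np.linspace(-0.6, 0.6, 25)
        np.testing.assert_allclose(cyl(xs) / (2 * r), pts(xs), rtol=1e-6)

    def test_closed_form_curvature_matches_quadrature_profile(self, cfg):
        """f''(0) closed form vs second finite difference of the integral."""
        profile = two_cylinder_profile(0.4, 0.1, 0.15, (1.0, 2.0), cfg)
        fd = central_second_difference(profile, 0.0, 1e-4)
        an = profile.second_derivative(0.0)
        assert abs(an - fd) / abs(an) < 1e-4

    def test_invalid_inputs_rejected(self, cfg):
        with pytest.raises(ValueError):
            two_cylinder_profile(0.3, 0.0, 0.1, (1.0, 1.0), cfg)
        with pytest.raises(ValueError):
            pair_profile(-0.1, (0.0, 0.0), (1.0, 1.0), cfg)
        with pytest.raises(ValueError):
            pair_profile(0.3, (0.0, 0.0), (0.0, 1.0), cfg)
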