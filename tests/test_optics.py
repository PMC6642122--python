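"""Unit and property tests for the physical-optics primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siht.optics import (ComplexField, ConfigurationError, GridSpec,
                         OpticalConfig, SamplingError, ZernikeCoeffs,
                         blazed_grating_phase, cgh_phase, fft2c, fit_zernike,
                         fresnel_lens_phase, make_transfer_functions,
                         noll_to_nm, propagate_angular_spectrum,
                         sparrow_limit, total_power, zernike_mode,
                         zernike_phase)


# ---------------------------------------------------------------------------
# grids and configuration
# ---------------------------------------------------------------------------

class TestGridSpec:
    def test_centred_coordinates(self):
        g = GridSpec(32, 32, 50.0)
        assert g.x[16] == 0.0 and g.fv[16] == 0.0
        assert g.dfx == pytest.approx(1.0 / (32 * 50.0))

    @pytest.mark.parametrize("bad", [dict(nx=15), dict(nx=8), dict(pitch=-1.0)])
    def test_invalid_grid_rejected(self, bad):
        kw = dict(nx=32, ny=32, pitch=40.0)
        kw.update(bad)
        with pytest.raises(ConfigurationError):
            GridSpec(**kw)

    def test_nyquist_check_for_synthetic_aperture(self, cfg):
        GridSpec(64, 64, 140.0).validate_for(cfg)     # 147.8 nm limit
        with pytest.raises(SamplingError):
            GridSpec(64, 64, 150.0).validate_for(cfg)

    @pytest.mark.parametrize("bad", [dict(na_ill=0.0), dict(na_det=1.5),
                                     dict(wavelength=-5.0),
                                     dict(focal_length=0.0)])
    def test_invalid_optics_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            OpticalConfig(**bad)


# ---------------------------------------------------------------------------
# CGH phase functions
# ---------------------------------------------------------------------------

class TestCGHPhases:
    # a grid whose pixel (24, 24) sits exactly at x = y = 1 mm
    mm_grid = GridSpec(32, 32, 1.25e5)

    def test_fresnel_lens_origin_and_point_value(self, cfg):
        phase = fresnel_lens_phase(self.mm_grid, cfg)
        assert phase[16, 16] == 0.0
        # direct scalar evaluation: pi * (x^2+y^2) / (lambda f)
        expect = math.pi * (2.0 * (1e6) ** 2) / (532.0 * 250.0e6)
        assert phase[24, 24] == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(47.242, abs=5e-4)

    def test_fresnel_requires_positive_focal_length(self):
        with pytest.raises(ConfigurationError):
            OpticalConfig(focal_length=-250.0)

    def test_blazed_origin_and_periodicity(self, cfg):
        g = GridSpec(64, 64, 6.4e3)   # 8 pixels per 51.2 um period
        phase = blazed_grating_phase(g, cfg, rotation=0.0)
        assert phase[32, 32] == 0.0
        assert phase[32, 40] - phase[32, 32] == pytest.approx(2.0 * math.pi)

    def test_blazed_far_field_single_displaced_order(self, cfg):
        g = GridSpec(128, 128, 6.4e3)
        # grating frequency = 1/51.2 um -> exactly 16 frequency pixels
        field = np.exp(1j * blazed_grating_phase(g, cfg, rotation=0.0))
        spec = np.abs(fft2c(field))
        iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
        assert (iy, ix) == (64, 64 + 16)
        # a single order: the peak carries essentially all power
        assert spec[iy, ix] ** 2 / total_power(spec) > 0.999

    def test_cgh_is_fresnel_plus_blaze(self, cfg):
        g = GridSpec(64, 64, 6.4e3)
        total = cgh_phase(g, cfg, axis="x")
        parts = fresnel_lens_phase(g, cfg) + blazed_grating_phase(g, cfg, 0.0)
        np.testing.assert_allclose(total, parts, rtol=0, atol=1e-9)

    def test_cgh_axis_convention_rotates_ramp(self, cfg):
        g = GridSpec(64, 64, 6.4e3)
        ramp_y = cgh_phase(g, cfg, axis="y") - fresnel_lens_phase(g, cfg)
        np.testing.assert_allclose(
            ramp_y, blazed_grating_phase(g, cfg, rotation=math.pi / 2),
            rtol=0, atol=1e-9)

    def test_cgh_compensation_is_added_as_given(self, cfg):
        g = GridSpec(64, 64, 6.4e3)
        comp = ZernikeCoeffs({4: 0.25})
        base = cgh_phase(g, cfg, axis="x")
        with_comp = cgh_phase(g, cfg, axis="x", compensation=comp)
        aperture = 32 * g.pitch
        expected = 2 * math.pi * zernike_phase(comp, g, aperture, space="object")
        np.testing.assert_allclose(with_comp - base, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# Zernike basis
# ---------------------------------------------------------------------------

class TestZernike:
    def test_noll_table_low_orders(self):
        assert noll_to_nm(1) == (0, 0)
        assert noll_to_nm(4) == (2, 0)
        assert noll_to_nm(7) == (3, -1)   # vertical coma is a sine mode
        assert noll_to_nm(11) == (4, 0)

    def test_piston_is_constant_inside_pupil(self):
        g = GridSpec(64, 64, 40.0)
        w = zernike_phase(ZernikeCoeffs({1: 1.0}), g, 1e-3)
        fu, fv = g.fmesh()
        inside = np.hypot(fu, fv) <= 1e-3
        np.testing.assert_allclose(w[inside], 1.0)
        np.testing.assert_allclose(w[~inside], 0.0)

    def test_defocus_closed_form(self):
        rho = np.array([0.0, 0.5, 1.0])
        z = zernike_mode(4, rho, np.zeros(3))
        np.testing.assert_allclose(z, math.sqrt(3) * (2 * rho ** 2 - 1),
                                   rtol=1e-12)
        assert z[2] == pytest.approx(math.sqrt(3))

    def test_modes_orthonormal_under_quadrature(self):
        n = 512
        x = (np.arange(n) + 0.5) / n * 2 - 1
        xx, yy = np.meshgrid(x, x)
        rho, th = np.hypot(xx, yy), np.arctan2(yy, xx)
        disk = rho <= 1.0
        modes = range(2, 16)
        vals = {j: zernike_mode(j, rho[disk], th[disk]) for j in modes}
        for j in modes:
            assert np.mean(vals[j] * vals[j]) == pytest.approx(1.0, abs=2e-3)
            for k in modes:
                if k > j:
                    assert abs(np.mean(vals[j] * vals[k])) < 2e-3

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            zernike_mode(0, np.array([0.5]), np.array([0.0]))
        with pytest.raises(ValueError):
            ZernikeCoeffs({-3: 0.1})

    def test_synthesis_then_fit_round_trip(self):
        g = GridSpec(128, 128, 40.0)
        coeffs = ZernikeCoeffs({4: 0.3, 6: -0.2, 9: 0.07, 11: 0.15})
        w = zernike_phase(coeffs, g, 1.5e-3)
        got = fit_zernike(w, g, 1.5e-3, modes=range(2, 16))
        for j in range(2, 16):
            assert got.get(j) == pytest.approx(coeffs.get(j), abs=1e-6)

    def test_rms_is_quadrature_sum(self):
        c = ZernikeCoeffs({4: 0.3, 7: 0.4})
        assert c.rms() == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# transfer functions
# ---------------------------------------------------------------------------

class TestTransferFunctions:
    def test_zero_aberration_gives_binary_pupil(self, cfg, grid256):
        tf = make_transfer_functions(cfg, grid256)
        np.testing.assert_array_equal(tf.ctf, tf.a_d)
        assert set(np.unique(tf.a_d)) == {0.0, 1.0}

    def test_pupil_area_matches_analytic_disk(self, cfg, grid256):
        tf = make_transfer_functions(cfg, grid256)
        r_px = cfg.cutoff_det / grid256.dfx
        count = tf.a_d.sum()
        assert abs(count - math.pi * r_px ** 2) < 2 * math.pi * r_px + 1

    def test_aberrated_ctf_has_unit_magnitude_inside(self, cfg, grid256):
        tf = make_transfer_functions(cfg, grid256,
                                     ZernikeCoeffs({4: 0.5, 7: 0.2}))
        inside = tf.a_d > 0
        np.testing.assert_allclose(np.abs(tf.ctf[inside]), 1.0, rtol=1e-12)
        np.testing.assert_array_equal(tf.ctf[~inside], 0.0)

    def test_pupil_exceeding_grid_raises(self, cfg):
        # pitch 280 nm -> f_max = 1.79e-3 < NA/lambda would fit, go coarser
        with pytest.raises(SamplingError):
            make_transfer_functions(cfg, GridSpec(64, 64, 320.0))


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _bandlimited_field(grid, cfg, seed=0):
    rng = np.random.default_rng(seed)
    spec = np.zeros(grid.shape, complex)
    fu, fv = grid.fmesh()
    band = np.hypot(fu, fv) < 0.8 / cfg.wavelength
    spec[band] = rng.normal(size=band.sum()) + 1j * rng.normal(size=band.sum())
    from siht.optics import ifft2c
    return ComplexField(grid, ifft2c(spec))


class TestPropagation:
    def test_zero_distance_is_identity(self, cfg, grid256):
        f = _bandlimited_field(grid256, cfg)
        out = propagate_angular_spectrum(f, 0.0, cfg)
        np.testing.assert_array_equal(out.values, f.values)

    def test_power_conserved_for_propagating_field(self, cfg, grid256):
        f = _bandlimited_field(grid256, cfg)
        out = propagate_angular_spectrum(f, 3.7e4, cfg)
        assert abs(out.power - f.power) / f.power < 1e-10

    def test_forward_backward_round_trip(self, cfg, grid256):
        f = _bandlimited_field(grid256, cfg, seed=3)
        out = propagate_angular_spectrum(
            propagate_angular_spectrum(f, 2.5e4, cfg), -2.5e4, cfg)
        rms = np.sqrt(np.mean(np.abs(out.values - f.values) ** 2)
                      / np.mean(np.abs(f.values) ** 2))
        assert rms < 1e-8

    def test_plane_wave_picks_up_analytic_phase(self, cfg, grid256):
        # tilted plane wave on an exact grid frequency, inside 1/lambda
        k = 15
        ix = np.arange(256) - 128
        wave = np.exp(2j * math.pi * k * ix / 256)[None, :] * np.ones((256, 1))
        f = ComplexField(grid256, wave)
        d = 1.23e4
        out = propagate_angular_spectrum(f, d, cfg)
        fx = k * grid256.dfx
        kz = math.sqrt(1.0 / cfg.wavelength ** 2 - fx ** 2)
        expect = np.exp(2j * math.pi * d * kz)
        np.testing.assert_allclose(out.values / f.values, expect, rtol=1e-9)

    def test_edge_energy_warns(self, cfg, grid256):
        rng = np.random.default_rng(0)
        f = ComplexField(grid256, rng.normal(size=grid256.shape) + 0j)
        with pytest.warns(RuntimeWarning):
            propagate_angular_spectrum(f, 1e4, cfg)


# ---------------------------------------------------------------------------
# resolution criterion
# ---------------------------------------------------------------------------

class TestSparrowLimit:
    def test_printed_instrument_values(self):
        assert round(sparrow_limit(532.0, 0.9)) == 455
        assert sparrow_limit(532.0, 1.8) == pytest.approx(227.6, abs=0.1)

    @given(st.floats(0.05, 1.0), st.floats(200.0, 1500.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_doubling_na_halves_the_limit(self, na, lam):
        assert sparrow_limit(lam, 2 * na) == pytest.approx(
            sparrow_limit(lam, na) / 2.0, rel=1e-12)

    def test_non_positive_na_rejected(self):
        with pytest.raises(ConfigurationError):
            sparrow_limit(532.0, 0.0)
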