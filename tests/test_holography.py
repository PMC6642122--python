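"""Tests for off-axis demodulation, passband separation and unwrapping."""

import math

import numpy as np
import pytest

from siht.forward import (DEFAULT_PHASE_SHIFTS, build_scan_schedule,
                          record_offaxis_hologram, simulate_si_exposure)
from siht.holography import (DemodulationError, MixingMatrix, PassbandSet,
                             SeparationError, demodulate_offaxis,
                             separate_passbands, unwrap_phase)
from siht.optics import (ComplexField, GridSpec, ZernikeCoeffs, fft2c, ifft2c,
                         make_transfer_functions, zernike_phase)


class TestDemodulation:
    def test_plane_wave_object_round_trip(self, cfg, grid256):
        """A tilted plane-wave image field is recovered with its linear
        phase intact."""
        k = 9
        ix = np.arange(256) - 128
        wave = np.exp(2j * math.pi * k * ix / 256)[None, :] * np.ones((256, 1))
        fld = ComplexField(grid256, wave, plane="image")
        holo = record_offaxis_hologram(fld, cfg)
        rec = demodulate_offaxis(holo, cfg)
        amp = np.abs(rec.values)
        assert amp.std() / amp.mean() < 1e-6
        err = np.abs(rec.values - fld.values)
        assert np.sqrt(np.mean(err ** 2)) < 0.01

    def test_simulated_exposure_round_trip(self, cfg, star256, grid256):
        s = build_scan_schedule(cfg, grid256, 2)
        fld = simulate_si_exposure(star256, s, 0, 0, cfg)
        holo = record_offaxis_hologram(fld, cfg)
        rec = demodulate_offaxis(holo, cfg)
        tf = make_transfer_functions(cfg, grid256)
        m = tf.a_d > 0
        fs, rs = fft2c(fld.values), fft2c(rec.values)
        err = np.sqrt(np.sum(np.abs(rs[m] - fs[m]) ** 2)
                      / np.sum(np.abs(fs[m]) ** 2))
        assert err < 1e-3

    def test_missing_order_raises(self, cfg, star256, grid256):
        s = build_scan_schedule(cfg, grid256, 2)
        fld = simulate_si_exposure(star256, s, 0, 0, cfg)
        holo = record_offaxis_hologram(fld, cfg)
        holo.ref_carrier_px = (-110, 110)   # point far away from any order
        with pytest.raises(DemodulationError):
            demodulate_offaxis(holo, cfg)


class TestSeparation:
    def test_mixing_matrix_condition_number_constant(self):
        mix = MixingMatrix.from_shifts(DEFAULT_PHASE_SHIFTS)
        # frozen regression value: cond of the {0, 120 deg} mixing matrix
        assert mix.cond == pytest.approx(math.sqrt(3.0), rel=1e-12)
        ident = mix.pinv @ mix.matrix
        assert np.abs(ident - np.eye(2)).max() < 1e-12

    def test_identical_shifts_singular(self):
        with pytest.raises(SeparationError):
            MixingMatrix.from_shifts((0.5, 0.5))

    def _mix_fields(self, grid, d1, d2, shifts):
        out = []
        for p in shifts:
            spec = np.exp(1j * p) * d1 + np.exp(-1j * p) * d2
            out.append(ComplexField(grid, ifft2c(spec), plane="image"))
        return out

    def _schedule(self, cfg, grid):
        return build_scan_schedule(cfg, grid, 1)

    def test_forward_mixed_random_passbands_recovered_exactly(self, cfg,
                                                              grid256):
        rng = np.random.default_rng(5)
        shape = grid256.shape
        d1 = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        d2 = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        s = self._schedule(cfg, grid256)
        fields = self._mix_fields(grid256, d1, d2, s.phase_shifts)
        pb = separate_passbands(fields, s, 0)
        for got, truth, w in ((pb.recorded(0), d1, 0), (pb.recorded(1), d2, 1)):
            rel = np.sqrt(np.sum(np.abs(got - truth) ** 2)
                          / np.sum(np.abs(truth) ** 2))
            assert rel < 1e-10

    def test_degenerate_mixture_yields_null_second_passband(self, cfg,
                                                            grid256):
        rng = np.random.default_rng(6)
        d1 = rng.normal(size=grid256.shape) + 1j * rng.normal(size=grid256.shape)
        s = self._schedule(cfg, grid256)
        fields = self._mix_fields(grid256, d1, np.zeros_like(d1),
                                  s.phase_shifts)
        pb = separate_passbands(fields, s, 0)
        assert np.abs(pb.d2).max() < 1e-10 * np.abs(pb.d1).max()

    def test_separation_is_linear(self, cfg, grid256):
        rng = np.random.default_rng(7)
        shape = grid256.shape
        s = self._schedule(cfg, grid256)

        def sep(d1, d2):
            pb = separate_passbands(
                self._mix_fields(grid256, d1, d2, s.phase_shifts), s, 0)
            return pb.d1, pb.d2

        pairs = [(rng.normal(size=shape) + 1j * rng.normal(size=shape),
                  rng.normal(size=shape) + 1j * rng.normal(size=shape))
                 for _ in range(2)]
        a, b = 1.7 - 0.3j, -0.8 + 2.1j
        lhs = sep(a * pairs[0][0] + b * pairs[1][0],
                  a * pairs[0][1] + b * pairs[1][1])
        rhs0 = sep(*pairs[0])
        rhs1 = sep(*pairs[1])
        for i in range(2):
            np.testing.assert_allclose(lhs[i], a * rhs0[i] + b * rhs1[i],
                                       atol=1e-9)

    def test_overdetermined_three_shifts(self, cfg, grid256):
        import dataclasses
        rng = np.random.default_rng(8)
        shape = grid256.shape
        d1 = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        d2 = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        base = build_scan_schedule(cfg, grid256, 1,
                                   phase_shifts=(0.0, 2 * math.pi / 3,
                                                 4 * math.pi / 3))
        fields = self._mix_fields(grid256, d1, d2, base.phase_shifts)
        pb = separate_passbands(fields, base, 0)
        rel = np.sqrt(np.sum(np.abs(pb.recorded(0) - d1) ** 2)
                      / np.sum(np.abs(d1) ** 2))
        assert rel < 1e-10

    def test_wrong_exposure_count_rejected(self, cfg, grid256):
        s = self._schedule(cfg, grid256)
        one = [ComplexField(grid256, np.ones(grid256.shape, complex))]
        with pytest.raises(ValueError):
            separate_passbands(one, s, 0)


class TestUnwrap:
    def test_smooth_phase_is_identity(self):
        x = np.linspace(-1, 1, 64)
        phase = 0.8 * np.add.outer(x, x)
        np.testing.assert_array_equal(unwrap_phase(phase), phase)

    def test_defocus_six_waves_round_trip(self):
        # a smooth edge-free defocus surface, ~6 waves peak-to-valley
        x = np.linspace(-1.0, 1.0, 256)
        xx, yy = np.meshgrid(x, x)
        truth = 2 * math.pi * 3.0 * (xx ** 2 + yy ** 2 - 1.0)
        wrapped = np.angle(np.exp(1j * truth))
        unwrapped = unwrap_phase(wrapped)
        diff = unwrapped - truth
        diff -= diff.mean()          # unwrapping is defined up to 2 pi k
        assert np.sqrt(np.mean(diff ** 2)) / (2 * math.pi) < 1e-6

    def test_rewrap_reproduces_input(self):
        rng = np.random.default_rng(0)
        smooth = np.cumsum(rng.normal(scale=0.05, size=(64, 64)), axis=1)
        wrapped = np.angle(np.exp(1j * smooth))
        out = unwrap_phase(wrapped)
        rewrapped = np.angle(np.exp(1j * out))
        np.testing.assert_allclose(rewrapped, wrapped, atol=1e-9)

    def test_noisy_phase_warns_about_residues(self):
        rng = np.random.default_rng(1)
        noisy = rng.uniform(-math.pi, math.pi, size=(64, 64))
        with pytest.warns(RuntimeWarning):
            unwrap_phase(noisy)
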