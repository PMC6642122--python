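"""Tests for the SI hologram forward simulator."""

import math

import numpy as np
import pytest

from siht.forward import (DEFAULT_PHASE_SHIFTS, ScanSchedule,
                          build_scan_schedule, record_offaxis_hologram,
                          reference_wave, si_illumination,
                          simulate_hologram_set, simulate_si_exposure)
from siht.optics import (ComplexField, ConfigurationError, GridSpec,
                         SamplingError, ZernikeCoeffs, fft2c,
                         make_transfer_functions, total_power)


class TestScanSchedule:
    def test_instrument_bookkeeping_60_pairs(self, cfg, grid1024):
        s = build_scan_schedule(cfg, grid1024, 60)
        assert s.pair_count == 60
        assert s.passband_count == 120
        assert s.exposure_count == 120  # two phase shifts per orientation

    def test_single_orientation_two_displaced_carriers(self, cfg, grid256):
        s = build_scan_schedule(cfg, grid256, 1)
        (k1, k2) = s.carriers_px[0]
        assert k1 != k2
        # x-axis CGH displaces along u, y-axis CGH along v
        assert k1[1] == 0 and k2[0] == 0

    def test_uniform_orientation_spacing(self, cfg, grid256):
        s = build_scan_schedule(cfg, grid256, 12)
        diffs = np.diff(list(s.orientations))
        np.testing.assert_allclose(diffs, 2 * math.pi / 12, rtol=1e-12)

    def test_carriers_sit_inside_both_pupils(self, cfg, grid512):
        s = build_scan_schedule(cfg, grid512, 16)
        r_cap = cfg.cutoff_det / grid512.dfx
        for k1, k2 in s.carriers_px:
            assert math.hypot(*k1) <= r_cap
            assert math.hypot(*k2) <= r_cap
            # and close to the nominal illumination radius
            assert math.hypot(*k1) > r_cap - 2.0

    def test_phase_shift_defaults(self, cfg, grid256):
        s = build_scan_schedule(cfg, grid256, 2)
        assert s.phase_shifts == pytest.approx((0.0, 2 * math.pi / 3))


class TestSIExposure:
    def test_empty_object_has_two_carrier_peaks(self, cfg, grid256):
        s = build_scan_schedule(cfg, grid256, 4)
        obj = ComplexField(grid256, np.ones(grid256.shape, complex))
        fld = simulate_si_exposure(obj, s, 0, 0, cfg)
        spec = np.abs(fft2c(fld.values))
        top2 = np.argsort(spec.ravel())[-2:]
        peaks = {tuple(np.array(np.unravel_index(i, spec.shape)) - 128)
                 for i in top2}
        (k1, k2) = s.carriers_px[0]
        assert peaks == {(-k1[1], -k1[0]), (-k2[1], -k2[0])}

    def test_moire_downmodulation_of_superresolution_content(self, cfg,
                                                             grid256):
        """Object frequency beyond the pupil appears inside the recorded
        spectrum, shifted by the illumination carrier."""
        s = build_scan_schedule(cfg, grid256, 1)
        (k1, _) = s.carriers_px[0]
        r_px = cfg.cutoff_det / grid256.dfx           # ~17.3 px
        k_obj = int(r_px) + 8                          # beyond the pupil
        assert k_obj * grid256.dfx > cfg.cutoff_det
        ix = np.arange(256) - 128
        obj = ComplexField(grid256, np.exp(
            0.3j * np.cos(2 * math.pi * k_obj * ix / 256))[None, :]
            * np.ones((256, 1)))
        fld = simulate_si_exposure(obj, s, 0, 0, cfg)
        spec = np.abs(fft2c(fld.values))
        # the +k_obj component rides carrier -k1 into the passband
        assert spec[128, 128 + k_obj - k1[0]] > 1e3 * spec[128, 128 - 5]

    def test_normal_incidence_reduces_to_plain_coherent_imaging(self, cfg,
                                                                star256,
                                                                grid256):
        sched = ScanSchedule(orientations=(0.0,),
                             phase_shifts=DEFAULT_PHASE_SHIFTS,
                             carrier_freq=0.0,
                             carriers_px=(((0, 0), (0, 0)),),
                             grid=grid256)
        fld = simulate_si_exposure(star256, sched, 0, 0, cfg)
        tf = make_transfer_functions(cfg, grid256)
        expect = 2.0 * np.cos(DEFAULT_PHASE_SHIFTS[0]) * fft2c(star256.values) * tf.ctf
        np.testing.assert_allclose(fft2c(fld.values), expect, atol=1e-9)

    def test_aberration_compensation_cancels_exactly(self, cfg, star256,
                                                     grid256):
        s = build_scan_schedule(cfg, grid256, 2)
        w = ZernikeCoeffs({4: 0.4, 7: -0.25})
        clean = simulate_si_exposure(star256, s, 0, 0, cfg)
        corrected = simulate_si_exposure(star256, s, 0, 0, cfg,
                                         aberration=w, compensation=-w)
        np.testing.assert_allclose(corrected.values, clean.values, atol=1e-9)

    def test_no_energy_gain_through_the_system(self, cfg, star256, grid256):
        s = build_scan_schedule(cfg, grid256, 2)
        fld = simulate_si_exposure(star256, s, 0, 0, cfg)
        illum = si_illumination(s, 0, 0)
        assert fld.power <= total_power(star256.values * illum) * (1 + 1e-12)

    def test_passbands_overlap_in_frequency(self, cfg, grid256):
        s = build_scan_schedule(cfg, grid256, 4)
        r_px = cfg.cutoff_det / grid256.dfx
        (k1, k2) = s.carriers_px[0]
        assert math.hypot(k1[0] - k2[0], k1[1] - k2[1]) < 2 * r_px

    def test_carrier_beyond_nyquist_raises(self, cfg, grid256):
        sched = ScanSchedule(orientations=(0.0,),
                             phase_shifts=DEFAULT_PHASE_SHIFTS,
                             carrier_freq=0.0,
                             carriers_px=(((115, 0), (0, 115)),),
                             grid=grid256)
        obj = ComplexField(grid256, np.ones(grid256.shape, complex))
        with pytest.raises((SamplingError, ConfigurationError)):
            simulate_si_exposure(obj, sched, 0, 0, cfg)


class TestHologramRecording:
    def test_zero_object_gives_flat_hologram(self, cfg, grid256):
        fld = ComplexField(grid256, np.zeros(grid256.shape, complex))
        holo = record_offaxis_hologram(fld, cfg, ref_amplitude=1.0)
        np.testing.assert_allclose(holo.values, 1.0, rtol=1e-12)

    def test_hologram_spectrum_is_hermitian(self, cfg, star256):
        fld = ComplexField(star256.grid, star256.values, plane="image")
        holo = record_offaxis_hologram(fld, cfg)
        spec = np.fft.fft2(holo.values)
        mirrored = np.conj(spec[np.ix_(-np.arange(256) % 256,
                                       -np.arange(256) % 256)])
        np.testing.assert_allclose(spec, mirrored, atol=1e-6 * np.abs(spec).max())

    def test_reference_carrier_separation_enforced(self, cfg, grid256):
        with pytest.raises(ConfigurationError):
            reference_wave(grid256, cfg, carrier_px=(10, 10))

    def test_shot_noise_statistics_on_flat_region(self, cfg, grid256):
        fld = ComplexField(grid256, np.zeros(grid256.shape, complex))
        holo = record_offaxis_hologram(fld, cfg, ref_amplitude=1.0,
                                       photons=1e4, seed=0)
        rel_std = holo.values.std() / holo.values.mean()
        assert rel_std == pytest.approx(1e-2, rel=0.1)

    def test_identical_seeds_bit_identical_sets(self, cfg, star256, grid256):
        s = build_scan_schedule(cfg, grid256, 2)
        h1, t1 = simulate_hologram_set(star256, s, cfg, photons=1e4, seed=42)
        h2, t2 = simulate_hologram_set(star256, s, cfg, photons=1e4, seed=42)
        assert len(h1) == len(h2) == 4
        for a, b in zip(h1, h2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_set_size_matches_schedule(self, cfg, star256, grid256):
        s = build_scan_schedule(cfg, grid256, 3)
        holos, truth = simulate_hologram_set(star256, s, cfg, photons=None)
        assert len(holos) == 6
        assert truth.schedule is s
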