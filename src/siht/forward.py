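"""Forward simulation of off-axis structured-illumination holograms.

One SI exposure illuminates the sample with the coherent sum of two tilted
plane waves (the +1 orders of the x- and y-axis CGHs), so its spectrum is
the sum of two object-spectrum copies displaced along u and v, each clipped
by the detection pupil and multiplied by the pupil aberration.  The two
copies overlap: object frequencies beyond the pupil are down-modulated into
it as moire beats, which is what the reconstruction chain later unmixes.

Conventions fixed here and shared with the reconstruction modules:

* the structured-illumination phase shift phi in {0 deg, 120 deg} multiplies
  passband D1 by exp(+j phi) and D2 by exp(-j phi);
* illumination carriers are rounded to integer frequency pixels so that
  passband re-centring is an exact array roll;
* the off-axis reference carrier sits on the grid diagonal at 3x the
  detection-pupil radius, which keeps the +1 order clear of the
  autocorrelation term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import (ComplexField, ConfigurationError, GridSpec, OpticalConfig,
                     SamplingError, ZernikeCoeffs, fft2c, ifft2c,
                     make_transfer_functions)

__all__ = [
    "DEFAULT_PHASE_SHIFTS",
    "DEFAULT_PHOTONS",
    "ScanSchedule",
    "Hologram",
    "SimTruth",
    "build_scan_schedule",
    "si_illumination",
    "simulate_si_exposure",
    "reference_wave",
    "record_offaxis_hologram",
    "simulate_hologram_set",
]

DEFAULT_PHASE_SHIFTS = (0.0, 2.0 * math.pi / 3.0)  # {0 deg, 120 deg}
DEFAULT_PHOTONS = 1.0e4


@dataclass(frozen=True)
class ScanSchedule:
    """Bookkeeping of the circular SI scan.

    ``carriers_px[m]`` holds the two integer-pixel carrier vectors
    ``(k1, k2)`` of orientation ``m`` as ``(kx, ky)`` pairs; ``k1`` descends
    from the x-axis CGH (displacement along u at orientation 0), ``k2`` from
    the y-axis CGH (displacement along v).  Each orientation contributes one
    hologram pair (two phase shifts) and two passbands.
    """

    orientations: tuple[float, ...]                 # radians
    phase_shifts: tuple[float, ...]                 # radians
    carrier_freq: float                             # nominal |f| in nm^-1
    carriers_px: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    grid: GridSpec

    def __post_init__(self) -> None:
        if len(self.carriers_px) != len(self.orientations):
            raise ValueError("one carrier pair per orientation required")
        if len(self.phase_shifts) < 2:
            raise ValueError("at least two phase shifts are required")

    @property
    def pair_count(self) -> int:
        return len(self.orientations)

    @property
    def passband_count(self) -> int:
        return 2 * self.pair_count

    @property
    def exposure_count(self) -> int:
        return len(self.phase_shifts) * self.pair_count

    def carrier_vectors(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        """Carrier frequency vectors (nm^-1) of orientation ``m``."""
        (k1, k2) = self.carriers_px[m]
        d = np.array([self.grid.dfx, self.grid.dfy])
        return np.array(k1) * d, np.array(k2) * d


def build_scan_schedule(cfg: OpticalConfig, grid: GridSpec, m_orientations: int,
                        phase_shifts: Sequence[float] = DEFAULT_PHASE_SHIFTS
                        ) -> ScanSchedule:
    """Uniform circular scan of ``m_orientations`` over 360 degrees.

    The two carriers of an orientation are 90 degrees apart (x- and y-axis
    CGHs rotated together) with magnitude NA_ill/lambda, rounded per
    component to the nearest frequency pixel.
    """
    if m_orientations < 1:
        raise ValueError("need at least one orientation")
    if grid.dfx != grid.dfy:
        raise SamplingError("anisotropic frequency grids are not supported")
    r_px = cfg.cutoff_ill / grid.dfx
    r_cap = min(r_px, cfg.cutoff_det / grid.dfx)
    angles = tuple(2.0 * math.pi * m / m_orientations
                   for m in range(m_orientations))
    carriers = []
    for a in angles:
        k1 = _round_carrier(r_px, r_cap, math.cos(a), math.sin(a))
        k2 = _round_carrier(r_px, r_cap, -math.sin(a), math.cos(a))
        carriers.append((k1, k2))
    return ScanSchedule(orientations=angles,
                        phase_shifts=tuple(float(p) for p in phase_shifts),
                        carrier_freq=cfg.cutoff_ill,
                        carriers_px=tuple(carriers),
                        grid=grid)


def _round_carrier(r_px: float, r_cap: float,
                   cx: float, cy: float) -> tuple[int, int]:
    """Round a carrier direction to integer pixels, kept just inside the
    pupil of radius ``r_cap`` so the carrier is transmitted un-clipped."""
    for shrink in np.arange(0.0, 2.0, 0.25):
        k = (round((r_px - shrink) * cx), round((r_px - shrink) * cy))
        if math.hypot(*k) <= r_cap:
            return k
    raise SamplingError("could not place the SI carrier inside the pupil")


def _ramp(grid: GridSpec, k: tuple[int, int]) -> np.ndarray:
    """exp(-2j pi (kx ix / nx + ky iy / ny)) for integer-pixel carrier k."""
    ix = np.arange(grid.nx) - grid.nx // 2
    iy = np.arange(grid.ny) - grid.ny // 2
    px = np.exp(-2j * math.pi * k[0] * ix / grid.nx)
    py = np.exp(-2j * math.pi * k[1] * iy / grid.ny)
    return np.outer(py, px)


def si_illumination(schedule: ScanSchedule, orientation: int,
                    shift_index: int) -> np.ndarray:
    """Coherent two-beam SI pattern of one exposure on the object grid."""
    phi = schedule.phase_shifts[shift_index]
    k1, k2 = schedule.carriers_px[orientation]
    return (np.exp(1j * phi) * _ramp(schedule.grid, k1)
            + np.exp(-1j * phi) * _ramp(schedule.grid, k2))


def net_aberration(aberration: ZernikeCoeffs | None,
                   compensation: ZernikeCoeffs | None) -> ZernikeCoeffs | None:
    """Pupil wavefront left after adding the CGH compensation term.

    ``compensation`` holds the *conjugate* (already negated) coefficients the
    adaptive loop folded into the CGHs, so the residual is their plain sum.
    """
    if compensation is None:
        return aberration
    if aberration is None:
        return compensation
    return aberration + compensation


def simulate_si_exposure(obj: ComplexField, schedule: ScanSchedule,
                         orientation: int, shift_index: int,
                         cfg: OpticalConfig,
                         aberration: ZernikeCoeffs | None = None,
                         compensation: ZernikeCoeffs | None = None,
                         ) -> ComplexField:
    """Image-plane field of one SI exposure.

    The object transmission is multiplied by the two-beam SI pattern, and
    the spectrum of the product is clipped by the aberrated detection CTF
    (the illumination pupil enters as the carrier-magnitude constraint).
    Raises :class:`SamplingError` when a carrier plus the detection pupil
    exceeds grid Nyquist.
    """
    grid = obj.grid
    if grid is not schedule.grid and grid != schedule.grid:
        raise ValueError("object and schedule grids differ")
    r_det_px = cfg.cutoff_det / grid.dfx
    for k in schedule.carriers_px[orientation]:
        if math.hypot(*k) > cfg.cutoff_ill / grid.dfx + 1.0:
            raise ConfigurationError("carrier outside the illumination NA")
        if abs(k[0]) + r_det_px >= grid.nx // 2 or abs(k[1]) + r_det_px >= grid.ny // 2:
            raise SamplingError("carrier plus detection pupil exceeds grid Nyquist")
    tf = make_transfer_functions(cfg, grid,
                                 net_aberration(aberration, compensation))
    illum = si_illumination(schedule, orientation, shift_index)
    spec = fft2c(obj.values * illum) * tf.ctf
    return ComplexField(grid, ifft2c(spec), plane="image")


# ---------------------------------------------------------------------------
# off-axis hologram recording
# ---------------------------------------------------------------------------

@dataclass
class Hologram:
    """A recorded intensity image plus the metadata needed to demodulate it."""

    values: np.ndarray              # real, non-negative
    grid: GridSpec
    ref_carrier_px: tuple[int, int]  # (kx, ky) of the reference ramp
    ref_amplitude: float
    orientation: int = 0
    shift_index: int = 0
    photons: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("hologram intensities must be finite and >= 0")


def reference_wave(grid: GridSpec, cfg: OpticalConfig,
                   carrier_px: tuple[int, int] | None = None,
                   amplitude: float = 1.0) -> tuple[np.ndarray, tuple[int, int]]:
    """Off-axis reference beam; default carrier on the diagonal at 3x the pupil.

    Raises :class:`ConfigurationError` when the carrier would let the +1
    order collide with the baseband autocorrelation (separation < 2x pupil)
    or exceed grid Nyquist.
    """
    r_det_px = cfg.cutoff_det / grid.dfx
    if carrier_px is None:
        k = round(3.0 * r_det_px / math.sqrt(2.0))
        carrier_px = (k, k)
    sep = math.hypot(*carrier_px)
    if sep < 2.0 * r_det_px:
        raise ConfigurationError(
            "reference carrier collides with the baseband autocorrelation")
    if abs(carrier_px[0]) + r_det_px >= grid.nx // 2 \
            or abs(carrier_px[1]) + r_det_px >= grid.ny // 2:
        raise SamplingError("reference carrier exceeds grid Nyquist")
    return amplitude * np.conj(_ramp(grid, carrier_px)), carrier_px


def record_offaxis_hologram(field: ComplexField, cfg: OpticalConfig,
                            photons: float | None = None,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            ref_carrier_px: tuple[int, int] | None = None,
                            ref_amplitude: float | None = None,
                            orientation: int = 0,
                            shift_index: int = 0) -> Hologram:
    """Record |object + reference|^2, optionally Poisson-corrupted.

    ``photons`` is the mean photon budget per pixel; noise is deterministic
    given ``seed`` (or an externally supplied ``rng``).
    """
    grid = field.grid
    if ref_amplitude is None:
        peak = float(np.abs(field.values).max())
        ref_amplitude = 2.0 * peak if peak > 0 else 1.0
    ref, carrier_px = reference_wave(grid, cfg, ref_carrier_px, ref_amplitude)
    intensity = np.abs(field.values + ref) ** 2
    if photons is not None:
        if rng is None:
            rng = np.random.default_rng(seed)
        mean = float(intensity.mean())
        if mean > 0:
            scale = photons / mean
            intensity = rng.poisson(intensity * scale).astype(float) / scale
    return Hologram(values=intensity, grid=grid, ref_carrier_px=carrier_px,
                    ref_amplitude=ref_amplitude, orientation=orientation,
                    shift_index=shift_index, photons=photons, seed=seed)


# ---------------------------------------------------------------------------
# full hologram sets
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Everything needed to re-create a simulated data set bit-for-bit."""

    aberration: ZernikeCoeffs | None
    compensation: ZernikeCoeffs | None
    photons: float | None
    seed: int | None
    schedule: ScanSchedule
    phantom: str = ""


def simulate_hologram_set(obj: ComplexField, schedule: ScanSchedule,
                          cfg: OpticalConfig,
                          aberration: ZernikeCoeffs | None = None,
                          compensation: ZernikeCoeffs | None = None,
                          photons: float | None = DEFAULT_PHOTONS,
                          seed: int | None = 0,
                          phantom: str = "") -> tuple[list[Hologram], SimTruth]:
    """Record the full schedule: pair_count x len(phase_shifts) holograms.

    The per-exposure noise streams are spawned from ``seed`` in a fixed
    order, so identical seeds give bit-identical sets.
    """
    rng = np.random.default_rng(seed) if photons is not None else None
    holos: list[Hologram] = []
    for m in range(schedule.pair_count):
        for k in range(len(schedule.phase_shifts)):
            fld = simulate_si_exposure(obj, schedule, m, k, cfg,
                                       aberration=aberration,
                                       compensation=compensation)
            holos.append(record_offaxis_hologram(
                fld, cfg, photons=photons, rng=rng,
                orientation=m, shift_index=k))
    truth = SimTruth(aberration=aberration, compensation=compensation,
                     photons=photons, seed=seed, schedule=schedule,
                     phantom=phantom)
    return holos, truth
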