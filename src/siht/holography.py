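"""Complex-field recovery and passband separation.

Off-axis demodulation crops the +1 interference order (a raised-cosine
apodised disk of 1.1x the detection-pupil radius around the reference
carrier), recentres it and inverse-transforms to the image-plane field.
The two overlapped SI passbands of a hologram pair are then unmixed by the
pseudoinverse of the phase-shift mixing matrix

    O_k = exp(+j phi_k) D1 + exp(-j phi_k) D2,

solved per frequency pixel; the pseudoinverse route keeps over-determined
shift sets (>= 3 exposures) working unchanged.  Separated passbands are
re-centred to their true spectral positions by exact integer-pixel rolls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase as _sk_unwrap

from .forward import Hologram, ScanSchedule
from .optics import (ComplexField, GridSpec, OpticalConfig, fft2c, ifft2c)

__all__ = [
    "DemodulationError",
    "SeparationError",
    "MixingMatrix",
    "PassbandSet",
    "demodulate_offaxis",
    "separate_passbands",
    "unwrap_phase",
]


class DemodulationError(RuntimeError):
    """The +1 order could not be located near its expected carrier."""


class SeparationError(RuntimeError):
    """The phase-shift mixing matrix is singular (or nearly so)."""


# ---------------------------------------------------------------------------
# off-axis demodulation
# ---------------------------------------------------------------------------

def _apodised_crop_mask(grid: GridSpec, center_px: tuple[int, int],
                        radius_px: float, guard: float = 0.1) -> np.ndarray:
    """Raised-cosine disk: 1 inside ``radius_px``, tapering to 0 at
    ``radius_px * (1 + guard)``, centred at integer pixel offset."""
    ix = np.arange(grid.nx) - grid.nx // 2 - center_px[0]
    iy = np.arange(grid.ny) - grid.ny // 2 - center_px[1]
    r = np.hypot(*np.meshgrid(ix, iy))
    r_out = radius_px * (1.0 + guard)
    mask = np.zeros(grid.shape)
    mask[r <= radius_px] = 1.0
    edge = (r > radius_px) & (r < r_out)
    mask[edge] = 0.5 * (1.0 + np.cos(math.pi * (r[edge] - radius_px)
                                     / (r_out - radius_px)))
    return mask


def demodulate_offaxis(holo: Hologram, cfg: OpticalConfig,
                       empty_threshold: float = 1e-8) -> ComplexField:
    """Recover the complex image-plane field from one off-axis hologram.

    The order containing the un-conjugated object field rides on
    ``exp(-j 2 pi f_R r)`` (object times conjugate reference), i.e. it is
    centred at minus the reference carrier.  As a guard against gross
    carrier-metadata mismatch the crop region must carry a non-negligible
    fraction of the spectrum's peak energy.
    """
    grid = holo.grid
    spec = fft2c(holo.values.astype(float))
    kx, ky = holo.ref_carrier_px
    cx, cy = -kx, -ky
    r_px = cfg.cutoff_det / grid.dfx
    mask = _apodised_crop_mask(grid, (cx, cy), r_px)
    signal = np.abs(spec[mask > 0]).max(initial=0.0)
    if signal < empty_threshold * np.abs(spec).max():
        raise DemodulationError(
            f"no +1 order found near expected carrier ({cx}, {cy})")
    cropped = np.roll(spec * mask, shift=(-cy, -cx), axis=(0, 1))
    field = ifft2c(cropped) / holo.ref_amplitude
    return ComplexField(grid, field, plane="image")


# ---------------------------------------------------------------------------
# passband separation
# ---------------------------------------------------------------------------

@dataclass
class MixingMatrix:
    """Phase-shift mixing of the two passbands and its pseudoinverse."""

    matrix: np.ndarray
    pinv: np.ndarray
    cond: float

    @classmethod
    def from_shifts(cls, shifts: tuple[float, ...] | list[float],
                    cond_limit: float = 1e8) -> "MixingMatrix":
        m = np.array([[np.exp(1j * p), np.exp(-1j * p)] for p in shifts])
        cond = float(np.linalg.cond(m))
        if not np.isfinite(cond) or cond > cond_limit:
            raise SeparationError(
                f"phase-shift set {tuple(shifts)} gives a singular mixing "
                f"matrix (condition number {cond:.3g})")
        return cls(matrix=m, pinv=np.linalg.pinv(m), cond=cond)


@dataclass
class PassbandSet:
    """The two separated passbands of one orientation.

    ``d1`` and ``d2`` are complex spectra *re-centred to their true
    positions* (the recorded copies sat displaced by minus their carrier);
    ``carriers_px`` keeps the integer-pixel carrier vectors used for the
    re-centring, ``cond`` the condition number of the mixing inversion.
    """

    d1: np.ndarray
    d2: np.ndarray
    carriers_px: tuple[tuple[int, int], tuple[int, int]]
    grid: GridSpec
    orientation: int
    cond: float

    def recorded(self, which: int) -> np.ndarray:
        """Undo the re-centring (passband as it sat in the recorded spectrum)."""
        d = (self.d1, self.d2)[which]
        kx, ky = self.carriers_px[which]
        return np.roll(d, shift=(-ky, -kx), axis=(0, 1))


def separate_passbands(fields: list[ComplexField],
                       schedule: ScanSchedule,
                       orientation: int) -> PassbandSet:
    """Unmix the overlapped passbands of one phase-shifted exposure set.

    ``fields`` are the demodulated image-plane fields of the orientation's
    exposures, ordered like ``schedule.phase_shifts``.
    """
    shifts = schedule.phase_shifts
    if len(fields) != len(shifts):
        raise ValueError(
            f"{len(shifts)} phase-shifted exposures expected, got {len(fields)}")
    mix = MixingMatrix.from_shifts(shifts)
    grid = fields[0].grid
    stack = np.stack([fft2c(f.values) for f in fields])      # (K, ny, nx)
    d = np.tensordot(mix.pinv, stack, axes=(1, 0))           # (2, ny, nx)
    (k1x, k1y), (k2x, k2y) = schedule.carriers_px[orientation]
    d1 = np.roll(d[0], shift=(k1y, k1x), axis=(0, 1))
    d2 = np.roll(d[1], shift=(k2y, k2x), axis=(0, 1))
    return PassbandSet(d1=d1, d2=d2,
                       carriers_px=schedule.carriers_px[orientation],
                       grid=grid, orientation=orientation, cond=mix.cond)


# ---------------------------------------------------------------------------
# phase unwrapping
# ---------------------------------------------------------------------------

def _residue_density(phase: np.ndarray) -> float:
    """Fraction of 2x2 plaquettes carrying a nonzero phase residue."""
    def w(a):
        return np.mod(a + math.pi, 2.0 * math.pi) - math.pi
    gx = w(np.diff(phase, axis=1))
    gy = w(np.diff(phase, axis=0))
    loop = gx[:-1, :] + gy[:, 1:] - gx[1:, :] - gy[:, :-1]
    return float(np.mean(np.abs(loop) > math.pi))


def unwrap_phase(phase: np.ndarray, mask: np.ndarray | None = None,
                 residue_warn: float = 0.01) -> np.ndarray:
    """Quality-guided 2-D phase unwrapping of a wrapped map in (-pi, pi].

    Re-wrapping the result reproduces the input modulo 2*pi exactly.  A
    warning is emitted when the residue density suggests the surface cannot
    be unwrapped consistently.  ``mask`` selects the valid region (True =
    valid); masked-out pixels are returned unchanged.
    """
    phase = np.asarray(phase, dtype=float)
    if _residue_density(phase) > residue_warn:
        warnings.warn("high phase-residue density: unwrapped surface may be "
                      "unreliable", RuntimeWarning, stacklevel=2)
    if mask is not None:
        ma = np.ma.array(phase, mask=~np.asarray(mask, dtype=bool))
        out = np.asarray(_sk_unwrap(ma))
        return np.where(mask, out, phase)
    smooth = (np.abs(np.diff(phase, axis=0)).max(initial=0.0) < math.pi
              and np.abs(np.diff(phase, axis=1)).max(initial=0.0) < math.pi
              and phase.max() - phase.min() < 2.0 * math.pi)
    if smooth:
        return phase.copy()
    return np.asarray(_sk_unwrap(phase))
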