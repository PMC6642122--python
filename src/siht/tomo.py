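"""3-D refractive-index tomography from angle-scanned complex fields.

The inversion is the standard optical-diffraction-tomography route: each
per-angle complex field, Rytov-linearised against its matching background,
samples the 3-D spectrum of the scattering potential

    V(r) = k^2 (n(r)^2 - n0^2),        k = 2 pi / lambda (vacuum)

on an Ewald cap displaced by the illumination vector (Fourier diffraction
theorem).  Nearest-voxel gridding with coverage counts fills a frequency
volume; the inverse transform plus Gerchberg-Papoulis-style constraint
iterations (non-negativity of n - n0, object support, frequency-domain data
consistency) mitigate the missing cone of circular scanning.

Rytov rather than Born linearisation is the default: for cell-scale phase
accumulation the complex logarithm stays in the weak regime where the Born
series has long diverged.  A first Born route is kept as a cross-check.

The module also provides an independent multislice (beam-propagation)
forward model used to generate per-angle fields for the SI-HT pipeline's
tomographic stage and for closed-loop phantom-recovery validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import fft as _fft
from scipy import ndimage

from .optics import GridSpec, OpticalConfig, SamplingError
from .phantoms import RIVolume

__all__ = [
    "FrequencyVolume",
    "AngleField",
    "rytov_phase",
    "born_field",
    "ewald_map",
    "invert_to_ri",
    "multislice_field",
    "tomo_carriers",
]


# ---------------------------------------------------------------------------
# per-angle linearised fields
# ---------------------------------------------------------------------------

def rytov_phase(field: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Complex Rytov phase psi = ln(u_s / u_b) with unwrapped imaginary part.

    ``field`` and ``background`` are complex fields at the in-focus plane
    (volume centre) under identical illumination.  Raises on zeros in the
    background.
    """
    from .holography import unwrap_phase  # local import avoids a cycle
    bg = np.asarray(background)
    if np.any(np.abs(bg) == 0.0):
        raise ValueError("background field contains zeros")
    ratio = np.asarray(field) / bg
    amp = np.abs(ratio)
    if np.any(amp == 0.0):
        raise ValueError("sample field contains zeros (Rytov log undefined)")
    return np.log(amp) + 1j * unwrap_phase(np.angle(ratio))


def born_field(field: np.ndarray, background: np.ndarray) -> np.ndarray:
    """First-Born equivalent scattered field u_b * psi -> u_s = u - u_b."""
    return np.asarray(field) - np.asarray(background)


@dataclass
class AngleField:
    """One linearised measurement: Rytov phase plus its illumination carrier.

    ``carrier_px`` is the integer-pixel transverse illumination frequency on
    the 2-D grid (positive convention ``exp(+2j pi f . r)``).
    """

    psi: np.ndarray
    carrier_px: tuple[int, int]


# ---------------------------------------------------------------------------
# Ewald mapping (Fourier diffraction theorem)
# ---------------------------------------------------------------------------

@dataclass
class FrequencyVolume:
    """Gridded scattering-potential spectrum with per-voxel coverage."""

    values: np.ndarray            # complex sums, DC-centred, shape (nz, ny, nx)
    coverage: np.ndarray          # int counts
    pitch: tuple[float, float, float]       # spatial voxel pitch (dx, dy, dz) nm
    n0: float
    wavelength: float

    @property
    def freq_pitch(self) -> tuple[float, float, float]:
        nz, ny, nx = self.values.shape
        dx, dy, dz = self.pitch
        return (1.0 / (nx * dx), 1.0 / (ny * dy), 1.0 / (nz * dz))

    def filled_fraction(self, within_band: bool = True) -> float:
        """Fraction of covered voxels (inside the synthetic band if asked)."""
        cover = self.coverage > 0
        if not within_band:
            return float(cover.mean())
        return float(cover.sum()) / cover.size


def ewald_map(angle_fields: Sequence[AngleField], grid: GridSpec,
              cfg: OpticalConfig, shape: tuple[int, int, int],
              pitch_z: float, n0: float = 1.34) -> FrequencyVolume:
    """Grid Rytov spectra onto their Ewald caps.

    The 2-D FFT of ``u_b * psi`` is the scattered spectrum shifted by the
    illumination carrier, so the FFT of ``psi`` itself is already indexed by
    the *relative* transverse frequency q = nu - nu_i; its Ewald-cap height
    is kz(nu) - kz(nu_i) with kz = sqrt((n0/lambda)^2 - |nu|^2).  Values are
    weighted by -4j pi kz(nu) per the Fourier diffraction theorem and
    accumulated into the nearest voxel.
    """
    nz, ny, nx = shape
    if (ny, nx) != grid.shape:
        raise ValueError("3-D transverse shape must match the 2-D field grid")
    dx = grid.pitch
    dnu_xy = 1.0 / (nx * dx)
    dnu_z = 1.0 / (nz * pitch_z)
    k_med = n0 / cfg.wavelength                      # medium wavenumber, cycles/nm
    qx = (np.arange(nx) - nx // 2) * dnu_xy
    qy = (np.arange(ny) - ny // 2) * dnu_xy
    qxx, qyy = np.meshgrid(qx, qy)

    values = np.zeros(shape, dtype=complex)
    coverage = np.zeros(shape, dtype=np.int32)
    d_area = dx * dx

    for af in angle_fields:
        if af.psi.shape != grid.shape:
            raise ValueError("psi shape does not match the grid")
        fi = (af.carrier_px[0] * dnu_xy, af.carrier_px[1] * dnu_xy)
        kz_i = k_med ** 2 - fi[0] ** 2 - fi[1] ** 2
        if kz_i <= 0:
            raise SamplingError("illumination carrier is evanescent")
        kz_i = math.sqrt(kz_i)
        # absolute detection frequency of every psi-spectrum pixel
        nu_x = qxx + fi[0]
        nu_y = qyy + fi[1]
        rho2 = nu_x ** 2 + nu_y ** 2
        det = rho2 <= cfg.cutoff_det ** 2
        prop = rho2 < k_med ** 2
        sel = det & prop
        kz = np.sqrt(np.where(prop, k_med ** 2 - rho2, np.nan))
        psi_hat = _fft.fftshift(_fft.fft2(_fft.ifftshift(af.psi))) * d_area
        vals = -4j * math.pi * kz[sel] * psi_hat[sel]
        # target voxel indices
        izf = (kz[sel] - kz_i) / dnu_z
        if np.any(np.abs(izf) > nz // 2 - 1):
            raise SamplingError("Ewald cap exceeds the axial Nyquist band")
        iz = np.rint(izf).astype(int) + nz // 2
        iy = np.nonzero(sel)[0] + 0        # psi-grid row index == q index
        ix = np.nonzero(sel)[1] + 0
        np.add.at(values, (iz, iy, ix), vals)
        np.add.at(coverage, (iz, iy, ix), 1)

    return FrequencyVolume(values=values, coverage=coverage,
                           pitch=(dx, dx, pitch_z), n0=n0,
                           wavelength=cfg.wavelength)


# ---------------------------------------------------------------------------
# constrained inversion
# ---------------------------------------------------------------------------

def invert_to_ri(fvol: FrequencyVolume, iterations: int = 50,
                 nonnegativity: bool = True,
                 support: np.ndarray | str | None = "auto",
                 support_threshold: float = 0.15,
                 support_dilation: int = 3,
                 callback: Callable[[int, np.ndarray], None] | None = None,
                 ) -> RIVolume:
    """Invert the gridded spectrum to n(x, y, z) with constraint iterations.

    Gerchberg-Papoulis style: alternate between (a) the object domain,
    where the potential is forced real, non-negative (n >= n0) and inside
    the support, and (b) the frequency domain, where measured voxels are
    reset to their coverage-averaged data.  ``support="auto"`` derives the
    support from the first pass (threshold at ``support_threshold`` of the
    maximum, dilated by ``support_dilation`` voxels); ``None`` disables the
    support constraint.  ``callback(iteration, n_volume)`` observes progress.
    """
    nz, ny, nx = fvol.values.shape
    dx, dy, dz = fvol.pitch
    known = fvol.coverage > 0
    data = np.where(known, fvol.values / np.maximum(fvol.coverage, 1), 0.0)
    k_vac = 2.0 * math.pi / fvol.wavelength
    inv_scale = 1.0 / (dx * dy * dz)     # integral measure of the inverse DFT

    def to_object(spec: np.ndarray) -> np.ndarray:
        v = _fft.fftshift(_fft.ifftn(_fft.ifftshift(spec))) * inv_scale
        return v.real

    def to_spectrum(v: np.ndarray) -> np.ndarray:
        return _fft.fftshift(_fft.fftn(_fft.ifftshift(v))) / inv_scale

    def as_ri(v: np.ndarray) -> np.ndarray:
        return np.sqrt(np.maximum(fvol.n0 ** 2 + v / k_vac ** 2, 1.0))

    v = to_object(data)
    sup_mask: np.ndarray | None
    if isinstance(support, str) and support == "auto":
        v0 = np.maximum(v, 0.0)
        thr = support_threshold * v0.max() if v0.max() > 0 else 0.0
        sup_mask = ndimage.binary_dilation(v0 > thr,
                                           iterations=max(support_dilation, 1))
    elif support is None:
        sup_mask = None
    else:
        sup_mask = np.asarray(support, dtype=bool)

    if callback is not None:
        callback(0, as_ri(np.maximum(v, 0.0) if nonnegativity else v))

    for it in range(1, iterations + 1):
        if nonnegativity:
            v = np.maximum(v, 0.0)
        if sup_mask is not None:
            v = np.where(sup_mask, v, 0.0)
        spec = to_spectrum(v)
        spec[known] = data[known]
        v = to_object(spec)
        if callback is not None:
            callback(it, as_ri(np.maximum(v, 0.0) if nonnegativity else v))

    if nonnegativity:
        v = np.maximum(v, 0.0)
    return RIVolume(as_ri(v), fvol.pitch)


# ---------------------------------------------------------------------------
# multislice forward model (independent of the FDT inverse)
# ---------------------------------------------------------------------------

def tomo_carriers(cfg: OpticalConfig, grid: GridSpec, m_orientations: int,
                  ) -> list[tuple[int, int]]:
    """Integer-pixel illumination carriers of a circular tomographic scan
    (both SI passband directions per orientation, as in the imaging chain)."""
    from .forward import build_scan_schedule
    sched = build_scan_schedule(cfg, grid, m_orientations)
    out: list[tuple[int, int]] = []
    for pair in sched.carriers_px:
        out.extend(pair)
    return out


def multislice_field(vol: RIVolume, carrier_px: tuple[int, int],
                     cfg: OpticalConfig, n0: float = 1.34,
                     band_limit: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Propagate a tilted plane wave through the volume slice by slice.

    Returns ``(u_sample, u_background)`` refocused to the volume-centre
    plane, both band-limited by the detection pupil when ``band_limit``.
    The background is the same numerical chain with the medium only, so
    numerical phase factors cancel exactly in the Rytov ratio.
    """
    nz, ny, nx = vol.values.shape
    dx, dy, dz = vol.pitch
    if dx != dy:
        raise SamplingError("anisotropic transverse sampling is not supported")
    grid = GridSpec(nx, ny, dx)
    fu, fv = grid.fmesh()
    k_med = n0 / cfg.wavelength
    arg = k_med ** 2 - fu ** 2 - fv ** 2
    prop = arg > 0
    kz = np.sqrt(np.where(prop, arg, 0.0))
    h_dz = np.where(prop, np.exp(2j * math.pi * dz * kz), 0.0)
    h_back = np.where(prop, np.exp(-2j * math.pi * (nz * dz / 2.0) * kz), 0.0)

    ix = np.arange(nx) - nx // 2
    iy = np.arange(ny) - ny // 2
    kx, ky = carrier_px
    u = np.outer(np.exp(2j * math.pi * ky * iy / ny),
                 np.exp(2j * math.pi * kx * ix / nx))
    ub = u.copy()

    def step(a: np.ndarray, kick: np.ndarray | None) -> np.ndarray:
        if kick is not None:
            a = a * kick
        spec = _fft.fft2(_fft.ifftshift(a))
        return _fft.fftshift(_fft.ifft2(spec * _fft.ifftshift(h_dz)))

    k_vac = 2.0 * math.pi / cfg.wavelength
    for iz in range(nz):
        kick = np.exp(1j * k_vac * (vol.values[iz] - n0) * dz)
        u = step(u, kick)
        ub = step(ub, None)

    def refocus(a: np.ndarray) -> np.ndarray:
        spec = _fft.fft2(_fft.ifftshift(a)) * _fft.ifftshift(h_back)
        if band_limit:
            pupil = _fft.ifftshift((fu ** 2 + fv ** 2) <= cfg.cutoff_det ** 2)
            spec = spec * pupil
        return _fft.fftshift(_fft.ifft2(spec))

    return refocus(u), refocus(ub)
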