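"""Physical-optics primitives for the SI-HT simulation chain.

Units convention (used across the whole package):

* lengths in nanometres (``x``, ``y``, ``pitch``, ``wavelength``, distances),
  except where a dataclass field explicitly says otherwise
  (:class:`OpticalConfig` stores the Fresnel-lens focal length in millimetres
  and the blazed-grating period in micrometres, the units instrument builders
  quote them in);
* spatial frequencies in cycles per nanometre (nm^-1);
* phase maps in radians unless a function explicitly returns waves.

All object-space grids are centred (origin at the pixel ``n // 2``) and all
spectra are stored DC-centred; :func:`fft2c` / :func:`ifft2c` implement the
centred, orthonormal transform pair used everywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from scipy import fft as _fft

__all__ = [
    "GridSpec",
    "OpticalConfig",
    "ComplexField",
    "ZernikeCoeffs",
    "TransferFunctions",
    "ConfigurationError",
    "SamplingError",
    "fft2c",
    "ifft2c",
    "total_power",
    "fresnel_lens_phase",
    "blazed_grating_phase",
    "cgh_phase",
    "noll_to_nm",
    "zernike_mode",
    "zernike_phase",
    "fit_zernike",
    "make_transfer_functions",
    "propagate_angular_spectrum",
    "sparrow_limit",
]


class ConfigurationError(ValueError):
    """Raised for physically invalid optical configurations."""


class SamplingError(ValueError):
    """Raised when a requested operation cannot be represented on the grid."""


# ---------------------------------------------------------------------------
# centred FFT helpers
# ---------------------------------------------------------------------------

def fft2c(a: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2-D FFT (DC of both domains at ``n // 2``)."""
    return _fft.fftshift(_fft.fft2(_fft.ifftshift(a), norm="ortho"))


def ifft2c(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return _fft.fftshift(_fft.ifft2(_fft.ifftshift(a), norm="ortho"))


def total_power(values: np.ndarray) -> float:
    """Sum of |values|^2 (conserved by the orthonormal FFT pair)."""
    return float(np.sum(np.abs(values) ** 2))


# ---------------------------------------------------------------------------
# grids and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Sampling of a square/rectangular field of view.

    Parameters
    ----------
    nx, ny:
        Pixel counts along x and y.  Must be even and at least 16 so that the
        centred-DC convention is well defined.
    pitch:
        Object-space sampling interval in nm.
    """

    nx: int = 1024
    ny: int = 1024
    pitch: float = 40.0

    def __post_init__(self) -> None:
        for n, name in ((self.nx, "nx"), (self.ny, "ny")):
            if n < 16 or n % 2:
                raise ConfigurationError(f"{name} must be even and >= 16, got {n}")
        if self.pitch <= 0:
            raise ConfigurationError(f"pitch must be positive, got {self.pitch}")

    # -- spatial coordinates (nm) -------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) - self.nx // 2) * self.pitch

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.pitch

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """``(X, Y)`` coordinate arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.x, self.y)

    # -- frequency coordinates (nm^-1) --------------------------------------------
    @property
    def dfx(self) -> float:
        return 1.0 / (self.nx * self.pitch)

    @property
    def dfy(self) -> float:
        return 1.0 / (self.ny * self.pitch)

    @property
    def fu(self) -> np.ndarray:
        return (np.arange(self.nx) - self.nx // 2) * self.dfx

    @property
    def fv(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.dfy

    def fmesh(self) -> tuple[np.ndarray, np.ndarray]:
        """``(FU, FV)`` frequency arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.fu, self.fv)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def validate_for(self, cfg: "OpticalConfig") -> None:
        """Check the Nyquist margin for the configured synthetic aperture."""
        limit = cfg.wavelength / (2.0 * (cfg.na_ill + cfg.na_det))
        if self.pitch > limit:
            raise SamplingError(
                f"pitch {self.pitch} nm violates Nyquist for the synthetic "
                f"aperture (needs <= {limit:.2f} nm)"
            )


@dataclass(frozen=True)
class OpticalConfig:
    """Source and aperture parameters of the SI-HT instrument.

    Defaults reproduce the experimental configuration this package emulates:
    a 532 nm DPSS source behind matched 0.9-NA illumination and detection
    objectives, a 250 mm tube-lens focal length for the Fresnel-lens CGH and
    a 51.2 um blazed-grating period (8 pixels of a 6.4 um-pitch SLM; the
    period itself only fixes the CGH export, not the simulated carriers,
    which are set by ``na_ill``).
    """

    wavelength: float = 532.0          # nm
    na_ill: float = 0.9
    na_det: float = 0.9
    focal_length: float = 250.0        # mm
    grating_period: float = 51.2       # um

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ConfigurationError("wavelength must be positive")
        for na, name in ((self.na_ill, "na_ill"), (self.na_det, "na_det")):
            if not 0 < na <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {na}")
        if self.focal_length <= 0:
            raise ConfigurationError("focal length must be positive")
        if self.grating_period <= 0:
            raise ConfigurationError("grating period must be positive")

    @property
    def cutoff_ill(self) -> float:
        """Illumination-pupil cut-off frequency NA_ill / lambda (nm^-1)."""
        return self.na_ill / self.wavelength

    @property
    def cutoff_det(self) -> float:
        """Detection-pupil cut-off frequency NA_det / lambda (nm^-1)."""
        return self.na_det / self.wavelength

    @property
    def na_synthetic(self) -> float:
        """Effective synthetic-aperture NA: NA_ill + NA_det."""
        return self.na_ill + self.na_det


@dataclass
class ComplexField:
    """A 2-D complex wavefront sampled on a physical grid."""

    grid: GridSpec
    values: np.ndarray
    plane: str = "object"  # object | image | pupil | frequency

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def power(self) -> float:
        return total_power(self.values)

    def copy(self) -> "ComplexField":
        return ComplexField(self.grid, self.values.copy(), self.plane)


# ---------------------------------------------------------------------------
# Zernike basis (Noll indexing, Noll normalisation: unit RMS over the disk)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def noll_to_nm(j: int) -> tuple[int, int]:
    """Map a Noll index ``j`` (1-based) to ``(n, m)``.

    ``m`` carries the sign convention used here: positive ``m`` denotes the
    cosine term, negative ``m`` the sine term (Noll parity: even ``j`` are
    cosine modes).
    """
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    jmax = 0
    while True:
        jmax += n + 1
        if j <= jmax:
            break
        n += 1
    # indices for this n run from jmax - n to jmax
    ms: list[int] = []
    for m_abs in range(n % 2, n + 1, 2):
        if m_abs == 0:
            ms.append(0)
        else:
            ms.extend([m_abs, m_abs])
    # assign within-n slots in Noll order (|m| ascending)
    slot = j - (jmax - n)
    m_abs = ms[slot]
    if m_abs == 0:
        return n, 0
    return (n, m_abs) if j % 2 == 0 else (n, -m_abs)


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)))
        out += c * rho ** (n - 2 * k)
    return out


def zernike_mode(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the Noll-normalised Zernike mode ``Z_j`` at polar points.

    The normalisation gives every mode (except piston) unit RMS over the unit
    disk, so a coefficient in waves equals the RMS wavefront error of that
    mode in waves.  Values outside the unit disk are not masked here.
    """
    n, m = noll_to_nm(j)
    r = _radial(n, abs(m), np.asarray(rho, dtype=float))
    if m == 0:
        return math.sqrt(n + 1) * r
    norm = math.sqrt(2 * (n + 1))
    if m > 0:
        return norm * r * np.cos(m * theta)
    return norm * r * np.sin(-m * theta)


@dataclass
class ZernikeCoeffs:
    """Ordered aberration coefficients in waves, keyed by Noll index."""

    coefficients: dict[int, float] = field(default_factory=dict)
    order: int | None = None  # highest mode included (q); defaults to max index

    def __post_init__(self) -> None:
        for j, z in self.coefficients.items():
            if j < 1:
                raise ValueError(f"Noll indices start at 1, got {j}")
            if not np.isfinite(z):
                raise ValueError(f"coefficient z_{j} is not finite")
        if self.order is None:
            self.order = max(self.coefficients, default=1)
        elif self.coefficients and self.order < max(self.coefficients):
            raise ValueError("order q is smaller than the highest mode present")

    @classmethod
    def from_vector(cls, modes: Iterable[int], values: Iterable[float]) -> "ZernikeCoeffs":
        return cls({int(j): float(z) for j, z in zip(modes, values)})

    def get(self, j: int) -> float:
        return self.coefficients.get(j, 0.0)

    def rms(self, exclude: tuple[int, ...] = (1,)) -> float:
        """RMS wavefront error in waves (piston excluded by default)."""
        return math.sqrt(sum(z * z for j, z in self.coefficients.items()
                             if j not in exclude))

    def __neg__(self) -> "ZernikeCoeffs":
        return ZernikeCoeffs({j: -z for j, z in self.coefficients.items()},
                             order=self.order)

    def __add__(self, other: "ZernikeCoeffs") -> "ZernikeCoeffs":
        keys = set(self.coefficients) | set(other.coefficients)
        return ZernikeCoeffs({j: self.get(j) + other.get(j) for j in keys})

    def items(self):
        return sorted(self.coefficients.items())


def zernike_phase(coeffs: ZernikeCoeffs | None,
                  grid: GridSpec,
                  pupil_radius: float,
                  space: str = "frequency") -> np.ndarray:
    """Zernike wavefront in *waves* on the grid, zero outside the disk.

    Parameters
    ----------
    coeffs:
        Coefficients in waves.  ``None`` yields a zero map.
    pupil_radius:
        Disk radius in the units of the chosen coordinate space: nm^-1 for
        ``space="frequency"`` (pupils), nm for ``space="object"`` (apertures).
    """
    if pupil_radius <= 0:
        raise ConfigurationError("pupil_radius must be positive")
    if space == "frequency":
        cx, cy = grid.fmesh()
    elif space == "object":
        cx, cy = grid.mesh()
    else:
        raise ValueError(f"unknown space {space!r}")
    out = np.zeros(grid.shape, dtype=float)
    if coeffs is None or not coeffs.coefficients:
        return out
    rho = np.hypot(cx, cy) / pupil_radius
    theta = np.arctan2(cy, cx)
    inside = rho <= 1.0
    for j, z in coeffs.items():
        if z != 0.0:
            out[inside] += z * zernike_mode(j, rho[inside], theta[inside])
    return out


def fit_zernike(phase_waves: np.ndarray,
                grid: GridSpec,
                pupil_radius: float,
                modes: Iterable[int],
                mask: np.ndarray | None = None,
                space: str = "frequency") -> ZernikeCoeffs:
    """Least-squares projection of a wavefront (waves) onto Zernike modes."""
    if space == "frequency":
        cx, cy = grid.fmesh()
    else:
        cx, cy = grid.mesh()
    rho = np.hypot(cx, cy) / pupil_radius
    theta = np.arctan2(cy, cx)
    sel = rho <= 1.0
    if mask is not None:
        sel &= mask.astype(bool)
    modes = list(modes)
    a = np.column_stack([zernike_mode(j, rho[sel], theta[sel]) for j in modes])
    sol, *_ = np.linalg.lstsq(a, phase_waves[sel], rcond=None)
    return ZernikeCoeffs.from_vector(modes, sol)


# ---------------------------------------------------------------------------
# CGH phase functions
# ---------------------------------------------------------------------------

def fresnel_lens_phase(grid: GridSpec, cfg: OpticalConfig) -> np.ndarray:
    """Quadratic Fresnel-lens phase pi/(lambda f) (x^2 + y^2), radians, unwrapped."""
    f_nm = cfg.focal_length * 1e6
    x, y = grid.mesh()
    return math.pi / (cfg.wavelength * f_nm) * (x ** 2 + y ** 2)


def blazed_grating_phase(grid: GridSpec, cfg: OpticalConfig,
                         rotation: float = 0.0) -> np.ndarray:
    """Linear blazed-grating ramp 2*pi/Lambda along ``rotation``, radians.

    The instrument steers the probe beam by rotating the grating period, so a
    single steerable ramp direction replaces the fixed diagonal form; the
    returned map is not wrapped (wrapping belongs to display/export only).
    """
    period_nm = cfg.grating_period * 1e3
    x, y = grid.mesh()
    return (2.0 * math.pi / period_nm
            * (x * math.cos(rotation) + y * math.sin(rotation)))


def cgh_phase(grid: GridSpec, cfg: OpticalConfig,
              axis: str = "x",
              rotation: float = 0.0,
              compensation: ZernikeCoeffs | None = None) -> np.ndarray:
    """Combined CGH phase: Fresnel lens + blazed ramp (+ compensation).

    ``axis="x"`` produces the ramp whose passband is displaced along u,
    ``axis="y"`` the one displaced along v; ``rotation`` adds the scan
    orientation on top of the axis convention.  When ``compensation`` is
    given (waves), its phase is added as-is (callers pass the conjugate,
    i.e. negated, estimate to cancel an aberration).
    """
    if axis == "x":
        base = 0.0
    elif axis == "y":
        base = math.pi / 2.0
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    phase = fresnel_lens_phase(grid, cfg) + blazed_grating_phase(
        grid, cfg, rotation=base + rotation)
    if compensation is not None:
        aperture = min(grid.nx, grid.ny) // 2 * grid.pitch
        phase = phase + 2.0 * math.pi * zernike_phase(
            compensation, grid, aperture, space="object")
    return phase


# ---------------------------------------------------------------------------
# transfer functions and propagation
# ---------------------------------------------------------------------------

@dataclass
class TransferFunctions:
    """Illumination/detection pupils and the aberrated coherent transfer function."""

    a_i: np.ndarray        # illumination pupil (binary, frequency grid)
    a_d: np.ndarray        # detection pupil (binary)
    ctf: np.ndarray        # A_d * exp(j 2 pi W) with W the pupil wavefront in waves
    grid: GridSpec
    cfg: OpticalConfig


def make_transfer_functions(cfg: OpticalConfig, grid: GridSpec,
                            aberration: ZernikeCoeffs | None = None) -> TransferFunctions:
    """Binary pupils of radius NA/lambda and the aberrated CTF.

    The aberration is a Zernike wavefront (waves) over the detection pupil;
    the CTF carries ``exp(j 2 pi W)`` inside that pupil and is zero outside.
    """
    fu, fv = grid.fmesh()
    fmax = min(abs(grid.fu).max(), abs(grid.fv).max())
    for cut, name in ((cfg.cutoff_ill, "illumination"), (cfg.cutoff_det, "detection")):
        if cut > fmax:
            raise SamplingError(
                f"{name} pupil radius {cut:.3e} nm^-1 exceeds the frequency grid "
                f"(max {fmax:.3e} nm^-1)")
    rho2 = fu ** 2 + fv ** 2
    a_i = (rho2 <= cfg.cutoff_ill ** 2).astype(float)
    a_d = (rho2 <= cfg.cutoff_det ** 2).astype(float)
    w = zernike_phase(aberration, grid, cfg.cutoff_det, space="frequency")
    ctf = a_d * np.exp(2j * math.pi * w)
    return TransferFunctions(a_i=a_i, a_d=a_d, ctf=ctf, grid=grid, cfg=cfg)


def propagate_angular_spectrum(field: ComplexField, distance: float,
                               cfg: OpticalConfig,
                               medium_index: float = 1.0,
                               alias_threshold: float = 1e-3) -> ComplexField:
    """Exact scalar angular-spectrum propagation by ``distance`` (nm).

    Evanescent components (|f| > n/lambda) are set to zero, which makes the
    kernel unitary on the propagating subspace.  A warning is emitted when a
    non-negligible fraction of the field energy sits at the grid edge, where
    the periodic FFT boundary makes propagation alias.
    """
    if distance == 0.0:
        return field.copy()
    grid = field.grid
    spec = fft2c(field.values)
    # aliasing guard: energy in the outer 2 % frequency annulus
    fu, fv = grid.fmesh()
    fmax = min(abs(grid.fu).max(), abs(grid.fv).max())
    edge = (np.abs(fu) > 0.98 * fmax) | (np.abs(fv) > 0.98 * fmax)
    p_tot = total_power(spec)
    if p_tot > 0 and total_power(spec[edge]) / p_tot > alias_threshold:
        warnings.warn("field energy at the grid edge: propagation may alias",
                      RuntimeWarning, stacklevel=2)
    k2 = (medium_index / cfg.wavelength) ** 2 - (fu ** 2 + fv ** 2)
    propagating = k2 > 0.0
    kz = np.sqrt(np.where(propagating, k2, 0.0))
    kernel = np.where(propagating,
                      np.exp(2j * math.pi * distance * kz), 0.0)
    out = ifft2c(spec * kernel)
    return ComplexField(grid, out, plane=field.plane)


def sparrow_limit(wavelength: float, na_effective: float) -> float:
    """Coherent two-point Sparrow resolution limit 0.77 * lambda / NA (nm)."""
    if na_effective <= 0:
        raise ConfigurationError("na_effective must be positive")
    return 0.77 * wavelength / na_effective
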