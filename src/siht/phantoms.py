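"""Ground-truth test objects: Siemens-star resolution target and 3-D cell phantom.

These generators stand in for the physical samples used to validate the
instrument: a chrome-on-glass Siemens star with 150 nm minimal line width
(300 nm per spoke pair) and a yeast-like cell whose refractive index spans
1.34-1.42.  All generators are deterministic functions of their spec and
grid; binary masks are rendered at 2x supersampling and box-downsampled to
limit pixelisation artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import ComplexField, GridSpec, SamplingError

__all__ = [
    "SiemensStarSpec",
    "Organelle",
    "CellPhantomSpec",
    "RIVolume",
    "siemens_star_mask",
    "make_siemens_star",
    "make_cell_phantom",
    "default_cell_phantom",
    "project_thin_phase",
]


@dataclass(frozen=True)
class SiemensStarSpec:
    """Geometry of a binary Siemens star.

    ``n_spokes`` counts spoke *pairs* (one opaque + one clear line per pair),
    so the line width at radius r is pi*r/n_spokes and the pair period is
    2*pi*r/n_spokes.  ``r_min`` is derived so the line width at the inner
    radius equals ``min_linewidth``.
    """

    n_spokes: int = 36
    min_linewidth: float = 150.0   # nm, line width at r_min
    r_max: float = 12000.0         # nm
    phase_height: float = math.pi  # radians; pi makes the +/-1 "chrome" target

    def __post_init__(self) -> None:
        if self.n_spokes < 2:
            raise ValueError("need at least 2 spoke pairs")
        if self.min_linewidth <= 0 or self.r_max <= 0:
            raise ValueError("lengths must be positive")
        if self.r_min >= self.r_max:
            raise ValueError("r_min derived from min_linewidth exceeds r_max")

    @property
    def r_min(self) -> float:
        """Inner radius (nm) where the line width equals ``min_linewidth``."""
        return self.min_linewidth * self.n_spokes / math.pi

    def linewidth_at(self, radius: float) -> float:
        return math.pi * radius / self.n_spokes

    def radius_for_linewidth(self, width: float) -> float:
        return width * self.n_spokes / math.pi


def siemens_star_mask(spec: SiemensStarSpec, grid: GridSpec,
                      supersample: int = 2) -> np.ndarray:
    """Anti-aliased spoke mask in [0, 1] (1 = phase-stepped spoke)."""
    if grid.pitch > spec.min_linewidth / 3.0:
        raise SamplingError(
            f"pitch {grid.pitch} nm cannot resolve {spec.min_linewidth} nm lines "
            f"(needs <= {spec.min_linewidth / 3.0:.1f} nm)")
    s = int(supersample)
    pitch = grid.pitch / s
    x = (np.arange(grid.nx * s) - (grid.nx * s) // 2 + 0.5 * ((s + 1) % 2)) * pitch
    y = (np.arange(grid.ny * s) - (grid.ny * s) // 2 + 0.5 * ((s + 1) % 2)) * pitch
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)
    theta = np.mod(np.arctan2(yy, xx), 2.0 * math.pi)
    period = 2.0 * math.pi / spec.n_spokes
    spoke = np.mod(theta, period) < 0.5 * period
    mask = spoke & (r >= spec.r_min) & (r <= spec.r_max)
    m = mask.astype(float).reshape(grid.ny, s, grid.nx, s).mean(axis=(1, 3))
    return m


def make_siemens_star(spec: SiemensStarSpec, grid: GridSpec,
                      supersample: int = 2) -> ComplexField:
    """Thin-sample transmission exp(j * phase_height * mask) of the star."""
    mask = siemens_star_mask(spec, grid, supersample=supersample)
    return ComplexField(grid, np.exp(1j * spec.phase_height * mask), plane="object")


# ---------------------------------------------------------------------------
# 3-D cell phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Organelle:
    """One compartment: an ellipsoid or an ellipsoidal shell.

    ``center`` and ``semi_axes`` are (x, y, z) in nm; for shells,
    ``thickness`` is the radial wall thickness in nm.
    """

    shape: str                      # "ellipsoid" | "shell"
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    ri: float
    thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "shell"):
            raise ValueError(f"unknown organelle shape {self.shape!r}")
        if self.shape == "shell" and self.thickness <= 0:
            raise ValueError("shell organelles need a positive thickness")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class CellPhantomSpec:
    """Medium plus an ordered organelle list (later entries overwrite)."""

    medium_ri: float = 1.34
    organelles: tuple[Organelle, ...] = ()
    bounds: tuple[float, float, float] = (10240.0, 10240.0, 10240.0)  # nm
    ri_range: tuple[float, float] = (1.34, 1.42)

    def __post_init__(self) -> None:
        lo, hi = self.ri_range
        for org in self.organelles:
            if not lo <= org.ri <= hi:
                raise ValueError(
                    f"organelle RI {org.ri} outside declared range [{lo}, {hi}]")
            for c, a, b in zip(org.center, org.semi_axes, self.bounds):
                if abs(c) + a > b / 2.0:
                    raise ValueError("organelle extends outside the bounding volume")


def default_cell_phantom(bounds: tuple[float, float, float] = (10240.0, 10240.0, 10240.0)
                         ) -> CellPhantomSpec:
    """Yeast-like phantom spanning RI 1.34-1.42.

    A 6 um ellipsoidal cell with a 150 nm wall (RI 1.40), cytoplasm 1.36,
    a 2 um nucleus (1.39) and six ~600 nm mitochondria (1.42) in 1.34 medium.
    Positions are fixed so the phantom is fully deterministic.
    """
    wall = Organelle("shell", (0, 0, 0), (3000.0, 2600.0, 2300.0), 1.40,
                     thickness=150.0)
    cyto = Organelle("ellipsoid", (0, 0, 0), (2850.0, 2450.0, 2150.0), 1.36)
    nucleus = Organelle("ellipsoid", (900.0, -500.0, 300.0),
                        (1050.0, 900.0, 800.0), 1.39)
    mito_sites = [(-1500.0, 800.0, -600.0), (-800.0, -1200.0, 500.0),
                  (300.0, 1400.0, -900.0), (-1800.0, -300.0, 800.0),
                  (1300.0, 900.0, 900.0), (-400.0, 300.0, -1400.0)]
    mitos = tuple(Organelle("ellipsoid", c, (420.0, 300.0, 280.0), 1.42)
                  for c in mito_sites)
    return CellPhantomSpec(medium_ri=1.34,
                           organelles=(wall, cyto, nucleus) + mitos,
                           bounds=bounds)


@dataclass
class RIVolume:
    """3-D refractive-index distribution with per-axis voxel pitch (nm)."""

    values: np.ndarray                 # shape (nz, ny, nx)
    pitch: tuple[float, float, float]  # (dx, dy, dz) nm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("RIVolume expects a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RI volume contains non-finite values")
        if self.values.min() < 1.0:
            raise ValueError("refractive index below 1 is unphysical")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Centred (z, y, x) coordinate vectors in nm."""
        nz, ny, nx = self.values.shape
        dx, dy, dz = self.pitch
        return ((np.arange(nz) - nz // 2) * dz,
                (np.arange(ny) - ny // 2) * dy,
                (np.arange(nx) - nx // 2) * dx)


def _ellipsoid_mask(zz, yy, xx, center, semi, shrink=0.0):
    ax, ay, az = (max(s - shrink, 1e-9) for s in semi)
    return (((xx - center[0]) / ax) ** 2
            + ((yy - center[1]) / ay) ** 2
            + ((zz - center[2]) / az) ** 2) <= 1.0


def make_cell_phantom(spec: CellPhantomSpec,
                      shape: tuple[int, int, int],
                      pitch: tuple[float, float, float]) -> RIVolume:
    """Voxelise the phantom; organelles are rasterised in list order
    (last-wins layering, so nested compartments simply overwrite)."""
    nz, ny, nx = shape
    dx, dy, dz = pitch
    z = (np.arange(nz) - nz // 2) * dz
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    vol = np.full(shape, spec.medium_ri, dtype=float)
    for org in spec.organelles:
        outer = _ellipsoid_mask(zz, yy, xx, org.center, org.semi_axes)
        if org.shape == "shell":
            inner = _ellipsoid_mask(zz, yy, xx, org.center, org.semi_axes,
                                    shrink=org.thickness)
            vol[outer & ~inner] = org.ri
        else:
            vol[outer] = org.ri
    return RIVolume(vol, pitch)


def project_thin_phase(vol: RIVolume, wavelength: float,
                       medium_ri: float | None = None) -> np.ndarray:
    """Thin-object reduction: phase = 2*pi/lambda * integral (n - n_medium) dz.

    Valid for weak-scattering phantoms; used to drive the 2-D imaging chain
    with a 3-D phantom.  ``medium_ri`` defaults to the corner voxel value.
    """
    if medium_ri is None:
        medium_ri = float(vol.values[0, 0, 0])
    dz = vol.pitch[2]
    return (2.0 * math.pi / wavelength
            * np.sum(vol.values - medium_ri, axis=0) * dz)
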