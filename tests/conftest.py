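"""Shared fixtures: optical configuration, grids, phantoms and simulated
data sets reused across the suite (session-scoped where generation is
expensive)."""

from __future__ import annotations

import numpy as np
import pytest

from siht.forward import build_scan_schedule
from siht.optics import GridSpec, OpticalConfig, ZernikeCoeffs
from siht.phantoms import SiemensStarSpec, make_siemens_star
from siht.pipeline import acquire_passbands


@pytest.fixture(scope="session")
def cfg() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def grid256() -> GridSpec:
    return GridSpec(256, 256, 40.0)


@pytest.fixture(scope="session")
def grid512() -> GridSpec:
    return GridSpec(512, 512, 40.0)


@pytest.fixture(scope="session")
def grid1024() -> GridSpec:
    return GridSpec(1024, 1024, 40.0)


@pytest.fixture(scope="session")
def star_spec_small() -> SiemensStarSpec:
    # fits a 256 x 40 nm field
    return SiemensStarSpec(n_spokes=36, min_linewidth=150.0, r_max=4500.0)


@pytest.fixture(scope="session")
def star256(star_spec_small, grid256):
    return make_siemens_star(star_spec_small, grid256)


@pytest.fixture(scope="session")
def star_spec_512() -> SiemensStarSpec:
    return SiemensStarSpec(n_spokes=36, min_linewidth=150.0, r_max=9000.0)


@pytest.fixture(scope="session")
def star512(star_spec_512, grid512):
    return make_siemens_star(star_spec_512, grid512)


@pytest.fixture(scope="session")
def star_spec_full() -> SiemensStarSpec:
    return SiemensStarSpec()  # 150 nm lines, r_max 12 um, 36 pairs


@pytest.fixture(scope="session")
def star1024(star_spec_full, grid1024):
    return make_siemens_star(star_spec_full, grid1024)


def random_aberration(seed: int, rms: float = 0.5,
                      modes=range(4, 12)) -> ZernikeCoeffs:
    """Random Zernike draw over the given modes, scaled to an exact RMS."""
    rng = np.random.default_rng(seed)
    modes = list(modes)
    v = rng.normal(size=len(modes))
    v *= rms / np.linalg.norm(v)
    return ZernikeCoeffs.from_vector(modes, v)


def acquire_list(obj, schedule, cfg, **kw):
    """Materialised passband list for one simulated scan."""
    return list(acquire_passbands(obj, schedule, cfg, **kw))


@pytest.fixture(scope="session")
def schedule256_m4(cfg, grid256):
    return build_scan_schedule(cfg, grid256, 4)


# ---------------------------------------------------------------------------
# shared tomography runs (expensive; reused by unit and acceptance tests)
# ---------------------------------------------------------------------------

TOMO_N0 = 1.34


def _sphere_volume(n=128, pitch=80.0, radius=1000.0, dn=0.02):
    from siht.phantoms import RIVolume
    z = (np.arange(n) - n // 2) * pitch
    zz, yy, xx = np.meshgrid(z, z, z, indexing="ij")
    ri = np.where(zz ** 2 + yy ** 2 + xx ** 2 <= radius ** 2,
                  TOMO_N0 + dn, TOMO_N0)
    return RIVolume(ri, (pitch,) * 3)


def _tomo_chain(vol, cfg, m_orientations=16, iterations=50, callback=None):
    from siht.tomo import (AngleField, ewald_map, invert_to_ri,
                           multislice_field, rytov_phase, tomo_carriers)
    n = vol.values.shape[2]
    grid = GridSpec(n, n, vol.pitch[0])
    fields = []
    for c in tomo_carriers(cfg, grid, m_orientations):
        us, ub = multislice_field(vol, c, cfg, n0=TOMO_N0)
        fields.append(AngleField(rytov_phase(us, ub), c))
    fvol = ewald_map(fields, grid, cfg, vol.values.shape, vol.pitch[2],
                     n0=TOMO_N0)
    ri = invert_to_ri(fvol, iterations=iterations, callback=callback)
    return fvol, ri


@pytest.fixture(scope="session")
def sphere_reconstruction(cfg):
    """Weak-sphere phantom (dn = 0.02, R = 1 um) through the full
    forward-simulate-then-invert chain at 128^3 voxels, 16 orientations,
    with axial-profile snapshots along the constraint iterations."""
    vol = _sphere_volume()
    snapshots = {}

    def cb(it, ri):
        if it in (0, 10, 30, 50):
            snapshots[it] = ri[:, 64, 64].copy()

    fvol, ri = _tomo_chain(vol, cfg, callback=cb)
    return vol, fvol, ri, snapshots


@pytest.fixture(scope="session")
def cell_reconstruction(cfg):
    """Default cell phantom through the same chain at 128^3 voxels."""
    from siht.phantoms import default_cell_phantom, make_cell_phantom
    vol = make_cell_phantom(default_cell_phantom(), (128, 128, 128),
                            (80.0,) * 3)
    fvol, ri = _tomo_chain(vol, cfg)
    return vol, ri
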