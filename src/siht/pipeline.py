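"""Pipeline orchestration, configuration, artifact I/O and logging.

The four reconstruction stages map onto the instrument's calibrated
measurement procedure: (1) ``simulate`` records the scheduled SI hologram
set, (2) ``separate`` demodulates and unmixes the passbands, (3)
``calibrate`` runs the adaptive-wavefront-correction loop (re-acquiring
with updated CGHs, which in the twin means re-simulating), (4)
``synthesize`` records with the compensated CGHs and merges the synthetic
aperture; ``tomo`` and ``report`` add the 3-D refractive-index inversion
and the resolution/summary tables.

Every stage writes its artifact plus a JSON manifest carrying the config
hash, the seed and content hashes of its inputs, so an interrupted run
resumes from the last completed stage and identical configs reproduce
bit-identical deterministic artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import h5py
import tifffile
import yaml

from . import awc as _awc
from . import tomo as _tomo
from .forward import (DEFAULT_PHASE_SHIFTS, Hologram, ScanSchedule, SimTruth,
                      build_scan_schedule, record_offaxis_hologram,
                      simulate_si_exposure)
from .holography import PassbandSet, demodulate_offaxis, separate_passbands
from .optics import (ComplexField, GridSpec, OpticalConfig, ZernikeCoeffs,
                     fft2c)
from .phantoms import (CellPhantomSpec, SiemensStarSpec, default_cell_phantom,
                       make_cell_phantom, make_siemens_star,
                       project_thin_phase)
from .synthesis import measure_resolution, reconstruct_image, synthesize

logger = logging.getLogger("siht")

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "STAGES",
    "run_pipeline",
    "acquire_passbands",
    "make_acquirer",
    "save_complex_field",
    "load_complex_field",
    "save_phase_tiff",
]

STAGES = ("simulate", "separate", "calibrate", "synthesize", "tomo", "report")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _strict_kwargs(cls, data: dict, context: str) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")
    return data


@dataclass(frozen=True)
class AWCSettings:
    q: int = 15                 # highest fitted Noll mode
    max_iter: int = 10
    tol: float = 0.01           # waves RMS

    def modes(self) -> tuple[int, ...]:
        return tuple(range(4, self.q + 1))


@dataclass(frozen=True)
class TomoSettings:
    orientations: int = 16
    shape: tuple[int, int, int] = (128, 128, 128)
    pitch: float = 80.0         # nm, isotropic voxel
    n0: float = 1.34
    iterations: int = 50


@dataclass(frozen=True)
class PipelineConfig:
    """Full run description; defaults reproduce the flagship configuration
    (532 nm, NA 0.9/0.9, 60 orientations, phase shifts 0 and 120 degrees)."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    orientations: int = 60
    phase_shifts_deg: tuple[float, ...] = (0.0, 120.0)
    photons: float | None = 1.0e4
    seed: int = 0
    phantom: str = "siemens"            # "siemens" | "cell"
    star: SiemensStarSpec = field(default_factory=SiemensStarSpec)
    aberration: dict[int, float] = field(default_factory=dict)  # Noll -> waves
    awc: AWCSettings = field(default_factory=AWCSettings)
    tomo: TomoSettings = field(default_factory=TomoSettings)

    def __post_init__(self) -> None:
        if self.phantom not in ("siemens", "cell"):
            raise ConfigError(f"unknown phantom {self.phantom!r}")
        if self.orientations < 1:
            raise ConfigError("need at least one orientation")
        self.grid.validate_for(self.optics)

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aberration"] = {int(k): float(v) for k, v in self.aberration.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(_strict_kwargs(cls, data, "pipeline config"))
        if "optics" in data:
            data["optics"] = OpticalConfig(
                **_strict_kwargs(OpticalConfig, data["optics"], "optics"))
        if "grid" in data:
            data["grid"] = GridSpec(
                **_strict_kwargs(GridSpec, data["grid"], "grid"))
        if "star" in data:
            data["star"] = SiemensStarSpec(
                **_strict_kwargs(SiemensStarSpec, data["star"], "star"))
        if "awc" in data:
            data["awc"] = AWCSettings(
                **_strict_kwargs(AWCSettings, data["awc"], "awc"))
        if "tomo" in data:
            t = dict(_strict_kwargs(TomoSettings, data["tomo"], "tomo"))
            if "shape" in t:
                t["shape"] = tuple(t["shape"])
            data["tomo"] = TomoSettings(**t)
        if "phase_shifts_deg" in data:
            data["phase_shifts_deg"] = tuple(data["phase_shifts_deg"])
        if "aberration" in data:
            data["aberration"] = {int(k): float(v)
                                  for k, v in data["aberration"].items()}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- derived objects -------------------------------------------------------
    def schedule(self) -> ScanSchedule:
        shifts = tuple(math.radians(p) for p in self.phase_shifts_deg)
        return build_scan_schedule(self.optics, self.grid, self.orientations,
                                   phase_shifts=shifts)

    def aberration_coeffs(self) -> ZernikeCoeffs | None:
        if not self.aberration:
            return None
        return ZernikeCoeffs(dict(self.aberration))

    def object_field(self) -> ComplexField:
        if self.phantom == "siemens":
            return make_siemens_star(self.star, self.grid)
        spec = default_cell_phantom()
        shape = self.tomo.shape
        vol = make_cell_phantom(spec, shape, (self.tomo.pitch,) * 3)
        phase = project_thin_phase(vol, self.optics.wavelength,
                                   medium_ri=spec.medium_ri)
        # embed the projected phase at the centre of the imaging grid
        full = np.zeros(self.grid.shape)
        oy = (self.grid.ny - phase.shape[0]) // 2
        ox = (self.grid.nx - phase.shape[1]) // 2
        full[oy:oy + phase.shape[0], ox:ox + phase.shape[1]] = phase
        return ComplexField(self.grid, np.exp(1j * full), plane="object")


# ---------------------------------------------------------------------------
# acquisition helpers (simulation stands in for the instrument)
# ---------------------------------------------------------------------------

def acquire_passbands(obj: ComplexField, schedule: ScanSchedule,
                      cfg: OpticalConfig,
                      aberration: ZernikeCoeffs | None = None,
                      compensation: ZernikeCoeffs | None = None,
                      photons: float | None = None,
                      seed: int | None = 0) -> Iterator[PassbandSet]:
    """Simulate, record, demodulate and separate one full scan, lazily."""
    rng = np.random.default_rng(seed) if photons is not None else None
    for m in range(schedule.pair_count):
        fields = []
        for k in range(len(schedule.phase_shifts)):
            fld = simulate_si_exposure(obj, schedule, m, k, cfg,
                                       aberration=aberration,
                                       compensation=compensation)
            holo = record_offaxis_hologram(fld, cfg, photons=photons, rng=rng,
                                           orientation=m, shift_index=k)
            fields.append(demodulate_offaxis(holo, cfg))
        yield separate_passbands(fields, schedule, m)


def make_acquirer(obj: ComplexField, schedule: ScanSchedule,
                  cfg: OpticalConfig,
                  aberration: ZernikeCoeffs | None,
                  photons: float | None, seed: int | None):
    """Closure for :func:`siht.awc.awc_loop`: compensation -> passband list."""
    call_count = {"n": 0}

    def acquire(compensation: ZernikeCoeffs | None) -> list[PassbandSet]:
        call_count["n"] += 1
        s = None if seed is None else seed + 1000 * call_count["n"]
        return list(acquire_passbands(obj, schedule, cfg,
                                      aberration=aberration,
                                      compensation=compensation,
                                      photons=photons, seed=s))

    return acquire


# ---------------------------------------------------------------------------
# artifact I/O
# ---------------------------------------------------------------------------

def save_complex_field(group: h5py.Group, name: str, values: np.ndarray,
                       **attrs) -> None:
    """Store a complex array as paired real/imag datasets (lossless)."""
    g = group.create_group(name)
    g.create_dataset("real", data=np.ascontiguousarray(values.real))
    g.create_dataset("imag", data=np.ascontiguousarray(values.imag))
    for k, v in attrs.items():
        g.attrs[k] = v


def load_complex_field(group: h5py.Group, name: str) -> np.ndarray:
    g = group[name]
    return np.asarray(g["real"]) + 1j * np.asarray(g["imag"])


def save_phase_tiff(path: str | Path, phase: np.ndarray) -> None:
    """Export a phase map wrapped to (-pi, pi], 32-bit float TIFF."""
    wrapped = np.angle(np.exp(1j * phase)).astype(np.float32)
    tifffile.imwrite(str(path), wrapped)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(out_dir: Path, stage: str, cfg: PipelineConfig,
                    inputs: Sequence[Path], outputs: Sequence[Path],
                    wall_time: float) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        "wall_time_s": round(wall_time, 3),
    }
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_done(out_dir: Path, stage: str, cfg: PipelineConfig) -> bool:
    path = out_dir / f"manifest_{stage}.json"
    if not path.exists():
        return False
    try:
        with open(path) as fh:
            manifest = json.load(fh)
    except (OSError, json.JSONDecodeError):
        return False
    return manifest.get("config_hash") == cfg.config_hash()


class StageDependencyError(RuntimeError):
    """A stage was requested before its upstream artifact exists."""


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    obj = cfg.object_field()
    schedule = cfg.schedule()
    holo_tif = out / "holograms.tif"
    meta_h5 = out / "holograms.h5"
    rng = np.random.default_rng(cfg.seed) if cfg.photons is not None else None
    with tifffile.TiffWriter(str(holo_tif)) as tw, h5py.File(meta_h5, "w") as hf:
        hf.attrs["orientations"] = cfg.orientations
        hf.attrs["phase_shifts_deg"] = list(cfg.phase_shifts_deg)
        hf.attrs["photons"] = -1.0 if cfg.photons is None else cfg.photons
        hf.attrs["seed"] = -1 if cfg.seed is None else cfg.seed
        hf.attrs["carrier_freq"] = schedule.carrier_freq
        hf.create_dataset("carriers_px", data=np.asarray(schedule.carriers_px))
        refs = []
        for m in range(schedule.pair_count):
            for k in range(len(schedule.phase_shifts)):
                fld = simulate_si_exposure(obj, schedule, m, k, cfg.optics,
                                           aberration=cfg.aberration_coeffs())
                holo = record_offaxis_hologram(fld, cfg.optics,
                                               photons=cfg.photons, rng=rng,
                                               orientation=m, shift_index=k)
                tw.write(holo.values.astype(np.float32), contiguous=True)
                refs.append((*holo.ref_carrier_px, holo.ref_amplitude))
        hf.create_dataset("reference", data=np.asarray(refs))
    logger.info("simulate: wrote %d holograms", schedule.exposure_count)
    return [holo_tif, meta_h5]


def _load_holograms(cfg: PipelineConfig, out: Path) -> Iterator[list[Hologram]]:
    schedule = cfg.schedule()
    meta = h5py.File(out / "holograms.h5", "r")
    refs = np.asarray(meta["reference"])
    meta.close()
    n_shift = len(schedule.phase_shifts)
    with tifffile.TiffFile(str(out / "holograms.tif")) as tf:
        idx = 0
        for m in range(schedule.pair_count):
            group = []
            for k in range(n_shift):
                page = tf.pages[idx]
                kx, ky, amp = refs[idx]
                group.append(Hologram(values=np.asarray(page.asarray(), dtype=float),
                                      grid=cfg.grid,
                                      ref_carrier_px=(int(kx), int(ky)),
                                      ref_amplitude=float(amp),
                                      orientation=m, shift_index=k))
                idx += 1
            yield group


def _stage_separate(cfg: PipelineConfig, out: Path) -> list[Path]:
    if not (out / "holograms.tif").exists():
        raise StageDependencyError("separate requires the simulate stage")
    schedule = cfg.schedule()
    pb_h5 = out / "passbands.h5"
    r_px = cfg.optics.cutoff_det / cfg.grid.dfx
    half = int(math.ceil(r_px)) + 2
    with h5py.File(pb_h5, "w") as hf:
        hf.attrs["crop_half"] = half
        hf.attrs["orientations"] = cfg.orientations
        for m, holos in enumerate(_load_holograms(cfg, out)):
            fields = [demodulate_offaxis(h, cfg.optics) for h in holos]
            pb = separate_passbands(fields, schedule, m)
            g = hf.create_group(f"orientation_{m:03d}")
            g.attrs["cond"] = pb.cond
            g.attrs["carriers_px"] = np.asarray(pb.carriers_px)
            cy, cx = cfg.grid.ny // 2, cfg.grid.nx // 2
            for name, w in (("d1", 0), ("d2", 1)):
                rec = pb.recorded(w)  # support is the pupil disk at DC
                crop = rec[cy - half:cy + half, cx - half:cx + half]
                save_complex_field(g, name, crop.astype(np.complex64))
    logger.info("separate: %d passbands", 2 * schedule.pair_count)
    return [pb_h5]


def load_passbands(cfg: PipelineConfig, out: Path) -> list[PassbandSet]:
    """Rehydrate the separated passbands written by the separate stage."""
    schedule = cfg.schedule()
    pbs = []
    with h5py.File(out / "passbands.h5", "r") as hf:
        half = int(hf.attrs["crop_half"])
        cy, cx = cfg.grid.ny // 2, cfg.grid.nx // 2
        for m in range(schedule.pair_count):
            g = hf[f"orientation_{m:03d}"]
            full = []
            for name, (kx, ky) in zip(("d1", "d2"), schedule.carriers_px[m]):
                rec = np.zeros(cfg.grid.shape, dtype=complex)
                rec[cy - half:cy + half, cx - half:cx + half] = \
                    load_complex_field(g, name)
                full.append(np.roll(rec, shift=(ky, kx), axis=(0, 1)))
            pbs.append(PassbandSet(d1=full[0], d2=full[1],
                                   carriers_px=schedule.carriers_px[m],
                                   grid=cfg.grid, orientation=m,
                                   cond=float(g.attrs["cond"])))
    return pbs


def _stage_calibrate(cfg: PipelineConfig, out: Path) -> list[Path]:
    obj = cfg.object_field()
    schedule = cfg.schedule()
    acquire = make_acquirer(obj, schedule, cfg.optics, cfg.aberration_coeffs(),
                            cfg.photons, cfg.seed)
    t0 = time.perf_counter()
    est, comp = _awc.awc_loop(acquire, cfg.optics, cfg.grid,
                              modes=cfg.awc.modes(),
                              max_iter=cfg.awc.max_iter, tol=cfg.awc.tol)
    for i, r in enumerate(est.history, 1):
        logger.info("calibrate: iteration %d residual %.4g waves", i, r)
    logger.info("calibrate: converged=%s in %d iterations (%.1f s)",
                est.converged, est.iterations, time.perf_counter() - t0)
    cal_h5 = out / "calibration.h5"
    with h5py.File(cal_h5, "w") as hf:
        modes = [j for j, _ in est.coeffs.items()]
        hf.create_dataset("modes", data=np.asarray(modes))
        hf.create_dataset("coefficients",
                          data=np.asarray([est.coeffs.get(j) for j in modes]))
        hf.create_dataset("residual_history", data=np.asarray(est.history))
        hf.attrs["residual_rms"] = est.residual_rms
        hf.attrs["update_rms"] = est.update_rms
        hf.attrs["iterations"] = est.iterations
        hf.attrs["converged"] = est.converged
    table = out / "coefficients.txt"
    with open(table, "w") as fh:
        fh.write("# Noll  estimate_waves\n")
        for j, z in est.coeffs.items():
            fh.write(f"{j:4d}  {z:+.6e}\n")
    return [cal_h5, table]


def load_calibration(out: Path) -> ZernikeCoeffs:
    with h5py.File(out / "calibration.h5", "r") as hf:
        modes = np.asarray(hf["modes"])
        vals = np.asarray(hf["coefficients"])
    return ZernikeCoeffs.from_vector(modes.tolist(), vals.tolist())


def _stage_synthesize(cfg: PipelineConfig, out: Path) -> list[Path]:
    obj = cfg.object_field()
    schedule = cfg.schedule()
    comp = None
    if (out / "calibration.h5").exists():
        comp = -load_calibration(out)
    elif cfg.aberration:
        logger.warning("synthesize: aberrations injected but no calibration "
                       "artifact found; synthesizing uncompensated data")
    pbs = acquire_passbands(obj, schedule, cfg.optics,
                            aberration=cfg.aberration_coeffs(),
                            compensation=comp,
                            photons=cfg.photons,
                            seed=None if cfg.seed is None else cfg.seed + 77)
    spec = synthesize(pbs, cfg.optics)
    img = reconstruct_image(spec)
    syn_h5 = out / "synthesis.h5"
    with h5py.File(syn_h5, "w") as hf:
        save_complex_field(hf, "spectrum", spec.values.astype(np.complex64),
                           passband_count=spec.passband_count)
        hf.create_dataset("coverage", data=spec.coverage)
    amp_tif = out / "amplitude.tif"
    ph_tif = out / "phase.tif"
    tifffile.imwrite(str(amp_tif), np.abs(img.values).astype(np.float32))
    save_phase_tiff(ph_tif, np.angle(img.values))
    logger.info("synthesize: %d passbands, support radius %.1f px",
                spec.passband_count, spec.support_radius_px())
    return [syn_h5, amp_tif, ph_tif]


def _stage_tomo(cfg: PipelineConfig, out: Path) -> list[Path]:
    spec = default_cell_phantom()
    t = cfg.tomo
    vol = make_cell_phantom(spec, t.shape, (t.pitch,) * 3)
    grid2d = GridSpec(t.shape[2], t.shape[1], t.pitch)
    comp = -load_calibration(out) if (out / "calibration.h5").exists() else None
    net = None
    if cfg.aberration:
        net = cfg.aberration_coeffs()
        if comp is not None:
            net = net + comp
    from .optics import zernike_phase
    w_map = zernike_phase(net, grid2d, cfg.optics.cutoff_det) if net else None
    angle_fields = []
    t0 = time.perf_counter()
    for carrier in _tomo.tomo_carriers(cfg.optics, grid2d, t.orientations):
        us, ub = _tomo.multislice_field(vol, carrier, cfg.optics, n0=t.n0)
        if w_map is not None:
            spec2 = fft2c(us) * np.exp(2j * math.pi * w_map)
            from .optics import ifft2c
            us = ifft2c(spec2)
        angle_fields.append(_tomo.AngleField(_tomo.rytov_phase(us, ub), carrier))
    fvol = _tomo.ewald_map(angle_fields, grid2d, cfg.optics, t.shape, t.pitch,
                           n0=t.n0)
    ri = _tomo.invert_to_ri(fvol, iterations=t.iterations)
    logger.info("tomo: %d caps, filled fraction %.4f (%.1f s)",
                len(angle_fields), fvol.filled_fraction(),
                time.perf_counter() - t0)
    ri_tif = out / "ri.tif"
    ri_h5 = out / "ri.h5"
    tifffile.imwrite(str(ri_tif), ri.values.astype(np.float32))
    with h5py.File(ri_h5, "w") as hf:
        hf.create_dataset("ri", data=ri.values)
        hf.attrs["pitch_nm"] = ri.pitch
        hf.attrs["n0"] = t.n0
    return [ri_tif, ri_h5]


def _stage_report(cfg: PipelineConfig, out: Path) -> list[Path]:
    if not (out / "synthesis.h5").exists():
        raise StageDependencyError("report requires the synthesize stage")
    with h5py.File(out / "synthesis.h5", "r") as hf:
        values = load_complex_field(hf, "spectrum")
        coverage = np.asarray(hf["coverage"])
        count = int(hf["spectrum"].attrs["passband_count"])
    from .synthesis import SynthesizedSpectrum
    spec = SynthesizedSpectrum(values=values, coverage=coverage,
                               grid=cfg.grid, passband_count=count)
    img = reconstruct_image(spec)
    rows = []
    if cfg.phantom == "siemens":
        rep = measure_resolution(img, cfg.star)
        rows = rep.as_rows()
        logger.info("report: smallest resolved width %s nm",
                    rep.smallest_resolved)
    csv = out / "resolution.csv"
    with open(csv, "w") as fh:
        fh.write("linewidth_nm,modulation,resolved\n")
        for w, m, ok in rows:
            fh.write(f"{w:.1f},{m:.5f},{int(ok)}\n")
    return [csv]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "separate": _stage_separate,
    "calibrate": _stage_calibrate,
    "synthesize": _stage_synthesize,
    "tomo": _stage_tomo,
    "report": _stage_report,
}

_STAGE_DEPS = {
    "simulate": (),
    "separate": ("simulate",),
    "calibrate": (),
    "synthesize": (),
    "tomo": (),
    "report": ("synthesize",),
}


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str] = STAGES,
                 out_dir: str | Path = "run", resume: bool = True) -> Path:
    """Execute the requested stages in canonical order; returns the run dir.

    Completed stages (matching manifest and config hash) are skipped when
    ``resume`` is true, so an aborted run picks up where it stopped.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        for dep in _STAGE_DEPS[stage]:
            if dep not in ordered and not _stage_done(out, dep, cfg):
                raise StageDependencyError(
                    f"stage {stage!r} requires {dep!r} to have run")
        if resume and _stage_done(out, stage, cfg):
            logger.info("%s: up to date, skipping", stage)
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FN[stage](cfg, out)
        wall = time.perf_counter() - t0
        logger.info("%s: finished in %.1f s", stage, wall)
        inputs = [out / "holograms.tif"] if stage == "separate" else []
        _write_manifest(out, stage, cfg, inputs, outputs, wall)
    return out
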