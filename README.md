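# siht — structured-illumination holographic tomography with adaptive wavefront correction

`siht` is a computational twin of a mechanical-movement-free
structured-illumination holographic tomography (SI-HT) microscope with
CGH-based adaptive wavefront correction (AWC).  It is written for
instrument builders and computational-imaging researchers who want to
develop, test and calibrate the full reconstruction chain of such a system
— passband separation, holographic aberration sensing, adaptive
compensation, synthetic-aperture synthesis and 3-D refractive-index
tomography — without hardware: every stage runs against simulated data
whose ground truth is known exactly.

## The system being modelled

A phase-only SLM displays computer-generated holograms combining a phase
Fresnel lens with a steerable blazed grating,

    Φ_FZL(x, y) = π/(λf) (x² + y²),        Φ_blazed = 2π/Λ (x cosα + y sinα),

so the probe beam is scanned over illumination angles without moving
parts.  Each exposure illuminates the sample with two tilted plane waves
(carriers `f_x`, `f_y` at the illumination-pupil edge, `f = sinθ/λ`), so
the recorded spectrum is the sum of two displaced object-spectrum copies —
passbands

    D₁(u,v) ∝ A_d(u,v) · S_obj(u + f_x, v) · e^{j2πW(u,v)},
    D₂(u,v) ∝ A_d(u,v) · S_obj(u, v + f_y) · e^{j2πW(u,v)},

clipped by the detection pupil `A_d` and multiplied by the pupil wavefront
error `W` (waves, a Zernike expansion).  Object frequencies far beyond the
pupil are down-modulated into it as moiré beats.  Off-axis holography
recovers the complex field of every exposure; two phase-shifted exposures
(0° and 120°) per orientation are unmixed by the pseudoinverse of the 2×2
phase-shift mixing matrix.  The aberration `W` is estimated from the
separated passbands themselves (the phase of `D₁·conj(D₂)` is a lateral
shear of `W`; the object cancels), the conjugate Zernike phase is folded
into the next CGH sequence, and the corrected passbands are merged into a
synthetic aperture of radius `(NA_ill + NA_det)/λ` — twice the detection
pupil.  Per-angle corrected fields finally map onto Ewald-sphere caps
(Rytov linearisation + Fourier diffraction theorem) and a
Gerchberg–Papoulis constrained inversion yields the 3-D refractive index.

Default configuration: λ = 532 nm, NA_ill = NA_det = 0.9, 60 scan
orientations × 2 phase shifts (120 passbands), 1024² grid at 40 nm pitch.
Phantoms: a Siemens star with 150 nm minimal line width (300 nm per spoke
pair) and a yeast-like cell with refractive indices spanning 1.34–1.42.

## Worked example

```python
import numpy as np
from siht import (OpticalConfig, GridSpec, ZernikeCoeffs, SiemensStarSpec,
                  make_siemens_star, build_scan_schedule, awc_loop,
                  make_acquirer, acquire_passbands, synthesize,
                  reconstruct_image, measure_resolution, sparrow_limit)

cfg  = OpticalConfig()                       # 532 nm, NA 0.9/0.9
grid = GridSpec(1024, 1024, 40.0)
star_spec = SiemensStarSpec()                # 150 nm minimal line width
star = make_siemens_star(star_spec, grid)
sched = build_scan_schedule(cfg, grid, 16)   # scaled 16-orientation scan

print(round(sparrow_limit(cfg.wavelength, cfg.na_det)))   # -> 455

# inject a 0.4-wave RMS aberration over Noll modes 4..11
rng = np.random.default_rng(1)
v = rng.normal(size=8); v *= 0.4 / np.linalg.norm(v)
w = ZernikeCoeffs.from_vector(range(4, 12), v)

# uncorrected synthetic-aperture reconstruction
img = reconstruct_image(synthesize(
    acquire_passbands(star, sched, cfg, aberration=w,
                      photons=1e4, seed=7), cfg))
print(measure_resolution(img, star_spec).smallest_resolved)   # -> 260.0

# adaptive wavefront correction, then re-acquire and synthesize
acq = make_acquirer(star, sched, cfg, w, photons=1e4, seed=7)
est, comp = awc_loop(acq, cfg, grid, modes=range(4, 16), tol=0.01)
print(est.iterations, f"{est.update_rms:.1e}")                # -> 2 3.1e-05
img = reconstruct_image(synthesize(
    acquire_passbands(star, sched, cfg, aberration=w,
                      compensation=comp.coeffs, photons=1e4, seed=8), cfg))
print(measure_resolution(img, star_spec).smallest_resolved)   # -> 150.0
```

The numbers mean: the uncorrected system resolves star lines only down to
260 nm under this aberration; the adaptive loop converges in two
iterations to a residual of ~3·10⁻⁵ waves; after correction the full
synthetic aperture is restored and the 150 nm lines (the finest the target
carries, just above the 147.8 nm synthetic-aperture cutoff λ/(2·1.8))
meet the 10 % modulation-dip criterion.

A command-line pipeline wraps the same chain and persists TIFF/HDF5
artifacts with manifests:

```bash
siht run-all --seed 1 --out-dir run       # simulate → … → tomo → report
siht simulate --orientations 16 --out-dir run
```

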