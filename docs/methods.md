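# Methods

This note records the physical model implemented by `siht`, the numerical
conventions, the choices made where the design was genuinely open, and the
limits of what the simulations demonstrate.

## Forward model

**Geometry and units.** All lengths are in nanometres, spatial frequencies
in cycles/nm. Object-space grids are centred on the pixel `n//2`; all
spectra are stored DC-centred and transformed with the orthonormal centred
FFT pair, so Parseval holds exactly between domains. The default grid is
1024×1024 at 40 nm pitch, a comfortable Nyquist margin for the synthetic
aperture (λ/(2·(NA_ill+NA_det)) = 147.8 nm at 532 nm and NA 0.9+0.9).

**Illumination.** One structured-illumination exposure is the coherent sum
of two tilted plane waves, the +1 orders of the x- and y-axis scanning
CGHs; their carriers are 90° apart on the illumination-pupil rim and
rotate together through M uniform orientations. The phase shift
φ ∈ {0°, 120°} enters as `e^{+jφ}` on the first beam and `e^{−jφ}` on the
second; this fixed convention is the single source of truth shared by the
simulator and the separation stage (the mixing matrix
`[[e^{jφ_k}, e^{−jφ_k}]]` has condition number √3 for the {0°, 120°} set).
Carriers are rounded to integer frequency pixels and clamped just inside
the detection pupil: integer carriers make passband re-centring an exact
array roll (no interpolation), and the clamp prevents the rounded carrier
from landing outside the pupil, where it would be clipped. Both are
idealisations a real instrument only approximates; they remove two
nuisance error sources that are irrelevant to what the twin is meant to
test.

**Aberration.** The system aberration is a Zernike wavefront W(u,v) (Noll
indexing and normalisation, coefficients in waves) over the detection
pupil: CTF = A_d·exp(j2πW). A pupil-plane aberration is what actually
degrades resolution — any phase screen at an image-conjugate plane
commutes through the shift-invariant imaging chain and leaves image
*amplitudes* untouched, so it could never reproduce the observed loss and
recovery of star contrast. Noll normalisation makes the RMS wavefront
error the quadrature sum of the coefficients.

**Recording.** The image-plane field interferes with an off-axis reference
placed on the grid diagonal at 3× the detection-pupil radius (the +1 order
then just clears the autocorrelation band). The reference amplitude
defaults to twice the object peak. Shot noise is Poisson at a configurable
photon budget (default 10⁴ photons/pixel mean), drawn from a seeded
generator; every simulated data set is bit-reproducible from its seed.

## Reconstruction chain

**Demodulation.** The +1 order is cropped with a raised-cosine-apodised
disk of 1.1× the pupil radius (10 % guard band limits ringing), recentred,
inverse-transformed and divided by the reference amplitude. The only
failure guard is gross emptiness of the crop region (no local peak search
beyond that; carrier metadata is trusted, as stated in the scope).

**Separation.** Per frequency pixel, the two-exposure system is solved
with the pseudoinverse of the mixing matrix, so over-determined shift sets
(≥3 exposures) work unchanged. Separated passbands are re-centred by their
integer carriers.

**Aberration estimation (pupil shear).** After re-centring, the two
passbands of one exposure are `D_i(u) = S(u)·A_d(u−f_i)·e^{j2πW(u−f_i)}`.
The object spectrum cancels exactly in `D₁·conj(D₂)`, whose phase over the
support overlap is the lateral shear `2π[W(u−f₁) − W(u−f₂)]` with a known
per-orientation shear vector. Differences of Zernike modes are linear in
the coefficients, so all orientations enter one weighted least-squares
system; the unknown per-orientation phase offsets are eliminated by
weighted centring. Piston cancels identically in the shear and tip/tilt is
degenerate with the per-orientation offsets (it only displaces the image),
so fitting starts at defocus (Noll 4; default modes 4–15, q=15 — the mode
count is a design choice, not an instrument datum). Numerical
safeguards: per orientation only the largest connected component above a
permissive magnitude floor is unwrapped (object-spectrum nulls otherwise
seed unwrap sheet errors), pixels below the median magnitude are dropped
from the fit, and the solution is polished by three wrapped-residual
refinement passes, which are immune to any remaining 2π-sheet error once
the model is within half a wave of the data pointwise. Noise-free and
within the fitted span, recovery is exact to machine precision; at 10⁴
photons/pixel the median coefficient-vector error over random draws is
~0.1 %. At least ~3 distinct shear directions are needed to condition 8+
modes (two orientations 180° apart share one shear axis and are
degenerate); the acceptance checks use M ≥ 4.

**Compensation.** The conjugate coefficients are folded into the scanning
CGHs (`CompensationModel` carries the modified Φ₁/Φ₂ maps). In the
simulator the compensation multiplies the system CTF by `e^{−j2πŴ}`: the
SLM hosts the Fresnel lens and is therefore the pupil-conjugate plane of
the illumination relay, so phase displayed on it arrives in the pupil
domain. The relay of the (smooth, low-order) compensation term is modelled
as ideal; `design_compensation` exposes a `conjugate_distance` parameter
(angular-spectrum propagation of the conjugate screen, default 0) for
studies of a displaced compensation plane.

**Adaptive loop.** Estimate → fold conjugate into CGHs → re-acquire,
until the RMS of the newly estimated *remaining* aberration falls below
tol (default 0.01 waves) or max_iter (default 10; neither is an instrument
datum). The best iterate is kept, making the reported residual sequence
non-increasing; an in-span noise-free aberration converges in two
iterations (the second merely verifies the null).

**Synthesis.** Each corrected, re-centred passband contributes on the
detection-pupil disk around its true offset; overlaps are combined by a
coverage-weighted mean rather than a plain sum, so a flat object spectrum
stays unbiased and the synthetic transfer behaves like a binary disk of
radius (NA_ill+NA_det)/λ. The 1024²×40 nm frequency grid already spans
more than twice the pupil, so no regridding is needed.

**Resolution metric.** The azimuthal intensity profile on the circle where
the local line width equals a candidate value is correlated against the
*known* spoke harmonics: the fundamental at the pair count n (phase −j/π
for the 0/1 duty-0.5 mask) and a −cos comb at multiples of 2n (the
transition dips of the ±1 binary-phase target; intensity frequency-doubles
there). Matching known phases is what makes the metric speckle-safe: a
fully scrambled image has O(1) random max–min contrast that a naive dip
measure would count as resolved, while its matched projection averages to
zero. Modulation is normalised by the local mean plus a 5 % image-mean
floor, clipped to [0,1], averaged over three nearby radii, and thresholded
at 10 % (configurable); the smallest resolved width is the end of the
contiguous resolved run from coarse to fine, so isolated speckle
coincidences deep in the unresolved regime do not count. The matched
comb under-reports very wide spokes (narrow dips spread power past the
comb), so the per-width contrast table is not forced to be monotone; the
contiguity rule provides the robustness a monotone table would have given.
Note the star-grating cutoff and the two-point Sparrow limit are different
observables: a pupil-filtered star resolves to λ/(2NA) = 295.6 nm (→ the
300 nm ladder rung), while `sparrow_limit` returns 0.77·λ/NA = 455 nm, the
system's quoted two-point figure.

## Tomography

Per-angle fields are generated by an independent multislice
(beam-propagation) forward model — phase kick `exp(jk(n−n₀)dz)` per slice,
angular-spectrum step in the n₀ = 1.34 medium, refocus to the volume
centre, detection-pupil band limit — with the background field run through
the identical numerical chain so all propagation phases cancel in the
Rytov ratio ψ = ln(u_s/u_b). Rytov rather than Born is the default
linearisation (cell-scale phase accumulation; Born is kept as a
cross-check). The Fourier diffraction theorem maps the 2-D FFT of ψ onto
an Ewald cap with weight −4jπk_z, nearest-voxel gridding with coverage
counts, overlaps averaged. Inversion alternates object-domain constraints
(real potential, n ≥ n₀, support from the thresholded first pass dilated
by 3 voxels) with frequency-domain data consistency for 50 iterations
(Gerchberg–Papoulis), which shrinks the missing-cone axial elongation
monotonically. Validation on a 128³×80 nm grid with 16 orientations (32
caps): a Δn = 0.02, R = 1 µm sphere recovers its centre contrast within
10 %, and the default cell phantom recovers the cytoplasm mean RI within
0.002. Gibbs ringing at voxel-sharp organelle boundaries overshoots the
true maximum RI by up to ~0.006; this is inherent to hard
frequency-consistency resets and is left unregularised by design (no TV or
other prior, per scope).

## Scaled problem sizes

The simulated validation conditions mirror the instrument's parameters
(λ = 532 nm, NA 0.9/0.9, {0°, 120°} shifts, 150 nm star, RI 1.34–1.42,
10⁴ photons/pixel) with these package-chosen sizes: the flagship AWC
resolution claim runs M = 16 orientations instead of the instrument's 60
(16 is the smallest power-of-two count whose rim coverage still spans
≥ 89 % of azimuth at the 150 nm ring; 60 is exercised separately in the
coverage-monotonicity property), recovery statistics use a 256² grid with
M = 4, and tomography 128³ voxels at 80 nm. The full 60-orientation,
1024² pipeline is available through `siht run-all`.

## What the phantoms do and do not show

The generators are deterministic, anti-aliased (2× supersampling,
box-downsampled) and geometrically exact, which is what parameter-recovery
oracles need. They do not emulate real samples' roughness, dispersion,
absorption, partial coherence, or candida morphology beyond compartment
structure and the printed RI range; the cell phantom's per-organelle RI
values are fixture conventions chosen to span 1.34–1.42. Passing tests
demonstrate correctness of the reconstruction mathematics under the stated
noise model — not robustness to camera MTF, SLM quantisation, drift, or
multiple scattering, all of which are out of scope.

## Known limitations

* Aberration sensing needs object spectral content in the passband
  overlap: an empty field of view gives delta spectra with nothing to
  shear, so calibration is self-referenced on object-bearing exposures.
* Tip/tilt and piston are not sensed (absorbed by carrier bookkeeping);
  aberration components outside the fitted mode span bias the fit by
  their projection onto it.
* The Rytov linearisation degrades for Δn beyond ~0.04 at cell scale;
  the missing cone is mitigated, not removed, by the constraints.
* Noise in the hologram corners is genuine energy to the demodulator; the
  metadata-mismatch guard only catches essentially empty crop regions.
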