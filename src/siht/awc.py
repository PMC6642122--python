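"""Adaptive wavefront correction: aberration estimation and CGH compensation.

Estimation principle
--------------------
After re-centring, the two separated passbands of one exposure are

    D1(u) = S(u) A_d(u - f1) exp(j 2 pi W(u - f1)),
    D2(u) = S(u) A_d(u - f2) exp(j 2 pi W(u - f2)),

with ``S`` the object spectrum and ``W`` the pupil wavefront in waves.  The
object cancels exactly in ``D1 * conj(D2)``, whose phase over the support
overlap is the *lateral shear* of the pupil wavefront,

    2 pi [ W(u - f1) - W(u - f2) ],

with a known shear vector per scanning orientation.  Differences of Zernike
modes are linear in the coefficients, so unwrapping the shear maps of all
orientations and solving one weighted least-squares system recovers the
coefficients directly — a self-calibration that needs no separate reference
object.  Piston cancels in the shear and tip/tilt is degenerate with the
per-orientation phase offsets (it only displaces the image), so fitted
modes start at defocus; tilt is absorbed by the carrier bookkeeping.

The compensation is the conjugate Zernike phase folded into the scanning
CGHs; the SLM sits in the Fresnel-lens (pupil-conjugate) plane, so in the
simulator the compensation term multiplies the system CTF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .holography import PassbandSet, unwrap_phase
from .optics import (ComplexField, GridSpec, OpticalConfig, ZernikeCoeffs,
                     cgh_phase, propagate_angular_spectrum, zernike_mode,
                     zernike_phase)

__all__ = [
    "ConditioningError",
    "AberrationEstimate",
    "CompensationModel",
    "DEFAULT_MODES",
    "estimate_aberration",
    "design_compensation",
    "awc_loop",
]

DEFAULT_MODES: tuple[int, ...] = tuple(range(4, 16))  # defocus .. Noll 15 (q = 15)


class ConditioningError(RuntimeError):
    """Too few usable pixels to condition the Zernike fit."""


@dataclass
class AberrationEstimate:
    """Zernike estimate of the shared detection-pupil wavefront.

    ``residual_rms`` is the weighted RMS misfit (waves) between the
    unwrapped shear phase and its Zernike model; ``update_rms`` the RMS of
    the estimated coefficients themselves — the remaining aberration the
    loop still has to correct.
    """

    coeffs: ZernikeCoeffs
    residual_rms: float
    update_rms: float = 0.0
    iterations: int = 1
    converged: bool = True
    history: list[float] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual must be non-negative")


def _passband_weight_and_phase(pb: PassbandSet, r_det_px: float
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overlap mask, weights and wrapped shear phase for one orientation."""
    grid = pb.grid
    ix = np.arange(grid.nx) - grid.nx // 2
    iy = np.arange(grid.ny) - grid.ny // 2
    xx, yy = np.meshgrid(ix, iy)
    (k1x, k1y), (k2x, k2y) = pb.carriers_px
    in1 = (xx - k1x) ** 2 + (yy - k1y) ** 2 <= r_det_px ** 2
    in2 = (xx - k2x) ** 2 + (yy - k2y) ** 2 <= r_det_px ** 2
    overlap = in1 & in2
    prod = pb.d1 * np.conj(pb.d2)
    return overlap, np.abs(prod), np.angle(prod)


def estimate_aberration(passbands: PassbandSet | Sequence[PassbandSet],
                        cfg: OpticalConfig,
                        modes: Iterable[int] = DEFAULT_MODES,
                        mask: np.ndarray | None = None,
                        weight_quantile: float = 0.5) -> AberrationEstimate:
    """Least-squares Zernike fit of the pupil wavefront from passband shear.

    Parameters
    ----------
    passbands:
        One or more separated :class:`PassbandSet` (one per scanning
        orientation; more orientations condition more modes).
    modes:
        Noll indices to fit; defaults to 4..15.  Tip/tilt cannot be sensed
        by the shear (they are returned as zero).
    mask:
        Optional boolean frequency-grid mask restricting the usable region
        (e.g. to exclude a contaminated band); ``None`` uses the full
        pupil-support overlap.
    weight_quantile:
        Pixels below this quantile of the magnitude weight are dropped;
        the rest enter the fit weighted by magnitude, which suppresses
        object-spectrum nulls and shot noise.
    """
    if isinstance(passbands, PassbandSet):
        passbands = [passbands]
    passbands = list(passbands)
    if not passbands:
        raise ValueError("no passbands given")
    modes = [int(j) for j in modes]
    if any(j < 2 for j in modes):
        raise ValueError("piston (Noll 1) cannot be fitted from shear data")
    fit_modes = [j for j in modes if j >= 4]
    grid = passbands[0].grid
    r_det_px = cfg.cutoff_det / grid.dfx
    n_par = len(fit_modes)

    # per-orientation cache: weights, wrapped phase, design matrix
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    n_pix_total = 0
    ix = np.arange(grid.nx) - grid.nx // 2
    iy = np.arange(grid.ny) - grid.ny // 2
    xx, yy = np.meshgrid(ix, iy)

    for pb in passbands:
        overlap, weight, wrapped_raw = _passband_weight_and_phase(pb, r_det_px)
        if mask is not None:
            overlap &= mask.astype(bool)
        if not overlap.any():
            continue
        w = np.where(overlap, weight, 0.0)
        # keep the largest connected component above a permissive floor, so
        # object-spectrum nulls cannot seed unwrap sheet errors or split the
        # region into patches with independent 2-pi offsets
        floor = np.quantile(w[overlap], min(0.5 * weight_quantile, 0.45))
        cand = overlap & (w > max(floor, 0.0))
        lab, nlab = ndimage.label(cand)
        if nlab == 0:
            continue
        largest = np.argmax(ndimage.sum_labels(np.ones_like(w), lab,
                                               range(1, nlab + 1))) + 1
        region = lab == largest
        thr = np.quantile(w[region], weight_quantile)
        sel = region & (w >= thr)
        if sel.sum() < 4:
            continue
        phase = unwrap_phase(np.where(region, wrapped_raw, 0.0), mask=region)
        wsel = w[sel]
        obs_init = phase[sel] / (2.0 * math.pi)       # waves, unwrap-seeded
        obs_raw = wrapped_raw[sel] / (2.0 * math.pi)  # waves, wrapped, exact
        (k1x, k1y), (k2x, k2y) = pb.carriers_px
        cols = []
        for j in fit_modes:
            z1 = _mode_at(j, (xx[sel] - k1x) / r_det_px, (yy[sel] - k1y) / r_det_px)
            z2 = _mode_at(j, (xx[sel] - k2x) / r_det_px, (yy[sel] - k2y) / r_det_px)
            cols.append(z1 - z2)
        blocks.append((wsel, obs_init, obs_raw, np.column_stack(cols)))
        n_pix_total += int(sel.sum())

    if n_pix_total < 5 * n_par:
        raise ConditioningError(
            f"only {n_pix_total} usable pixels for {n_par} modes "
            f"(need >= {5 * n_par})")

    def solve(observations: list[np.ndarray]) -> np.ndarray:
        ata = np.zeros((n_par, n_par))
        atb = np.zeros(n_par)
        for (wsel, _, _, a), obs in zip(blocks, observations):
            obs_c = obs - np.average(obs, weights=wsel)
            a_c = a - np.average(a, axis=0, weights=wsel)
            aw = a_c * wsel[:, None]
            ata += a_c.T @ aw
            atb += aw.T @ obs_c
        return np.linalg.solve(ata, atb)

    sol = solve([obs for _, obs, _, _ in blocks])
    # wrapped-residual refinement against the *raw* phase: once the model is
    # within half a wave of the data pointwise this is immune to unwrap
    # sheet errors and to the smoothing bias of the seeding pass
    for _ in range(3):
        resid_obs = []
        for wsel, _, obs_raw, a in blocks:
            r = obs_raw - a @ sol
            resid_obs.append(np.angle(np.exp(2j * math.pi * r)) / (2.0 * math.pi))
        sol = sol + solve(resid_obs)

    # weighted RMS misfit of the shear model, in waves (wrapped residual)
    rss = 0.0
    wss = 0.0
    for wsel, _, obs_raw, a in blocks:
        r = obs_raw - a @ sol
        r = np.angle(np.exp(2j * math.pi * r)) / (2.0 * math.pi)
        r = r - np.average(r, weights=wsel)
        rss += float(np.sum(wsel * r * r))
        wss += float(wsel.sum())
    residual = math.sqrt(rss / wss) if wss > 0 else 0.0
    coeffs = {j: 0.0 for j in modes}
    coeffs.update(dict(zip(fit_modes, (float(s) for s in sol))))
    zc = ZernikeCoeffs(coeffs, order=max(modes))
    return AberrationEstimate(coeffs=zc, residual_rms=residual,
                              update_rms=zc.rms(exclude=(1, 2, 3)))


def _mode_at(j: int, ux: np.ndarray, uy: np.ndarray) -> np.ndarray:
    rho = np.hypot(ux, uy)
    theta = np.arctan2(uy, ux)
    return zernike_mode(j, rho, theta)


# ---------------------------------------------------------------------------
# compensation design
# ---------------------------------------------------------------------------

@dataclass
class CompensationModel:
    """Conjugate Zernike phase folded into the scanning CGHs.

    ``coeffs`` are the conjugate (negated-estimate) coefficients in waves;
    ``pupil_phase`` is the conjugate wavefront map (waves) on the frequency
    grid; ``phi1``/``phi2`` are the x- and y-axis CGH phase maps with the
    compensation term added.
    """

    coeffs: ZernikeCoeffs
    pupil_phase: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    grid: GridSpec

    def is_null(self) -> bool:
        return all(z == 0.0 for _, z in self.coeffs.items())


def design_compensation(est: AberrationEstimate, cfg: OpticalConfig,
                        grid: GridSpec,
                        conjugate_distance: float = 0.0) -> CompensationModel:
    """Build the compensation model from an aberration estimate.

    The conjugate phase is evaluated at the SLM (pupil-conjugate) plane; a
    non-zero ``conjugate_distance`` (nm) additionally diffracts the
    conjugate screen to a displaced conjugate plane with the angular-
    spectrum propagator before it is combined with the CGHs.
    """
    conj = -est.coeffs
    pupil_phase = zernike_phase(conj, grid, cfg.cutoff_det, space="frequency")
    if conjugate_distance != 0.0:
        screen = ComplexField(grid,
                              np.exp(2j * math.pi * pupil_phase),
                              plane="pupil")
        screen = propagate_angular_spectrum(screen, conjugate_distance, cfg)
        pupil_phase = np.angle(screen.values) / (2.0 * math.pi)
    phi1 = cgh_phase(grid, cfg, axis="x", compensation=conj)
    phi2 = cgh_phase(grid, cfg, axis="y", compensation=conj)
    return CompensationModel(coeffs=conj, pupil_phase=pupil_phase,
                             phi1=phi1, phi2=phi2, grid=grid)


# ---------------------------------------------------------------------------
# the adaptive loop
# ---------------------------------------------------------------------------

def awc_loop(acquire: Callable[[ZernikeCoeffs | None], Sequence[PassbandSet]],
             cfg: OpticalConfig, grid: GridSpec,
             modes: Iterable[int] = DEFAULT_MODES,
             max_iter: int = 10, tol: float = 0.01,
             ) -> tuple[AberrationEstimate, CompensationModel]:
    """Estimate / compensate / re-acquire until the residual falls below tol.

    ``acquire`` maps a compensation coefficient set (conjugate waves, or
    ``None``) to freshly separated passbands — in simulation a re-run of the
    forward model, on an instrument a re-recording with updated CGHs.  The
    residual metric is the RMS (waves) of the estimated *remaining*
    aberration; the best iterate is kept, so the reported residual sequence
    is non-increasing.
    """
    modes = list(modes)
    total = ZernikeCoeffs({j: 0.0 for j in modes})
    best_total = total
    best_resid = math.inf
    history: list[float] = []
    converged = False
    iterations = 0
    last_fit_resid = 0.0

    for it in range(1, max_iter + 1):
        iterations = it
        comp = None if all(z == 0.0 for _, z in best_total.items()) else -best_total
        pbs = acquire(comp)
        delta = estimate_aberration(pbs, cfg, modes=modes)
        last_fit_resid = delta.residual_rms
        if delta.update_rms < best_resid:
            # accept the update; the estimated remaining aberration shrank
            best_resid = delta.update_rms
            best_total = best_total + delta.coeffs
        history.append(best_resid)
        if best_resid < tol:
            converged = True
            break

    est = AberrationEstimate(coeffs=best_total,
                             residual_rms=last_fit_resid,
                             update_rms=best_resid if history else 0.0,
                             iterations=iterations, converged=converged,
                             history=history)
    comp_model = design_compensation(est, cfg, grid)
    return est, comp_model
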