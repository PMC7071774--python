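"""Inverse stage: optical properties from frequency-domain sweeps and
broadband reflectance.

Three steps mirror the instrument's processing chain:

1. :func:`fit_fd_properties` — per laser wavelength, least-squares fit of the
   measured amplitude/phase sweep to the diffusion forward model, recovering
   (mua, musp).  Amplitude is known only up to a per-sweep instrumental gain,
   which is profiled out analytically by default.
2. :func:`fit_scatter_power` — power-law fit musp(lambda) = A (lambda/800)^-b
   through the per-wavelength musp estimates, giving the broadband scattering
   spectrum.
3. :func:`recover_broadband_mua` — the broadband reflectance channel is
   rescaled by a single gain chosen to match the model-predicted CW
   reflectance at the laser (anchor) wavelengths, then inverted wavelength by
   wavelength for mua with musp fixed from the power law.  The CW reflectance
   is strictly decreasing in mua, so the 1-D inversion has a unique root;
   wavelengths where the measurement falls outside the bracket are returned
   as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .photon import (
    FDDatum,
    OpticalProperties,
    ProbeGeometry,
    _cw_reflectance_grid,
    fd_reflectance,
)

__all__ = [
    "LaserSet",
    "ScatterModel",
    "FDFitResult",
    "fit_fd_properties",
    "fit_scatter_power",
    "recover_broadband_mua",
]

MUA_BRACKET = (1e-7, 0.2)  # 1/mm search interval for the 1-D inversion


@dataclass(frozen=True)
class LaserSet:
    """Laser diode wavelengths (nm); the instrument carries 4-6 in 650-1000 nm."""

    wavelengths: tuple = (659.0, 689.0, 781.0, 829.0)

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths)
        if not 4 <= len(wl) <= 6:
            raise ValueError("laser set must contain 4-6 wavelengths")
        if any(w < 650 or w > 1000 for w in wl):
            raise ValueError("laser wavelengths must lie in 650-1000 nm")
        object.__setattr__(self, "wavelengths", wl)


@dataclass(frozen=True)
class ScatterModel:
    """Reduced-scattering power law musp(lambda) = A (lambda / lambda_ref)^-b."""

    a: float
    b: float
    lambda_ref: float = 800.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("scattering amplitude A must be > 0")
        if self.b < 0:
            raise ValueError("scattering power b must be >= 0")

    def musp(self, wavelengths) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.a * (wl / self.lambda_ref) ** (-self.b)


@dataclass(frozen=True)
class FDFitResult:
    """Recovered optical properties plus fit diagnostics for one sweep."""

    props: OpticalProperties
    gain: float
    residual_norm: float
    converged: bool
    clipped: bool = False


def _sweep_arrays(sweep):
    data = sorted(sweep, key=lambda d: d.frequency)
    f = np.array([d.frequency for d in data])
    amp = np.array([d.amplitude for d in data])
    ph = np.array([d.phase for d in data])
    return f, amp, ph


def fit_fd_properties(
    sweep,
    geom: ProbeGeometry,
    init: OpticalProperties | None = None,
    fit_gain: bool = True,
    detector: str = "fluence",
    cost_tol: float = 1e-10,
    max_iter: int = 500,
) -> FDFitResult:
    """Recover (mua, musp) from one frequency sweep of amplitude and phase.

    The residual stacks relative amplitude errors and absolute phase errors
    (radians), equally weighted.  With ``fit_gain=True`` (default) the
    per-sweep amplitude gain is profiled out in closed form at every residual
    evaluation; ``fit_gain=False`` assumes an amplitude-calibrated sweep.
    Optimization is over log(mua), log(musp), so estimates are positive by
    construction; estimates pinned at the box bounds are flagged ``clipped``.
    Non-convergence is flagged, never raised.
    """
    sweep = list(sweep)
    if len(sweep) < 4:
        raise ValueError(f"need >= 4 frequencies, got {len(sweep)}")
    if not isinstance(sweep[0], FDDatum):
        sweep = [FDDatum(*row) for row in sweep]
    f, amp, ph = _sweep_arrays(sweep)
    init = init or OpticalProperties(0.005, 1.0)
    lb, ub = np.log([1e-5, 0.05]), np.log([0.5, 5.0])
    x0 = np.clip(np.log([init.mua, init.musp]), lb, ub)

    def residuals(x):
        mua, musp = np.exp(x)
        model = fd_reflectance(OpticalProperties(mua, musp), geom, f, detector=detector)
        a_model = np.abs(model)
        if fit_gain:
            u = a_model / amp
            g = float(np.sum(u) / np.sum(u**2))
        else:
            g = 1.0
        r_amp = (g * a_model - amp) / amp
        r_ph = np.angle(model) - ph
        return np.concatenate([r_amp, r_ph])

    import warnings

    def solve(x_start):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # trial points may leave the diffusion regime
            return least_squares(
                residuals, x_start, bounds=(lb, ub), ftol=cost_tol, xtol=1e-12,
                gtol=cost_tol, max_nfev=max_iter * 3,
            )

    sol = solve(x0)
    if np.linalg.norm(sol.fun) > 0.5:  # likely a local minimum from a far init
        for mua0 in (0.003, 0.01, 0.03):
            for musp0 in (0.5, 1.0, 2.0):
                cand = solve(np.log([mua0, musp0]))
                if cand.cost < sol.cost:
                    sol = cand
    mua, musp = np.exp(sol.x)
    clipped = bool(np.any(np.isclose(sol.x, lb)) or np.any(np.isclose(sol.x, ub)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        props = OpticalProperties(float(mua), float(musp))
        model = fd_reflectance(props, geom, f, detector=detector)
    a_model = np.abs(model)
    if fit_gain:
        u = a_model / amp
        gain = float(np.sum(u) / np.sum(u**2))
    else:
        gain = 1.0
    return FDFitResult(
        props=props,
        gain=gain,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0 and not clipped),
        clipped=clipped,
    )


def fit_scatter_power(wavelengths, musp_values, lambda_ref: float = 800.0) -> ScatterModel:
    """Fit the scattering power law through per-wavelength musp estimates.

    Linear least squares in log-log space: log musp = log A - b log(lambda/ref).
    Requires at least two wavelengths with positive musp; with exactly two the
    fit interpolates both points.
    """
    wl = np.asarray(wavelengths, dtype=float)
    musp = np.asarray(musp_values, dtype=float)
    ok = musp > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 wavelengths with positive musp")
    wl, musp = wl[ok], musp[ok]
    x = np.log(wl / lambda_ref)
    design = np.column_stack([np.ones_like(x), -x])
    coef, *_ = np.linalg.lstsq(design, np.log(musp), rcond=None)
    return ScatterModel(a=float(np.exp(coef[0])), b=float(coef[1]), lambda_ref=lambda_ref)


def recover_broadband_mua(
    wavelengths,
    reflectance,
    scatter: ScatterModel,
    geom: ProbeGeometry,
    anchor_wavelengths,
    anchors,
    detector: str = "fluence",
    n_bisect: int = 60,
):
    """Broadband mua spectrum from uncalibrated broadband reflectance.

    Parameters
    ----------
    wavelengths, reflectance : arrays
        Broadband grid (nm) and measured diffuse reflectance (arbitrary
        units, positive).
    scatter : ScatterModel
        Fixes musp(lambda) during the inversion.
    anchor_wavelengths, anchors : arrays / sequence of OpticalProperties
        Laser wavelengths and their FD-fitted properties; the broadband
        channel is rescaled by the single gain that best matches the
        model-predicted CW reflectance at these anchors (least squares).

    Returns
    -------
    mua : ndarray
        Recovered absorption (1/mm) on the input grid; NaN where the
        calibrated reflectance is not bracketed by the model over
        mua in (1e-7, 0.2].
    gain : float
        Fitted calibration gain applied to the measured reflectance.
    """
    wl = np.asarray(wavelengths, dtype=float)
    refl = np.asarray(reflectance, dtype=float)
    awl = np.asarray(anchor_wavelengths, dtype=float)
    if wl.min() > awl.min() or wl.max() < awl.max():
        raise ValueError("broadband grid must cover the anchor wavelengths")
    r_model = np.array(
        [
            _cw_reflectance_grid(a.mua, scatter.musp(w), geom, detector)
            for w, a in zip(awl, anchors)
        ],
        dtype=float,
    )
    r_meas = np.interp(awl, wl, refl)
    denom = float(np.sum(r_meas**2))
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("anchor gain fit is ill-conditioned (nonpositive reflectance)")
    gain = float(np.sum(r_model * r_meas) / denom)
    target = gain * refl

    musp = scatter.musp(wl)
    lo = np.full_like(wl, MUA_BRACKET[0])
    hi = np.full_like(wl, MUA_BRACKET[1])
    # CW reflectance decreases in mua: root bracketed iff R(hi) <= target <= R(lo)
    r_lo = _cw_reflectance_grid(lo, musp, geom, detector)
    r_hi = _cw_reflectance_grid(hi, musp, geom, detector)
    ok = (target <= r_lo) & (target >= r_hi)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        r_mid = _cw_reflectance_grid(mid, musp, geom, detector)
        take_hi = r_mid >= target  # root above mid
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    mua = 0.5 * (lo + hi)
    mua[~ok] = np.nan
    return mua, gain
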