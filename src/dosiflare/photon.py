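"""Frequency-domain photon diffusion forward model for a semi-infinite medium.

The P1 (diffusion) approximation to the Boltzmann transport equation, solved
in the frequency domain with extrapolated-boundary semi-infinite boundary
conditions, predicts the amplitude and phase of intensity-modulated light
remitted from tissue.  A real isotropic source is placed one transport mean
free path below the surface and balanced by a negative image source above the
extrapolated boundary; the complex fluence at the detector is the difference
of the two spherical-wave terms.

Quantities and units
--------------------
``mua``, ``musp``   absorption / reduced scattering coefficients, 1/mm
``rho``             source-detector separation, mm
``f_mod``           modulation frequency, MHz
phase               radians, negative-going with frequency (e^{+i omega t}
                    convention); reported relative to the zero-frequency limit
reflectance         fluence-based surface reflectance, 1/mm^2 (up to the
                    instrument gain, which the inverse stage treats as a
                    nuisance parameter)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

__all__ = [
    "C0_MM_PER_NS",
    "OpticalProperties",
    "ProbeGeometry",
    "ModulationSweep",
    "FDDatum",
    "diffusion_coefficient",
    "effective_reflection_coefficient",
    "fd_reflectance",
    "cw_reflectance",
]

#: Vacuum speed of light in mm/ns.
C0_MM_PER_NS = 299.792458


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering at one wavelength.

    Parameters
    ----------
    mua : float
        Absorption coefficient (1/mm), > 0.
    musp : float
        Reduced scattering coefficient (1/mm), > 0.  The diffusion
        approximation assumes ``musp >> mua``; a warning is emitted when
        ``musp / mua < 10``.
    """

    mua: float
    musp: float

    def __post_init__(self) -> None:
        if not (self.mua > 0 and np.isfinite(self.mua)):
            raise ValueError(f"mua must be positive and finite, got {self.mua}")
        if not (self.musp > 0 and np.isfinite(self.musp)):
            raise ValueError(f"musp must be positive and finite, got {self.musp}")
        if self.musp / self.mua < 10:
            warnings.warn(
                f"musp/mua = {self.musp / self.mua:.2f} < 10: outside the "
                "diffusion-validity regime",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ProbeGeometry:
    """Handheld-probe geometry and refractive indices.

    rho is the source-detector separation on the tissue surface (mm);
    n_tissue / n_outside are the interior and exterior refractive indices.
    """

    rho: float = 28.0
    n_tissue: float = 1.4
    n_outside: float = 1.0

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.n_tissue < 1 or self.n_outside < 1:
            raise ValueError("refractive indices must be >= 1")


@dataclass(frozen=True)
class ModulationSweep:
    """Ordered modulation frequencies (MHz), by default the 50-400 MHz band."""

    frequencies: tuple = field(
        default_factory=lambda: tuple(np.linspace(50.0, 400.0, 15))
    )

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", tuple(float(x) for x in f))


@dataclass(frozen=True)
class FDDatum:
    """One measured (frequency, amplitude, phase) triple.

    Amplitude is in arbitrary linear units (known only up to a gain);
    phase is in radians, negative-going with frequency.
    """

    frequency: float
    amplitude: float
    phase: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not np.isfinite(self.phase):
            raise ValueError("phase must be finite")


def diffusion_coefficient(op: OpticalProperties) -> float:
    """Photon diffusion coefficient D = 1 / (3 (mua + musp)), in mm."""
    return 1.0 / (3.0 * (op.mua + op.musp))


def _fresnel_unpolarized(cos_ti: np.ndarray, n_rel: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for internal incidence, n_rel = n_in/n_out."""
    cos_ti = np.asarray(cos_ti, dtype=float)
    sin_ti = np.sqrt(np.clip(1.0 - cos_ti**2, 0.0, 1.0))
    sin_tt = n_rel * sin_ti
    total = sin_tt >= 1.0  # total internal reflection
    cos_tt = np.sqrt(np.clip(1.0 - sin_tt**2, 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (n_rel * cos_ti - cos_tt) / (n_rel * cos_ti + cos_tt)
        rp = (n_rel * cos_tt - cos_ti) / (n_rel * cos_tt + cos_ti)
    r = 0.5 * (rs**2 + rp**2)
    return np.where(total, 1.0, r)


@lru_cache(maxsize=32)
def effective_reflection_coefficient(n_tissue: float, n_outside: float) -> float:
    """Effective internal reflection coefficient R_eff of the index mismatch.

    Computed from the fluence-rate and current Fresnel moments

        R_phi = int_0^{pi/2} 2 sin(t) cos(t)   R_F(t) dt
        R_j   = int_0^{pi/2} 3 sin(t) cos^2(t) R_F(t) dt
        R_eff = (R_phi + R_j) / (2 - R_phi + R_j)

    by adaptive quadrature (no polynomial approximation).  Matched indices
    give exactly 0.  Results are cached per index pair.
    """
    if n_tissue == n_outside:
        return 0.0
    n_rel = n_tissue / n_outside

    def integrand_phi(t: float) -> float:
        return 2.0 * np.sin(t) * np.cos(t) * float(_fresnel_unpolarized(np.cos(t), n_rel))

    def integrand_j(t: float) -> float:
        return 3.0 * np.sin(t) * np.cos(t) ** 2 * float(_fresnel_unpolarized(np.cos(t), n_rel))

    # split at the critical angle: the Fresnel kink otherwise limits accuracy
    if n_rel > 1:
        theta_c = float(np.arcsin(1.0 / n_rel))
        pieces = [(0.0, theta_c), (theta_c, np.pi / 2)]
    else:
        pieces = [(0.0, np.pi / 2)]
    r_phi = sum(quad(integrand_phi, a, b, limit=200)[0] for a, b in pieces)
    r_j = sum(quad(integrand_j, a, b, limit=200)[0] for a, b in pieces)
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


def _complex_fluence(
    mua: np.ndarray,
    musp: np.ndarray,
    rho: float,
    n_tissue: float,
    n_outside: float,
    f_mod: np.ndarray,
    detector: str = "fluence",
):
    """Vectorized two-source Green's function evaluation (internal).

    Broadcasts over mua, musp and f_mod.  ``detector`` selects the
    fluence-rate model (default) or the Fick's-law flux variant.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    f_mod = np.asarray(f_mod, dtype=float)
    d = 1.0 / (3.0 * (mua + musp))
    v = C0_MM_PER_NS / n_tissue  # mm/ns
    omega = 2.0 * np.pi * f_mod * 1e-3  # MHz -> rad/ns
    k = np.sqrt((mua + 1j * omega / v) / d)
    z0 = 1.0 / (mua + musp)
    r_eff = effective_reflection_coefficient(float(n_tissue), float(n_outside))
    zb = 2.0 * d * (1.0 + r_eff) / (1.0 - r_eff)
    r1 = np.sqrt(rho**2 + z0**2)
    r2 = np.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)
    if detector == "fluence":
        return (np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2) / (4.0 * np.pi * d)
    if detector == "flux":
        term1 = z0 * (k + 1.0 / r1) * np.exp(-k * r1) / r1**2
        term2 = (z0 + 2.0 * zb) * (k + 1.0 / r2) * np.exp(-k * r2) / r2**2
        return (term1 + term2) / (4.0 * np.pi)
    raise ValueError(f"unknown detector model {detector!r}")


def fd_reflectance(
    op: OpticalProperties,
    geom: ProbeGeometry,
    f_mod,
    detector: str = "fluence",
) -> complex | np.ndarray:
    """Complex frequency-domain reflectance at modulation frequency f_mod (MHz).

    Returns the complex surface reflectance whose modulus is the measured
    amplitude (arbitrary gain) and whose argument is the phase relative to
    zero frequency.  ``f_mod`` may be a scalar or an array; frequencies must
    be >= 0.  The phase is exactly 0 at ``f_mod = 0``.

    The optional ``detector`` flag switches between the fluence-rate surface
    model (default) and a Fick's-law flux model.
    """
    f = np.asarray(f_mod, dtype=float)
    if np.any(f < 0):
        raise ValueError("modulation frequency must be >= 0")
    out = _complex_fluence(
        op.mua, op.musp, geom.rho, geom.n_tissue, geom.n_outside, f, detector
    )
    if np.isscalar(f_mod) or np.ndim(f_mod) == 0:
        return complex(out)
    return out


def cw_reflectance(
    op: OpticalProperties, geom: ProbeGeometry, detector: str = "fluence"
) -> float:
    """Steady-state (zero-frequency) diffuse reflectance, 1/mm^2.

    Equal to the modulus of :func:`fd_reflectance` at ``f_mod = 0`` and
    strictly decreasing in ``mua`` at fixed ``musp`` and ``rho``.
    """
    return float(np.real(fd_reflectance(op, geom, 0.0, detector=detector)))


def _cw_reflectance_grid(
    mua, musp, geom: ProbeGeometry, detector: str = "fluence"
) -> np.ndarray:
    """Vectorized CW reflectance over arrays of (mua, musp); used by inversion."""
    return np.real(
        _complex_fluence(mua, musp, geom.rho, geom.n_tissue, geom.n_outside, 0.0, detector)
    )
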