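"""Chromophore spectral unmixing and composite tissue metrics.

Broadband tissue absorption in the near-infrared window (650-1000 nm) is
modelled as a nonnegative linear combination of four chromophores by Beer's
law:

    mua(lambda) = eps_HbO2(lambda) * [HbO2] + eps_HHb(lambda) * [HHb]
                + eps_water(lambda) * water% + eps_lipid(lambda) * lipid%

with hemoglobins in uM and water/lipid as percent volume fractions.  From the
fitted concentrations the standard composite metrics are derived: total
hemoglobin THb = HbO2 + HHb, oxygen saturation StO2 = HbO2 / THb, and the
tissue optical index TOI = HHb * water / lipid, a malignancy-contrast
composite.

The packaged extinction library is SYNTHETIC: smooth Gaussian/logistic
parameterizations with realistic magnitudes and band positions (HHb band near
757 nm, lipid band near 928 nm, water band near 975 nm, HbO2 rising beyond
800 nm), not digitized literature spectra.  All simulation and recovery in
this package use the same library, so concentrations are internally
consistent; absolute scales need not match any particular clinical
compilation, which is immaterial for percent-change biomarkers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ExtinctionLibrary",
    "ChromophoreState",
    "CHROMOPHORES",
    "synthetic_extinction_spectra",
    "load_extinction_library",
    "unmix",
    "composites",
]

CHROMOPHORES = ("hbo2", "hhb", "water", "lipid")


@dataclass(frozen=True)
class ExtinctionLibrary:
    """Per-chromophore specific-absorption spectra on a common wavelength grid.

    Units: 1/mm per uM for hbo2/hhb; 1/mm per % volume fraction for
    water/lipid.
    """

    wavelengths: np.ndarray  # nm, strictly increasing
    epsilon: np.ndarray  # (n_wavelengths, 4) columns ordered as CHROMOPHORES
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if eps.shape != (wl.size, 4):
            raise ValueError("epsilon must be (n_wavelengths, 4)")
        if np.any(eps < 0) or not np.all(np.isfinite(eps)):
            raise ValueError("extinction spectra must be finite and nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", eps)

    def mua(self, concentrations) -> np.ndarray:
        """Forward Beer's-law absorption spectrum for (hbo2, hhb, water, lipid)."""
        c = np.asarray(concentrations, dtype=float)
        return self.epsilon @ c

    def interp(self, wavelengths) -> "ExtinctionLibrary":
        """Library resampled onto another wavelength grid (linear interpolation)."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < self.wavelengths.min() or wl.max() > self.wavelengths.max():
            raise ValueError("requested grid extends outside library support")
        eps = np.column_stack(
            [np.interp(wl, self.wavelengths, self.epsilon[:, j]) for j in range(4)]
        )
        return ExtinctionLibrary(wl, eps, provenance=self.provenance)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.epsilon))


@dataclass(frozen=True)
class ChromophoreState:
    """Chromophore concentrations and composites at one grid site.

    hbo2/hhb in uM, water/lipid in % volume fraction; thb (uM), sto2
    (fraction) and toi (uM.%/%) are derived and validated against the base
    concentrations on construction.
    """

    hbo2: float
    hhb: float
    water: float
    lipid: float
    thb: float
    sto2: float
    toi: float

    @classmethod
    def from_concentrations(
        cls, hbo2: float, hhb: float, water: float, lipid: float
    ) -> "ChromophoreState":
        thb, sto2, toi = composites(hbo2, hhb, water, lipid)
        return cls(hbo2, hhb, water, lipid, thb, sto2, toi)

    def __post_init__(self) -> None:
        if self.hbo2 < 0 or self.hhb < 0:
            raise ValueError("hemoglobin concentrations must be >= 0")
        if not (0 <= self.water <= 100 and 0 <= self.lipid <= 100):
            raise ValueError("water/lipid must be in [0, 100] %")

    def as_dict(self) -> dict:
        return {
            "hbo2_uM": self.hbo2,
            "hhb_uM": self.hhb,
            "water_pct": self.water,
            "lipid_pct": self.lipid,
            "thb_uM": self.thb,
            "sto2": self.sto2,
            "toi": self.toi,
        }


def composites(hbo2: float, hhb: float, water: float, lipid: float):
    """Composite metrics (THb, StO2, TOI) from base chromophores.

    THb = HbO2 + HHb; StO2 = HbO2/THb (NaN when THb = 0);
    TOI = HHb * water / lipid (NaN when lipid = 0).
    """
    if min(hbo2, hhb, water, lipid) < 0:
        raise ValueError("chromophore concentrations must be >= 0")
    thb = hbo2 + hhb
    sto2 = hbo2 / thb if thb > 0 else math.nan
    toi = hhb * water / lipid if lipid > 0 else math.nan
    return thb, sto2, toi


def synthetic_extinction_spectra(wavelengths) -> np.ndarray:
    """Parametric synthetic extinction spectra (columns: hbo2, hhb, water, lipid).

    Smooth stand-ins with the qualitative features of the near-infrared
    chromophores: HbO2 rising monotonically through the window, HHb with its
    characteristic band near 757 nm over a decaying background, water with
    overtone bands at 740/835 nm and the strong 975 nm band, lipid dominated
    by the 928 nm band.  Magnitudes give typical breast-tissue mua around
    0.005-0.02 /mm for physiological concentrations.
    """
    wl = np.asarray(wavelengths, dtype=float)

    def g(center, width, height):
        return height * np.exp(-(((wl - center) / width) ** 2))

    eps_hbo2 = 6e-5 + 2.3e-4 / (1.0 + np.exp(-(wl - 760.0) / 55.0))
    eps_hhb = 4.5e-4 * np.exp(-(wl - 650.0) / 120.0) + g(757.0, 18.0, 1.8e-4)
    water_pure = 2e-4 + g(740.0, 25.0, 2.5e-3) + g(835.0, 30.0, 4e-3) + g(975.0, 45.0, 4.5e-2)
    lipid_pure = 2e-4 + g(760.0, 20.0, 7e-4) + g(895.0, 40.0, 1.2e-3) + g(928.0, 17.0, 1.06e-2)
    return np.column_stack([eps_hbo2, eps_hhb, water_pure / 100.0, lipid_pure / 100.0])


def load_extinction_library(path=None) -> ExtinctionLibrary:
    """Load an extinction library CSV (wavelength_nm, eps_hbo2, eps_hhb, eps_water, eps_lipid).

    With no path, loads the packaged synthetic library on the native 1-nm
    650-1000 nm grid.
    """
    if path is None:
        ref = resources.files("dosiflare.data") / "synthetic_extinction_library.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
        provenance = "synthetic-gaussian-v1"
    else:
        df = pd.read_csv(path, comment="#")
        provenance = str(path)
    cols = ["eps_hbo2", "eps_hhb", "eps_water", "eps_lipid"]
    return ExtinctionLibrary(
        df["wavelength_nm"].to_numpy(), df[cols].to_numpy(), provenance=provenance
    )


def unmix(
    wavelengths,
    mua_values,
    lib: ExtinctionLibrary,
    nonnegative: bool = True,
):
    """Decompose an absorption spectrum into chromophore concentrations.

    Solves ``mua(lambda) = sum_i eps_i(lambda) c_i`` by least squares over the
    overlap of the spectrum and the library support (at least 50 wavelengths
    required).  Nonnegativity is enforced by default (physical
    concentrations); set ``nonnegative=False`` for an unconstrained
    sensitivity fit.

    Returns
    -------
    state : ChromophoreState
    residual : float
        Euclidean norm of the fit residual over the overlap wavelengths.
    """
    wl = np.asarray(wavelengths, dtype=float)
    mua = np.asarray(mua_values, dtype=float)
    if wl.shape != mua.shape:
        raise ValueError("wavelengths and mua_values must have the same shape")
    ok = (
        np.isfinite(mua)
        & (wl >= lib.wavelengths.min())
        & (wl <= lib.wavelengths.max())
    )
    if ok.sum() < 50:
        raise ValueError(
            f"only {int(ok.sum())} usable wavelengths overlap the library; need >= 50"
        )
    wl, mua = wl[ok], mua[ok]
    design = lib.interp(wl).epsilon
    if np.all(mua == 0):
        c = np.zeros(4)
        resid = 0.0
    elif nonnegative:
        c, resid = nnls(design, mua)
    else:
        c, res, *_ = np.linalg.lstsq(design, mua, rcond=None)
        resid = float(np.sqrt(res[0])) if res.size else float(
            np.linalg.norm(design @ c - mua)
        )
    hbo2, hhb, water, lipid = (float(x) for x in c)
    # clip to physical ranges (no-op for clean nonnegative fits)
    state = ChromophoreState.from_concentrations(
        max(hbo2, 0.0),
        max(hhb, 0.0),
        min(max(water, 0.0), 100.0),
        min(max(lipid, 0.0), 100.0),
    )
    return state, float(resid)
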