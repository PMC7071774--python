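"""Digital phantoms and synthetic longitudinal cohorts.

Two layers of synthesis make every stage of the pipeline testable without
patient data:

* **Phantoms** (:func:`generate_phantom_measurements`): a gridded breast-like
  chromophore field with a Gaussian lesion of elevated HbO2/HHb/water and
  reduced lipid (so the lesion carries tissue-optical-index contrast), pushed
  through the diffusion forward model to per-site frequency-domain sweeps
  (with per-sweep gain, multiplicative amplitude noise and additive phase
  noise) and broadband reflectance spectra (with its own gain and noise).
  Ground-truth maps ride along, so forward -> inverse round trips are exact
  parameter-recovery checks.

* **Cohorts** (:func:`generate_cohort`): tumors assigned to the two regimen
  arms (maximum tolerated dose, MTD n=35 with 25 responders; metronomic,
  MET n=19 with 10 responders) with covariates drawn to match the published
  cohort characteristics.  Each tumor gets a day 0-7 oxyhemoglobin
  percent-change trajectory: group day-1 means +40% (MTD responders), -13%
  (MTD non-responders), +3% (MET responders), -1% (MET non-responders), with
  the responder flare decaying linearly back to baseline by day 7 and
  non-responder trajectories flat.  Between-tumor and within-tumor variance
  are split by an exchangeable intraclass correlation so the GEE's working
  correlation is the generating truth.  Visits after baseline are missing
  independently with fixed probability, giving the unbalanced panels the
  GEE is built for.  Fast mode emits biomarker tables directly; full mode
  emits per-visit phantom measurements whose lesion HbO2 follows the
  trajectory, for end-to-end measurement-level recovery.

All randomness flows from a single seeded :class:`numpy.random.Generator`;
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromophores import (
    CHROMOPHORES,
    ChromophoreState,
    ExtinctionLibrary,
    load_extinction_library,
)
from .mapping import ChromophoreMap, MeasurementGrid
from .photon import FDDatum, OpticalProperties, ProbeGeometry, fd_reflectance
from .photon import _cw_reflectance_grid
from .recovery import LaserSet, ScatterModel

__all__ = [
    "PhantomSpec",
    "TrajectorySpec",
    "CohortSpec",
    "SiteMeasurement",
    "PhantomMeasurements",
    "DEFAULT_TRAJECTORIES",
    "default_trajectories",
    "generate_phantom_measurements",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Digital-phantom description: tissue field, lesion, instrument noise.

    Background means/SDs are typical healthy-breast values (HbO2 20 uM,
    HHb 8 uM, water 30%, lipid 60%); lesion contrast multipliers give the
    malignant TOI contrast (HHb x3, water x1.5, lipid x0.7, HbO2 x2).
    Noise defaults: 1% multiplicative amplitude noise, 0.2 deg additive
    phase noise, 1% broadband reflectance noise.
    """

    nx: int = 9
    ny: int = 7
    spacing: float = 1.0
    background_mean: dict = field(
        default_factory=lambda: {"hbo2": 20.0, "hhb": 8.0, "water": 30.0, "lipid": 60.0}
    )
    background_sd: dict = field(
        default_factory=lambda: {"hbo2": 1.0, "hhb": 0.4, "water": 1.5, "lipid": 3.0}
    )
    lesion_center: tuple = (4, 3)
    lesion_diameter_cm: float = 3.5
    lesion_contrast: dict = field(
        default_factory=lambda: {"hbo2": 2.0, "hhb": 3.0, "water": 1.5, "lipid": 0.7}
    )
    amplitude_noise_rel: float = 0.01
    phase_noise_deg: float = 0.2
    broadband_noise_rel: float = 0.01
    geom: ProbeGeometry = field(default_factory=ProbeGeometry)
    lasers: LaserSet = field(default_factory=LaserSet)
    frequencies: tuple = field(default_factory=lambda: tuple(np.linspace(50.0, 400.0, 15)))
    scatter: ScatterModel = field(default_factory=lambda: ScatterModel(a=0.95, b=0.8))
    broadband_step_nm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        cx, cy = self.lesion_center
        if not (0 <= cx < self.nx and 0 <= cy < self.ny):
            raise ValueError("lesion center must lie inside the grid")
        if min(self.amplitude_noise_rel, self.phase_noise_deg, self.broadband_noise_rel) < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def grid(self) -> MeasurementGrid:
        return MeasurementGrid.rectangular(self.nx, self.ny, self.spacing)


@dataclass(frozen=True)
class SiteMeasurement:
    """What the instrument records at one grid site."""

    fd_sweeps: dict  # laser wavelength (nm) -> tuple[FDDatum]
    broadband_wavelengths: np.ndarray  # nm
    broadband_reflectance: np.ndarray  # arbitrary units


@dataclass(frozen=True)
class PhantomMeasurements:
    """One simulated visit: per-site measurements plus the generating truth."""

    spec: PhantomSpec
    sites: dict  # (x, y) -> SiteMeasurement
    truth: ChromophoreMap
    visit_day: int = 0


def _lesion_multiplier(spec: PhantomSpec, x: int, y: int) -> float:
    """Gaussian lesion profile weight in [0, 1]; FWHM = lesion diameter."""
    cx, cy = spec.lesion_center
    r2 = ((x - cx) ** 2 + (y - cy) ** 2) * spec.spacing**2
    sigma = spec.lesion_diameter_cm / 2.355  # FWHM -> sigma
    return float(np.exp(-r2 / (2.0 * sigma**2)))


def draw_background(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """One realization of the tissue background: (x, y) -> {chromophore: value}.

    A breast's tissue composition persists across visits, so the background
    is drawn once per tumor and shared by all its visit simulations; only
    measurement noise and the programmed trajectory change between visits.
    """
    return {
        pt: {
            c: max(spec.background_mean[c] + rng.normal(0.0, spec.background_sd[c]), 0.5)
            for c in CHROMOPHORES
        }
        for pt in spec.grid.points
    }


def _truth_field(
    spec: PhantomSpec, background: dict, chromophore_scale: dict | None = None
) -> dict:
    """Ground-truth ChromophoreState per grid point.

    ``chromophore_scale`` applies a uniform multiplicative factor to selected
    chromophore fields for this visit; longitudinal trajectories scale HbO2
    this way, so the programmed factor is exactly the truth of the ROI-mean
    percent-change biomarker while the static lesion contrast pattern is
    unchanged.
    """
    chromophore_scale = chromophore_scale or {}
    states = {}
    for x, y in spec.grid.points:
        w = _lesion_multiplier(spec, x, y)
        conc = {}
        for c in CHROMOPHORES:
            k = spec.lesion_contrast[c]
            conc[c] = (
                background[(x, y)][c]
                * (1.0 + (k - 1.0) * w)
                * chromophore_scale.get(c, 1.0)
            )
        conc["water"] = min(conc["water"], 100.0)
        conc["lipid"] = min(conc["lipid"], 100.0)
        states[(x, y)] = ChromophoreState.from_concentrations(**conc)
    return states


def generate_phantom_measurements(
    spec: PhantomSpec,
    lib: ExtinctionLibrary | None = None,
    rng: np.random.Generator | None = None,
    chromophore_scale: dict | None = None,
    visit_day: int = 0,
    background: dict | None = None,
) -> PhantomMeasurements:
    """Forward-simulate one visit of grid measurements from a phantom spec.

    Per site: truth chromophores -> mua(lambda) via the extinction library
    and musp(lambda) via the scattering power law -> frequency-domain sweeps
    at the laser wavelengths and a broadband CW reflectance spectrum, each
    with its own random instrumental gain (log-uniform in [0.5, 2]) plus the
    spec's noise.  Deterministic for a fixed generator state.
    """
    lib = lib or load_extinction_library()
    rng = rng or np.random.default_rng(spec.seed)
    wl_bb = np.arange(650.0, 1000.0 + 1e-9, spec.broadband_step_nm)
    lib_bb = lib.interp(wl_bb)
    musp_bb = spec.scatter.musp(wl_bb)
    freqs = np.asarray(spec.frequencies, dtype=float)
    if background is None:
        background = draw_background(spec, rng)
    truth = _truth_field(spec, background, chromophore_scale)

    sites = {}
    for pt, state in truth.items():
        conc = np.array([state.hbo2, state.hhb, state.water, state.lipid])
        mua_bb = lib_bb.mua(conc)
        sweeps = {}
        for lam in spec.lasers.wavelengths:
            mua = float(np.interp(lam, wl_bb, mua_bb))
            musp = float(spec.scatter.musp(lam))
            model = fd_reflectance(OpticalProperties(mua, musp), spec.geom, freqs)
            gain = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
            amp = gain * np.abs(model) * (
                1.0 + rng.normal(0.0, spec.amplitude_noise_rel, freqs.size)
            )
            ph = np.angle(model) + rng.normal(
                0.0, np.deg2rad(spec.phase_noise_deg), freqs.size
            )
            sweeps[lam] = tuple(
                FDDatum(float(f), float(a), float(p)) for f, a, p in zip(freqs, amp, ph)
            )
        r_bb = _cw_reflectance_grid(mua_bb, musp_bb, spec.geom)
        gain_bb = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        r_meas = gain_bb * r_bb * (1.0 + rng.normal(0.0, spec.broadband_noise_rel, wl_bb.size))
        sites[pt] = SiteMeasurement(
            fd_sweeps=sweeps,
            broadband_wavelengths=wl_bb.copy(),
            broadband_reflectance=np.maximum(r_meas, 1e-12),
        )
    truth_map = ChromophoreMap(grid=spec.grid, states=truth, visit_day=visit_day)
    return PhantomMeasurements(spec=spec, sites=sites, truth=truth_map, visit_day=visit_day)


@dataclass(frozen=True)
class TrajectorySpec:
    """Oxyhemoglobin percent-change trajectory for one arm/response group.

    ``day1_mean_pct`` is the group's mean day-1 change; responder flares
    decay linearly to 0 by day 7, non-responder means stay flat (override
    with ``per_day_means``).  ``between_sd_pct`` is the total SD of the
    day-1 change across tumors; ``icc`` splits it into a tumor-level random
    intercept and visit-level noise (exchangeable correlation).
    """

    arm: str  # "MTD" | "MET"
    response: str  # "responder" | "non-responder"
    day1_mean_pct: float
    between_sd_pct: float
    icc: float = 0.5
    missing_prob: float = 0.5
    per_day_means: dict | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("MTD", "MET"):
            raise ValueError("arm must be MTD or MET")
        if self.response not in ("responder", "non-responder"):
            raise ValueError("response must be responder or non-responder")
        if not 0 <= self.icc <= 1 or self.between_sd_pct < 0:
            raise ValueError("need icc in [0,1] and between_sd_pct >= 0")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")

    def mean(self, day: int) -> float:
        if day == 0:
            return 0.0
        if self.per_day_means is not None:
            return float(self.per_day_means.get(day, 0.0))
        if self.response == "responder":
            return self.day1_mean_pct * max(7 - day, 0) / 6.0  # linear decay to day 7
        return self.day1_mean_pct


def default_trajectories() -> dict:
    """Published day-1 group means with documented-assumption dispersions.

    Day-1 means: MTD responders +40%, MTD non-responders -13%, MET
    responders +3%, MET non-responders -1%.  The between-tumor SDs (25% MTD,
    10% MET) are free parameters chosen to be consistent with the published
    standard-error bars at the printed group sizes, not published values.
    """
    return {
        ("MTD", True): TrajectorySpec("MTD", "responder", 40.0, 25.0),
        ("MTD", False): TrajectorySpec("MTD", "non-responder", -13.0, 25.0),
        ("MET", True): TrajectorySpec("MET", "responder", 3.0, 10.0),
        ("MET", False): TrajectorySpec("MET", "non-responder", -1.0, 10.0),
    }


DEFAULT_TRAJECTORIES = default_trajectories()


@dataclass(frozen=True)
class CohortSpec:
    """Arm sizes, response mix and covariate generators for a synthetic cohort.

    Defaults reproduce the published cohort: MTD n=35 (10 pCR, 15 PR, 10 NR),
    MET n=19 (5 pCR, 5 PR, 9 NR); ages normal per arm (51.3 +/- 11.1 and
    47.4 +/- 10.8 years, clipped to the published 26-71 range), tumor sizes
    3.8 +/- 1.9 and 3.0 +/- 1.3 cm (clipped to >= 1 cm), institution,
    hormone-receptor and HER2 frequencies from the cohort table.
    """

    n_mtd: int = 35
    n_met: int = 19
    mtd_response_counts: tuple = (10, 15, 10)  # (pCR, PR, NR)
    met_response_counts: tuple = (5, 5, 9)
    age_mean_sd: dict = field(
        default_factory=lambda: {"MTD": (51.3, 11.1), "MET": (47.4, 10.8)}
    )
    tumor_size_mean_sd: dict = field(
        default_factory=lambda: {"MTD": (3.8, 1.9), "MET": (3.0, 1.3)}
    )
    p_bmc: dict = field(default_factory=lambda: {"MTD": 6 / 35, "MET": 0.0})
    p_hr_pos: float = 0.65
    p_her2_pos: float = 0.28
    days: tuple = (0, 1, 2, 3, 4, 5, 6, 7)

    def __post_init__(self) -> None:
        if sum(self.mtd_response_counts) != self.n_mtd:
            raise ValueError("MTD response counts must sum to the MTD arm size")
        if sum(self.met_response_counts) != self.n_met:
            raise ValueError("MET response counts must sum to the MET arm size")


def _assign_tumors(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for arm, counts in (("MTD", spec.mtd_response_counts), ("MET", spec.met_response_counts)):
        labels = ["pCR"] * counts[0] + ["PR"] * counts[1] + ["NR"] * counts[2]
        rng.shuffle(labels)
        mu_a, sd_a = spec.age_mean_sd[arm]
        mu_t, sd_t = spec.tumor_size_mean_sd[arm]
        for lab in labels:
            idx += 1
            rows.append(
                {
                    "tumor_id": f"T{idx:03d}",
                    "subject_id": f"S{idx:03d}",
                    "regimen": arm,
                    "response3": lab,
                    "responder": lab in ("pCR", "PR"),
                    "age": float(np.clip(rng.normal(mu_a, sd_a), 26, 71)),
                    "tumor_size_cm": float(np.clip(rng.normal(mu_t, sd_t), 1.0, 8.0)),
                    "institution": int(rng.random() < spec.p_bmc[arm]),
                    "hr_status": int(rng.random() < spec.p_hr_pos),
                    "her2_status": int(rng.random() < spec.p_her2_pos),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec | None = None,
    trajectories: dict | None = None,
    seed: int = 0,
    mode: str = "fast",
    phantom: PhantomSpec | None = None,
):
    """Simulate a longitudinal cohort.

    Fast mode returns a tidy biomarker table (one row per tumor-day) with
    columns tumor_id, subject_id, regimen, response3, responder, day,
    hbo2_pct, hhb_pct, water_pct_chg, lipid_pct_chg and the covariates —
    the format the cohort statistics consume.  Full mode additionally
    returns, per tumor, the per-visit phantom measurements whose lesion
    HbO2 follows the tumor's true trajectory, as
    ``{tumor_id: {day: PhantomMeasurements}}``; the returned table then
    holds the true (noise-free at biomarker level) percent changes for
    comparison with measurement-level recovery.

    Baseline visits are never missing; later visits are dropped
    independently with each group's ``missing_prob``.
    """
    spec = spec or CohortSpec()
    trajectories = trajectories or default_trajectories()
    if mode not in ("fast", "full"):
        raise ValueError("mode must be 'fast' or 'full'")
    rng = np.random.default_rng(seed)
    tumors = _assign_tumors(spec, rng)

    rows = []
    true_day1 = {}
    per_tumor_days = {}
    for _, t in tumors.iterrows():
        traj = trajectories[(t.regimen, bool(t.responder))]
        sd_b = traj.between_sd_pct * np.sqrt(traj.icc)
        sd_w = traj.between_sd_pct * np.sqrt(1.0 - traj.icc)
        u = rng.normal(0.0, sd_b)
        # secondary chromophores: no systematic change, modest noise
        u2 = rng.normal(0.0, 5.0, size=3)
        days = [0] + [
            d for d in spec.days[1:] if rng.random() >= traj.missing_prob
        ]
        per_tumor_days[t.tumor_id] = days
        for d in days:
            if d == 0:
                hbo2 = hhb = water = lipid = 0.0
            else:
                hbo2 = traj.mean(d) + u + rng.normal(0.0, sd_w)
                hhb, water, lipid = u2 + rng.normal(0.0, 5.0, size=3)
            if d == 1:
                true_day1[t.tumor_id] = hbo2
            rows.append(
                {
                    **t.to_dict(),
                    "day": d,
                    "hbo2_pct": hbo2,
                    "hhb_pct": hhb,
                    "water_pct_chg": water,
                    "lipid_pct_chg": lipid,
                }
            )
    table = pd.DataFrame(rows)
    if mode == "fast":
        return table

    phantom = phantom or PhantomSpec()
    measurements = {}
    for _, t in tumors.iterrows():
        per_visit = {}
        tumor_rows = table[table.tumor_id == t.tumor_id]
        background = draw_background(phantom, rng)  # one tissue per tumor
        for d in per_tumor_days[t.tumor_id]:
            pct = float(tumor_rows.loc[tumor_rows.day == d, "hbo2_pct"].iloc[0])
            scale = max(1.0 + pct / 100.0, 0.05)
            per_visit[d] = generate_phantom_measurements(
                phantom,
                rng=rng,
                chromophore_scale={"hbo2": scale},
                visit_day=d,
                background=background,
            )
        measurements[t.tumor_id] = per_visit
    return table, measurements
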