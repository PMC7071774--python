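"""End-to-end orchestration: simulate -> recover -> unmix -> map -> analyze.

The measurement-level processing chain, site by site:

1. fit (mua, musp) at each laser wavelength from its frequency-domain sweep;
2. fit the scattering power law through the per-wavelength musp estimates;
3. calibrate the broadband reflectance against the model-predicted CW
   reflectance at the laser anchors and invert it for broadband mua;
4. unmix the mua spectrum into HbO2/HHb/water/lipid and the composites.

Visit maps feed ROI selection and registration, ROI means feed
percent-change series, and the cohort table feeds the GEE / LDA analysis.
:func:`run_pipeline` wires the stages behind a :class:`RunConfig` that
round-trips losslessly through YAML; every artifact records the config hash
and the seed, and reruns with the same seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .chromophores import ExtinctionLibrary, load_extinction_library, unmix
from .cohort import fit_cohort_model
from .gee import bonferroni_level
from .mapping import (
    ChromophoreMap,
    LongitudinalRecord,
    percent_change,
    register_roi_shift,
    select_tumor_roi,
    tumor_mean,
)
from .photon import OpticalProperties, ProbeGeometry
from .recovery import fit_fd_properties, fit_scatter_power, recover_broadband_mua
from .stats import crossval_roc, two_proportion_ztest
from .synthetic import CohortSpec, PhantomSpec, SiteMeasurement, generate_cohort

logger = logging.getLogger("dosiflare")

__all__ = [
    "RunConfig",
    "process_site",
    "process_visit",
    "build_longitudinal_record",
    "analyze_cohort",
    "run_pipeline",
]


def process_site(
    site: SiteMeasurement,
    geom: ProbeGeometry,
    lib: ExtinctionLibrary | None = None,
    init: OpticalProperties | None = None,
):
    """Full single-site inversion: sweeps + broadband -> ChromophoreState.

    Returns (state, diagnostics) where diagnostics carries the per-wavelength
    FD fits, the scattering power law, the broadband calibration gain and the
    unmixing residual.
    """
    lib = lib or load_extinction_library()
    fd_fits = {
        lam: fit_fd_properties(sweep, geom, init=init)
        for lam, sweep in sorted(site.fd_sweeps.items())
    }
    lams = np.array(sorted(fd_fits))
    scatter = fit_scatter_power(lams, [fd_fits[l].props.musp for l in lams])
    anchors = [fd_fits[l].props for l in lams]
    mua_bb, gain = recover_broadband_mua(
        site.broadband_wavelengths,
        site.broadband_reflectance,
        scatter,
        geom,
        lams,
        anchors,
    )
    ok = np.isfinite(mua_bb)
    state, resid = unmix(site.broadband_wavelengths[ok], mua_bb[ok], lib)
    diagnostics = {
        "fd_fits": fd_fits,
        "scatter": scatter,
        "broadband_gain": gain,
        "n_inverted": int(ok.sum()),
        "unmix_residual": resid,
    }
    return state, diagnostics


def process_visit(grid, sites: dict, visit_day: int, geom: ProbeGeometry,
                  lib: ExtinctionLibrary | None = None) -> ChromophoreMap:
    """Process every site of one visit into a chromophore map."""
    lib = lib or load_extinction_library()
    states = {}
    for pt, site in sites.items():
        state, diag = process_site(site, geom, lib)
        if diag["n_inverted"] >= 50:
            states[pt] = state  # sites failing broadband inversion stay missing
    return ChromophoreMap(grid=grid, states=states, visit_day=visit_day)


def build_longitudinal_record(
    tumor_id: str,
    maps_by_day: dict,
    tumor_size_cm: float,
    regimen: str,
    response3: str,
    responder: bool,
    covariates: dict | None = None,
    max_shift: int = 1,
) -> LongitudinalRecord:
    """ROI selection, registration, tumor means and percent change for one tumor."""
    if 0 not in maps_by_day:
        raise ValueError("baseline (day 0) map is required")
    roi = select_tumor_roi(maps_by_day[0], tumor_size_cm)
    means = {}
    for day in sorted(maps_by_day):
        cmap = maps_by_day[day]
        r = roi if day == 0 else register_roi_shift(roi, cmap, max_shift=max_shift)
        assert len(r.members) <= len(roi.members)
        means[day] = tumor_mean(cmap, r)
    return LongitudinalRecord.from_tumor_means(
        tumor_id, regimen, response3, responder, means, covariates
    )


def analyze_cohort(table: pd.DataFrame, seed: int = 0, roc_folds: int = 5) -> dict:
    """Cohort statistics on a tidy biomarker table.

    Fits the three stratification GEE models for day-wise oxyhemoglobin
    percent change (MTD response, MET response, responders MTD-vs-MET), runs
    the per-day post hoc contrasts at the Bonferroni level, and evaluates
    day-1 oxyhemoglobin as a cross-validated LDA classifier of pathologic
    response within each arm.
    """
    results: dict = {"models": {}, "roc": {}}
    mtd = table[table.regimen == "MTD"]
    met = table[table.regimen == "MET"]
    resp = table[table.responder].copy()
    resp["is_mtd"] = (resp.regimen == "MTD").astype(int)

    strata = {
        "mtd_response": (mtd.assign(responder=mtd.responder.astype(int)), "responder"),
        "met_response": (met.assign(responder=met.responder.astype(int)), "responder"),
        "responders_regimen": (resp, "is_mtd"),
    }
    for name, (df, group) in strata.items():
        try:
            model = fit_cohort_model(df, group)
        except ValueError as exc:  # e.g. a tiny cohort with an empty cell
            logger.warning("GEE model %s not fit: %s", name, exc)
            continue
        results["models"][name] = model

    for arm, df in (("MTD", mtd), ("MET", met)):
        d1 = df[(df.day == 1) & np.isfinite(df.hbo2_pct)]
        labels = d1.responder.astype(int).to_numpy()
        n1, n0 = int(labels.sum()), int(len(labels) - labels.sum())
        k = min(roc_folds, n1, n0)
        # every training fold must keep >= 2 samples per class
        feasible = k >= 2 and all(n - -(-n // k) >= 2 for n in (n1, n0))
        if feasible:
            results["roc"][arm] = crossval_roc(
                d1.hbo2_pct.to_numpy(), labels, k=k, seed=seed
            )
        else:
            logger.warning("ROC for %s skipped: day-1 classes too small", arm)

    n_mtd = table[table.regimen == "MTD"].tumor_id.nunique()
    n_met = table[table.regimen == "MET"].tumor_id.nunique()
    r_mtd = table[table.regimen == "MTD"].groupby("tumor_id").responder.first().sum()
    r_met = table[table.regimen == "MET"].groupby("tumor_id").responder.first().sum()
    results["responder_proportions"] = {
        "mtd": (int(r_mtd), int(n_mtd)),
        "met": (int(r_met), int(n_met)),
        "p_ztest": two_proportion_ztest(int(r_mtd), n_mtd, int(r_met), n_met),
    }
    results["bonferroni"] = {
        "chromophore_models": bonferroni_level(0.05, 4),
        "posthoc_contrasts": bonferroni_level(0.05, 14),
    }
    return results


@dataclass
class RunConfig:
    """Pipeline run configuration; round-trips losslessly through YAML."""

    out_dir: str = "dosiflare_run"
    seed: int = 0
    stages: tuple = ("simulate", "analyze", "report")
    mode: str = "fast"  # "fast" = biomarker-level, "full" = measurement-level
    n_mtd: int = 35
    n_met: int = 19
    phantom_nx: int = 9
    phantom_ny: int = 7
    log_level: str = "INFO"
    manifest: str | None = None  # external cohort table CSV for processing

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _model_summary(model) -> dict:
    return {
        "alpha": model.fit.alpha,
        "phi": model.fit.phi,
        "n_clusters": model.fit.n_clusters,
        "converged": model.fit.converged,
        "day_contrasts": {
            str(day): {
                "estimate": float(r.estimate),
                "se": float(r.se),
                "p": float(r.p),
                "significant": bool(r.significant),
            }
            for day, r in model.contrasts.iterrows()
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write artifacts under ``out_dir``.

    Returns the summary dictionary that is also written to
    ``summary.json``.  Idempotent for a fixed seed and config.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.hash(), "seed": config.seed}
    table = None

    if "simulate" in config.stages:
        logger.info("stage simulate: cohort n_mtd=%d n_met=%d mode=%s",
                    config.n_mtd, config.n_met, config.mode)
        cohort = _scaled_cohort_spec(config)
        if config.mode == "fast":
            table = generate_cohort(cohort, seed=config.seed, mode="fast")
        else:
            phantom = PhantomSpec(nx=config.phantom_nx, ny=config.phantom_ny)
            truth_table, measurements = generate_cohort(
                cohort, seed=config.seed, mode="full", phantom=phantom
            )
            truth_table.to_csv(out / "cohort_truth.csv", index=False)
            table = _process_full_cohort(truth_table, measurements, phantom)
        table.to_csv(out / "cohort_table.csv", index=False)
    elif config.manifest:
        table = pd.read_csv(config.manifest)
    if table is None and ("analyze" in config.stages or "report" in config.stages):
        raise FileNotFoundError(
            "no cohort table: enable the simulate stage or pass a manifest path"
        )

    if "analyze" in config.stages:
        logger.info("stage analyze: %d rows, %d tumors", len(table), table.tumor_id.nunique())
        results = analyze_cohort(table, seed=config.seed)
        for name, model in results["models"].items():
            model.contrasts.to_csv(out / f"contrasts_{name}.csv")
            model.fit.params.rename("beta").to_frame().assign(
                se=model.fit.bse()
            ).to_csv(out / f"coefficients_{name}.csv")
        for arm, roc in results["roc"].items():
            pd.DataFrame(
                {"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                 "specificity": roc.specificity}
            ).to_csv(out / f"roc_{arm.lower()}.csv", index=False)
        summary["models"] = {
            name: _model_summary(m) for name, m in results["models"].items()
        }
        summary["roc"] = {
            arm: {"auc": roc.auc, **roc.optimal} for arm, roc in results["roc"].items()
        }
        summary["responder_proportions"] = results["responder_proportions"]
        summary["bonferroni"] = results["bonferroni"]

    if "report" in config.stages:
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        logger.info("wrote %s", out / "summary.json")
    return summary


def _scaled_cohort_spec(config: RunConfig) -> CohortSpec:
    """CohortSpec with arm sizes from the config, response mix scaled to match."""
    def scale(counts, n):
        total = sum(counts)
        raw = [round(c * n / total) for c in counts]
        raw[-1] += n - sum(raw)
        return tuple(raw)

    mtd = scale((10, 15, 10), config.n_mtd)
    met = scale((5, 5, 9), config.n_met)
    return CohortSpec(
        n_mtd=config.n_mtd, n_met=config.n_met,
        mtd_response_counts=mtd, met_response_counts=met,
    )


def _process_full_cohort(truth_table, measurements, phantom: PhantomSpec):
    """Measurement-level processing of a full-mode cohort into a biomarker table."""
    lib = load_extinction_library()
    tumor_info = truth_table.groupby("tumor_id").first()
    rows = []
    for tumor_id, per_visit in measurements.items():
        info = tumor_info.loc[tumor_id]
        maps = {
            day: process_visit(m.spec.grid, m.sites, day, m.spec.geom, lib)
            for day, m in per_visit.items()
        }
        rec = build_longitudinal_record(
            tumor_id, maps, float(info.tumor_size_cm), info.regimen,
            info.response3, bool(info.responder),
        )
        for day in sorted(rec.tumor_means):
            rows.append(
                {
                    "tumor_id": tumor_id,
                    "subject_id": info.subject_id,
                    "regimen": info.regimen,
                    "response3": info.response3,
                    "responder": bool(info.responder),
                    "age": float(info.age),
                    "tumor_size_cm": float(info.tumor_size_cm),
                    "institution": int(info.institution),
                    "hr_status": int(info.hr_status),
                    "her2_status": int(info.her2_status),
                    "day": day,
                    "hbo2_pct": rec.pct_change.loc[day, "hbo2"],
                    "hhb_pct": rec.pct_change.loc[day, "hhb"],
                    "water_pct_chg": rec.pct_change.loc[day, "water"],
                    "lipid_pct_chg": rec.pct_change.loc[day, "lipid"],
                }
            )
    return pd.DataFrame(rows)
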