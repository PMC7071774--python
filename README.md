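# dosiflare

Frequency-domain diffuse optical spectroscopic imaging (DOSI) analysis for
monitoring breast-tumor response to neoadjuvant chemotherapy — from raw
amplitude/phase modulation sweeps to chromophore maps, tumor-ROI
longitudinal biomarkers, and regimen-stratified prognostic statistics.

DOSI measures deep-tissue near-infrared (650–1000 nm) absorption and
scattering with a handheld probe, yielding absolute concentrations of
oxyhemoglobin (HbO₂, µM), deoxyhemoglobin (HHb, µM), water and lipid (%)
plus the composites THb = HbO₂ + HHb, StO₂ = HbO₂/THb and the tissue
optical index TOI = HHb · water / lipid. Tumors that respond to
maximum-tolerated-dose (MTD) chemotherapy show an **oxyhemoglobin flare** —
a transient HbO₂ rise peaking ~1 day after the first infusion — that is
absent under metronomic (MET) dosing, making the day-1 HbO₂ percent change
a regimen-dependent early response marker. This package is for researchers
who want that full computational chain as tested, reusable Python, with a
digital-phantom generator standing in for (non-public) patient data.

## What it implements

1. **Photon model** — P1 diffusion approximation for a semi-infinite
   medium, extrapolated-boundary image-source solution in the frequency
   domain; `R_eff` from Fresnel integrals.
2. **Property recovery** — per-wavelength (µa, µs′) from 50–400 MHz
   amplitude/phase sweeps (gain-nuisance profiled out), scattering power law
   µs′(λ) = A(λ/800)⁻ᵇ, and broadband µa(λ) from anchor-calibrated
   broadband reflectance by monotone 1-D inversion.
3. **Chromophores** — nonnegative Beer's-law unmixing against a packaged
   (synthetic, internally consistent) extinction library; composites.
4. **Tumor mapping** — 1-cm measurement grids, ROI at peak TOI with extent
   from clinical tumor size, bounded lateral re-registration across visits,
   ROI-mean biomarkers and percent change from baseline.
5. **Cohort statistics** — pCR/PR/NR response rules; identity-link normal
   GEE with exchangeable working correlation and sandwich inference,
   hand-implemented; per-day Bonferroni-corrected post hoc contrasts; LDA
   with cross-validated ROC/AUC; rank-sum and two-proportion tests.
6. **Synthetic cohorts** — digital phantoms and longitudinal cohorts
   matching the published study design (MTD n=35 / MET n=19; day-1 means
   +40 / −13 / +3 / −1 %), in fast (biomarker-level) and full
   (measurement-level) modes.
7. **Pipeline + CLI** — `run_pipeline(RunConfig)` and a thin `dosiflare`
   command (`run`, `simulate`, `analyze`, `init-config`), seed-deterministic
   end to end.

## Worked example

```python
import dosiflare as df
from dosiflare.pipeline import analyze_cohort

table = df.generate_cohort(seed=15, mode="fast")   # 54 simulated tumors
res = analyze_cohort(table, seed=15)

c = res["models"]["mtd_response"].contrasts.loc[1]
print(f"{c.estimate:+.2f} +/- {c.se:.2f} %  (p = {c.p:.2e})")
for arm in ("MTD", "MET"):
    print(arm, f"AUC = {res['roc'][arm].auc:.2f}")
```

prints

```
+52.96 +/- 10.02 %  (p = 1.27e-07)
MTD AUC = 0.89
MET AUC = 0.45
```

The first line is the covariate-adjusted day-1 HbO₂ contrast between MTD
responders and non-responders (the generator programs a 53-point
difference), significant well below the Bonferroni level 0.0036. The AUCs
are 5-fold cross-validated LDA discrimination of pathologic response from
the day-1 HbO₂ change alone: strong under MTD, chance-level under MET —
the flare is regimen-dependent. The `examples/` directory has one short
narrative script per capability (forward model, property recovery,
unmixing, mapping, cohort statistics, orchestrated pipeline).

Shell equivalent:

```bash
dosiflare run --seed 15 --out results/demo
```

## Data formats

Sweeps are CSVs (`frequency_MHz, amplitude, phase_deg`; phase stored in
degrees, radians in memory), broadband spectra are CSVs
(`wavelength_nm, reflectance`), visits are indexed by a `manifest.json`
(subject, visit day, grid coordinates, file paths), chromophore maps are
tidy CSVs (`tumor_id, visit_day, grid_x, grid_y, hbo2_uM, …, toi`), ROIs
are JSON sidecars, and the cohort biomarker table is a tidy CSV with one
row per tumor-day. Grid coordinates are integers, origin top-left, x
rightward, y downward.

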