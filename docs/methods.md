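# Methods

`dosiflare` implements the full analysis chain of frequency-domain diffuse
optical spectroscopic imaging (DOSI) of breast tumors under neoadjuvant
chemotherapy: a photon-diffusion forward model, the inverse recovery of
tissue optical properties, Beer's-law chromophore unmixing, tumor-ROI
mapping of longitudinal percent-change biomarkers, and the cohort-level
inference (GEE, LDA/ROC) used to test whether the day-1 oxyhemoglobin
"flare" predicts pathologic response in a regimen-dependent way. Because no
patient data ship with the package, a digital-phantom and synthetic-cohort
generator provides inputs with known ground truth for every stage.

## Forward model

Light transport is modelled with the P1 (diffusion) approximation for a
semi-infinite homogeneous medium with extrapolated-boundary conditions. For
absorption `mua` and reduced scattering `musp` (both 1/mm), the diffusion
coefficient is `D = 1/(3(mua + musp))` (mm) and the complex wavenumber at
modulation frequency `f` (MHz) is `k = sqrt((mua + i*omega/v)/D)` with
`omega = 2*pi*f` and `v = c0/n_tissue`. A real isotropic source sits one
transport mean free path deep (`z0 = 1/(mua+musp)`); its negative image sits
at `-(z0 + 2*zb)` above the extrapolated boundary `zb = 2D(1+R_eff)/(1-R_eff)`.
The detected quantity is the fluence-rate reflectance at lateral distance
`rho`,

    R(f) = [exp(-k r1)/r1 - exp(-k r2)/r2] / (4 pi D),

with `r1 = sqrt(rho^2 + z0^2)`, `r2 = sqrt(rho^2 + (z0+2 zb)^2)`. Amplitude
is `|R|` (known only up to an instrument gain) and phase is `arg R`
(radians, negative-going with frequency, exactly zero at `f = 0`). A
Fick's-law flux detector model is available behind the `detector="flux"`
flag; the fluence model is the default because the two differ only in a
smooth frequency-independent factor at these geometries and the fit treats
amplitude scale as a nuisance anyway.

`R_eff` is computed from the unpolarized Fresnel reflection moments by
adaptive quadrature, splitting the polar integral at the critical angle (the
kink otherwise limits accuracy); results are cached per index pair. No
polynomial approximation is used. For `n_tissue = 1.4` against air this
gives `R_eff = 0.4935`. Matched indices give `R_eff = 0` and `zb = 2D`.

Defaults: `rho = 28 mm`, `n_tissue = 1.4`, `n_outside = 1.0`, modulation
band 50-400 MHz. The source instrument's exact source-detector separation
and detector model are not fixed by the measurement protocol we emulate;
these defaults are flagged assumptions and are configurable.

## Inverse stage

Per laser wavelength, `(mua, musp)` are recovered by trust-region least
squares (bounded, on `log mua, log musp` so estimates are positive by
construction) over the stacked residual of *relative* amplitude errors and
*absolute* phase errors, equally weighted — amplitude is scale-free once the
per-sweep gain is profiled out in closed form at each iteration, and phase
noise is additive. Cost tolerance 1e-10, at most 500 iterations. If the
first solve ends with a large residual (norm > 0.5, far above the noise
floor), the fit restarts from a coarse 3x3 grid of physiological
initializations and keeps the best optimum; this makes the fit robust to
initializations an order of magnitude off. Non-convergence and bound-pinned
estimates are flagged, not raised.

The scattering spectrum is the power law `musp(lambda) = A (lambda/800)^-b`,
fit by linear least squares in log-log space through the per-wavelength
`musp` estimates (exact interpolation with two wavelengths).

Broadband absorption: the uncalibrated broadband reflectance is rescaled by
the single gain that best matches (least squares) the model-predicted CW
reflectance at the laser anchor wavelengths, then inverted wavelength by
wavelength for `mua` with `musp` fixed from the power law. The CW
reflectance is strictly decreasing in `mua`, so each inversion is a
bracketed 1-D root on (1e-7, 0.2] 1/mm, solved by 60 vectorized bisection
steps (~1e-9 precision); out-of-bracket wavelengths return NaN and are
excluded downstream. Recovery is exactly invariant to any positive gain on
the measured spectrum. The precise broadband-calibration scheme of the
original instrument family is not published; the anchor-gain scheme is this
package's documented stand-in.

## Chromophores

`mua(lambda)` on 650-1000 nm is decomposed as a nonnegative linear
combination of oxyhemoglobin (uM), deoxyhemoglobin (uM), water (% volume
fraction) and lipid (% volume fraction) via active-set NNLS. Nonnegativity
is enforced because concentrations are physical and unconstrained fits go
negative under noise; an unconstrained mode exists for sensitivity analysis.
Composites: `THb = HbO2 + HHb`, `StO2 = HbO2/THb` (NaN at `THb = 0`),
`TOI = HHb * water / lipid` (NaN at zero lipid).

The packaged extinction library is **synthetic**: smooth Gaussian/logistic
parameterizations with realistic magnitudes and band positions (HHb band at
757 nm, lipid at 928 nm, water overtones at 740/835/975 nm, HbO2 rising
through the window), generated by
`chromophores.synthetic_extinction_spectra` and shipped as
`data/synthetic_extinction_library.csv` (condition number ~12 over the
window). Simulation and recovery share the library, so concentrations are
internally consistent; absolute scales need not match any particular
literature compilation, which is immaterial for percent-change biomarkers.

## Tumor mapping

Measurements lie on a hand-drawn rectangular grid with 1-cm spacing; integer
grid coordinates have their origin at the top-left, x rightward, y downward.
The tumor ROI is an axis-aligned rectangle of grid points centred on the
site of peak TOI at baseline (ties to the smallest x, then y), spanning
`ceil(size/spacing)` points per axis from the clinical tumor size, clipped
to the grid. The extent is fixed across a tumor's visits; on follow-ups the
ROI may shift laterally by at most one grid unit (configurable), choosing
the shift that maximizes mean TOI inside the ROI (ties prefer the null
shift). Tumor biomarkers are arithmetic means of the base chromophores over
ROI sites with composites recomputed from the means; the longitudinal
series is the percent change from day 0, `100 (x_d - x_0)/x_0`. Dense map
rasters (bilinear, nearest-neighbour inpainted, clamped to the site range)
exist for display only — no statistic ever uses interpolated values.

## Cohort statistics

*Response rules.* pCR = no residual invasive disease; PR = shrinkage of the
largest dimension by strictly more than 50%; NR otherwise. Exactly 50% is
classified NR (the printed definitions leave the boundary unassigned).
Responder = pCR or PR.

*GEE.* Percent-change outcomes are modelled marginally with identity link,
normal variance, exchangeable working correlation, subjects as clusters:
quasi-scoring beta updates alternate with moment estimates of the
correlation `alpha` and dispersion `phi` from Pearson residuals until the
beta step falls below 1e-8 (max 200 iterations); inference uses the robust
sandwich covariance without small-sample correction. Clusters of size one
reduce the estimator exactly to OLS. Model coding: only post-chemotherapy
days 1-7 enter (the baseline is identically zero by construction); day is
categorical with day 1 as reference; the group factor (response, or regimen
within responders) interacts with day, so the group main effect *is* the
adjusted day-1 contrast; covariates are centred age and 0/1 indicators for
institution, hormone-receptor and HER2 status, with constant columns
dropped. Post hoc per-day contrasts are Wald tests at the Bonferroni level
`0.05/m` (0.0125 for the four chromophore models; 0.0036 for the family of
14 per-day contrasts).

*LDA/ROC.* The classifier for day-1 response is linear discriminant
analysis on the day-1 HbO2 percent change (one feature by default):
equal-covariance Gaussian class densities, pooled covariance with the
unbiased 1/(n-2) convention, empirical priors (no rebalancing — the cohort
imbalance is kept deliberately), posteriors by Bayes' rule. Evaluation is
stratified 5-fold cross-validation (seeded; stratification keeps both
classes in every training fold), pooling out-of-fold posteriors into one
ROC built by sweeping every distinct posterior as threshold; AUC is the
trapezoidal area (and equals the Mann-Whitney statistic exactly). The
"optimal" operating point maximizes Youden's J. Descriptive tests:
two-sided Wilcoxon rank sum (exact for small tie-free samples) and the
pooled two-proportion z-test without continuity correction.

## Synthetic cohorts

The generator encodes the study conditions. Arms: MTD n=35 (10 pCR, 15 PR,
10 NR), MET n=19 (5/5/9); ages N(51.3, 11.1) and N(47.4, 10.8) years
clipped to 26-71; tumor sizes N(3.8, 1.9) and N(3.0, 1.3) cm clipped at
1 cm; institution, hormone-receptor (65%) and HER2 (28%) frequencies from
the published cohort table. Day-1 HbO2 percent-change means: +40% (MTD
responders), -13% (MTD non-responders), +3% (MET responders), -1% (MET
non-responders); responder flares decay linearly to zero by day 7,
non-responder means stay flat. The published report gives only group means
and standard-error bars, so the dispersions are free parameters chosen
once: between-tumor SD 25% (MTD) and 10% (MET), split by an intraclass
correlation of 0.5 into a tumor-level random intercept plus visit noise —
so the GEE's exchangeable working correlation is the generating truth.
Non-baseline visits are missing independently with probability 0.5
(baseline never), giving unbalanced panels.

Digital phantoms map a background breast field (HbO2 20 uM, HHb 8 uM,
water 30%, lipid 60%, with site-to-site SDs of 1.0/0.4/1.5/3.0) with a
Gaussian lesion (FWHM = clinical diameter) carrying contrast multipliers
(HbO2 x2, HHb x3, water x1.5, lipid x0.7 — a TOI-bright lesion) through the
forward chain: extinction library -> mua(lambda), power law (A=0.95,
b=0.8) -> musp(lambda), then frequency sweeps at the four laser wavelengths
and a broadband CW spectrum, each with its own random gain (log-uniform in
[0.5, 2]) plus noise (1% multiplicative amplitude, 0.2 deg additive phase,
1% broadband). The tissue background is drawn once per tumor and shared
across its visits — tissue persists between visits; only the programmed
trajectory and measurement noise change. Trajectories scale the HbO2 field
uniformly for the visit, so the programmed factor is exactly the truth of
the ROI-mean percent-change biomarker while the static lesion pattern that
drives ROI selection is untouched.

What the generator does **not** emulate: real breast anatomy and the
areola's TOI contrast, heterogeneous scattering, chromophore-specific
treatment responses beyond HbO2, instrument drift, grid-placement rotation
(only integer translation), and any pharmacodynamics. Passing tests
therefore demonstrate the correctness and calibration of the *analysis
chain* under its own assumptions, not clinical performance.

## Numerical choices and problem sizes

- Bisection bracket for broadband `mua`: (1e-7, 0.2] 1/mm; 60 iterations.
- FD fit: bounds mua in [1e-5, 0.5], musp in [0.05, 5] 1/mm (log-space).
- GEE convergence 1e-8 on the beta step; LDA ridge 1e-8 of the covariance
  trace only when singular.
- Replicate studies use 100 fast-mode (biomarker-level) cohorts at the
  default 54-tumor design; the measurement-level (full-mode) chain is
  exercised on a scaled-down cohort (13 tumors, days 0-1, 7x5 grid, 2-nm
  broadband step) — the package's chosen balance between coverage and
  simulation size. On that cohort the day-1 recovery error of the ROI-mean
  HbO2 percent change has a per-tumor spread of a few percentage points and
  a small positive bias (~2-4 points), dominated by measurement noise plus
  a selection effect of TOI-maximizing re-registration on noisy maps.
- In a minority of fast-mode replicates the default 50% visit missingness
  leaves fewer than three day-1 MET subjects in a class; cross-validated
  ROC is then undefined for that arm and the replicate is excluded from
  AUC comparisons (logged, never imputed).

## Known limitations

- Homogeneous semi-infinite diffusion only; no layered or tomographic
  models, no instrument-response deconvolution or phantom calibration.
- The synthetic extinction library fixes an internally consistent but
  non-clinical absolute concentration scale.
- GEE robust SEs carry no small-sample correction (a flagged option),
  matching common practice for cohorts of this size.
- The exact-50% shrinkage convention, the ROI rectangle, the registration
  criterion and the Youden-optimal ROC point are documented conventions
  where the emulated protocol is silent.
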