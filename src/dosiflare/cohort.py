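"""Cohort-level longitudinal modelling of percent-change biomarkers.

Builds the regression designs used for the three population stratifications
(MTD responders vs non-responders; MET responders vs non-responders; MTD vs
MET within responders), fits the exchangeable-correlation GEE, and runs the
post hoc per-day adjusted contrasts with Bonferroni control.

Model coding: percent-change outcomes are modelled on post-chemotherapy days
1-7 only — the baseline value is identically zero by construction and
carries no information.  Day enters as categorical indicators with day 1 as
the reference level and the group factor interacts with day, so the group
main effect IS the covariate-adjusted day-1 group contrast and the day-d
contrast adds the corresponding interaction coefficient.  Additional
covariates: centred age and 0/1 indicators for institution, hormone-receptor
and HER2 status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gee import GEEFit, bonferroni_level, contrast, fit_gee

__all__ = ["CohortModel", "build_design", "fit_cohort_model", "posthoc_day_contrasts"]

DEFAULT_COVARIATES = ("age", "institution", "hr_status", "her2_status")


@dataclass
class CohortModel:
    """A fitted stratification model plus its per-day post hoc contrasts."""

    fit: GEEFit
    group: str
    days: tuple
    contrasts: pd.DataFrame  # index day; estimate, se, z, p, significant


def build_design(
    table: pd.DataFrame,
    group: str,
    outcome: str = "hbo2_pct",
    covariates=DEFAULT_COVARIATES,
):
    """Design matrix, outcome and cluster labels for one stratification.

    ``group`` names a 0/1 column of ``table`` (e.g. ``responder`` or an
    ``is_mtd`` indicator).  Only rows with day >= 1 and a finite outcome are
    used.  Returns (X, y, clusters, days_present).
    """
    df = table[(table["day"] >= 1) & np.isfinite(table[outcome])].copy()
    if df.empty:
        raise ValueError("no post-baseline rows with finite outcome")
    days = tuple(sorted(df["day"].unique()))
    ref = days[0]
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for d in days[1:]:
        X[f"day_{d}"] = (df["day"] == d).astype(float)
    g = df[group].astype(float)
    X[group] = g
    for d in days[1:]:
        X[f"{group}:day_{d}"] = g * (df["day"] == d)
    for cov in covariates:
        if cov not in df.columns:
            continue
        v = df[cov].astype(float)
        if v.nunique() <= 1:
            continue  # empty level / constant covariate: drop
        X[cov] = v - v.mean() if cov == "age" else v
    return X, df[outcome].to_numpy(dtype=float), df["subject_id"].to_numpy(), days, ref


def posthoc_day_contrasts(
    fit: GEEFit, group: str, days, ref, level: float | None = None, family_alpha=0.05
) -> pd.DataFrame:
    """Covariate-adjusted group contrast at each post-chemotherapy day.

    The family is the set of per-day contrasts; by default significance is
    declared at the Bonferroni level ``family_alpha / len(days)``.
    """
    if level is None:
        level = bonferroni_level(family_alpha, len(days))
    rows = []
    for d in days:
        w = {group: 1.0}
        if d != ref:
            w[f"{group}:day_{d}"] = 1.0
        c = contrast(fit, w, level=level)
        rows.append(
            {"day": d, "estimate": c.estimate, "se": c.se, "z": c.z, "p": c.p,
             "significant": c.significant}
        )
    return pd.DataFrame(rows).set_index("day")


def fit_cohort_model(
    table: pd.DataFrame,
    group: str,
    outcome: str = "hbo2_pct",
    covariates=DEFAULT_COVARIATES,
    contrast_level: float | None = None,
) -> CohortModel:
    """Fit one stratification's GEE and its per-day post hoc contrasts."""
    X, y, clusters, days, ref = build_design(table, group, outcome, covariates)
    fit = fit_gee(X, y, clusters)
    contrasts = posthoc_day_contrasts(fit, group, days, ref, level=contrast_level)
    return CohortModel(fit=fit, group=group, days=days, contrasts=contrasts)
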