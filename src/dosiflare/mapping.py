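"""Spatial chromophore maps, tumor ROI selection, and longitudinal series.

Measurements are taken on a hand-drawn rectangular grid with 1-cm spacing;
each site carries a :class:`~dosiflare.chromophores.ChromophoreState`.  The
tumor region of interest (ROI) is an axis-aligned rectangle of grid points
centred on the site of peak tissue optical index (TOI) contrast at baseline,
with extent set by the clinically measured tumor size.  The ROI extent is
held constant across visits but may shift laterally (default by at most one
grid unit) to follow grid-placement displacement; the shift maximizing mean
TOI inside the ROI is chosen.  Tumor-level biomarkers are the arithmetic
means of the base chromophores over the ROI, with composites recomputed from
the mean concentrations, and longitudinal series are expressed as percent
change from the baseline visit.

Grid coordinates are integer indices with the origin at the top-left of the
drawn grid, x increasing rightward and y downward.  Interpolated rasters are
cosmetic only — every statistic is computed on native grid sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

from .chromophores import CHROMOPHORES, ChromophoreState

__all__ = [
    "MeasurementGrid",
    "ChromophoreMap",
    "TumorROI",
    "LongitudinalRecord",
    "interpolate_map",
    "select_tumor_roi",
    "register_roi_shift",
    "tumor_mean",
    "percent_change",
]

METRICS = CHROMOPHORES + ("thb", "sto2", "toi")


@dataclass(frozen=True)
class MeasurementGrid:
    """Rectangular measurement grid: 1-cm spacing by default.

    points are unique integer (x, y) coordinates; landmarks (nipple, moles)
    are pass-through metadata used by the clinic for coregistration.
    """

    points: tuple
    spacing: float = 1.0
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("grid spacing must be > 0")
        pts = tuple((int(x), int(y)) for x, y in self.points)
        if len(set(pts)) != len(pts):
            raise ValueError("grid point coordinates must be unique")
        object.__setattr__(self, "points", pts)

    @classmethod
    def rectangular(cls, nx: int, ny: int, spacing: float = 1.0) -> "MeasurementGrid":
        return cls(
            points=tuple((x, y) for y in range(ny) for x in range(nx)),
            spacing=spacing,
        )


@dataclass
class ChromophoreMap:
    """Per-site chromophore states for one breast at one visit.

    ``states`` maps (x, y) -> ChromophoreState; grid points absent from
    ``states`` are explicitly missing sites.
    """

    grid: MeasurementGrid
    states: dict
    visit_day: int = 0

    def __post_init__(self) -> None:
        extra = set(self.states) - set(self.grid.points)
        if extra:
            raise ValueError(f"states at coordinates off the grid: {sorted(extra)}")

    def metric_values(self, metric: str) -> dict:
        """(x, y) -> value of one metric at each non-missing site."""
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}; one of {METRICS}")
        return {pt: getattr(s, metric) for pt, s in self.states.items()}


@dataclass(frozen=True)
class TumorROI:
    """Axis-aligned rectangular tumor ROI on the measurement grid.

    ``half_extent`` = (hx, hy) grid units; the member points are the grid
    points within the rectangle [center - h, center + h] per axis.  The
    extent is fixed for one tumor across all its visits.
    """

    center: tuple
    half_extent: tuple
    members: tuple

    def shifted(self, dx: int, dy: int, grid: MeasurementGrid) -> "TumorROI":
        cx, cy = self.center
        members = tuple(
            (x + dx, y + dy) for (x, y) in self.members if (x + dx, y + dy) in set(grid.points)
        )
        if not members:
            raise ValueError(f"ROI shifted by ({dx}, {dy}) leaves the grid entirely")
        return TumorROI((cx + dx, cy + dy), self.half_extent, members)


@dataclass
class LongitudinalRecord:
    """Per-tumor biomarker series over the first post-chemotherapy week.

    days must include baseline day 0; ``tumor_means`` maps day ->
    ChromophoreState; ``pct_change`` is a DataFrame (index day, columns the
    seven metrics) of percent change from baseline, identically 0 at day 0.
    """

    tumor_id: str
    regimen: str  # "MTD" | "MET"
    response3: str  # "pCR" | "PR" | "NR"
    responder: bool
    tumor_means: dict
    pct_change: pd.DataFrame
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if 0 not in self.tumor_means:
            raise ValueError("baseline (day 0) tumor mean is required")
        if self.regimen not in ("MTD", "MET"):
            raise ValueError(f"regimen must be MTD or MET, got {self.regimen}")

    @classmethod
    def from_tumor_means(
        cls, tumor_id, regimen, response3, responder, tumor_means, covariates=None
    ) -> "LongitudinalRecord":
        days = sorted(tumor_means)
        pct = pd.DataFrame(
            {
                m: percent_change(
                    {d: getattr(tumor_means[d], m) for d in days}
                )
                for m in METRICS
            }
        )
        pct.index.name = "day"
        return cls(
            tumor_id=tumor_id,
            regimen=regimen,
            response3=response3,
            responder=responder,
            tumor_means=tumor_means,
            pct_change=pct,
            covariates=covariates or {},
        )


def interpolate_map(
    cmap: ChromophoreMap, metric: str, resolution: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense raster of one metric for display (bilinear, no overshoot).

    Missing interior sites are inpainted from nearest neighbours before
    gridding.  Returns (X, Y, Z) meshgrid arrays with ``resolution`` raster
    cells per grid unit.  Display only: statistics never touch the raster.
    """
    vals = cmap.metric_values(metric)
    if len(vals) < 4:
        raise ValueError(f"need >= 4 non-missing sites, got {len(vals)}")
    pts = np.array(list(vals), dtype=float)
    z = np.array(list(vals.values()), dtype=float)
    xs = np.array([p[0] for p in cmap.grid.points], dtype=float)
    ys = np.array([p[1] for p in cmap.grid.points], dtype=float)
    nxr = int(round((xs.max() - xs.min()) * resolution)) + 1
    nyr = int(round((ys.max() - ys.min()) * resolution)) + 1
    gx = np.linspace(xs.min(), xs.max(), max(nxr, 2))
    gy = np.linspace(ys.min(), ys.max(), max(nyr, 2))
    X, Y = np.meshgrid(gx, gy)
    Z = griddata(pts, z, (X, Y), method="linear")
    hole = np.isnan(Z)
    if hole.any():  # outside the convex hull of measured sites
        Z[hole] = griddata(pts, z, (X[hole], Y[hole]), method="nearest")
    # bilinear interpolation cannot overshoot, but inpainting guards stay
    np.clip(Z, z.min(), z.max(), out=Z)
    return X, Y, Z


def select_tumor_roi(
    baseline: ChromophoreMap, tumor_size_cm: float
) -> TumorROI:
    """Baseline tumor ROI: peak-TOI site, extent from the clinical tumor size.

    The ROI is centred on the grid point with maximal TOI (ties broken toward
    the smallest x, then y) and spans ``ceil(size / spacing)`` points per
    axis, clipped to the grid.  A tumor no larger than the grid spacing gives
    a single-point ROI.
    """
    if not tumor_size_cm > 0:
        raise ValueError("tumor size must be > 0")
    toi = {
        pt: v for pt, v in baseline.metric_values("toi").items() if np.isfinite(v)
    }
    if not toi:
        raise ValueError("no finite TOI values on the baseline map")
    best = max(toi.values())
    center = min(pt for pt, v in toi.items() if v == best)
    n_pts = math.ceil(tumor_size_cm / baseline.grid.spacing)
    half = (n_pts - 1) // 2  # n_pts points per axis -> offsets -half..half(+1)
    offsets = range(-half, n_pts - half)
    grid_set = set(baseline.grid.points)
    members = tuple(
        (center[0] + dx, center[1] + dy)
        for dy in offsets
        for dx in offsets
        if (center[0] + dx, center[1] + dy) in grid_set
    )
    return TumorROI(center=center, half_extent=(half, half), members=members)


def register_roi_shift(
    roi: TumorROI, followup: ChromophoreMap, max_shift: int = 1
) -> TumorROI:
    """Re-register the ROI on a follow-up visit by a bounded lateral shift.

    Among all integer shifts with |dx|, |dy| <= max_shift, pick the one
    maximizing mean TOI over the shifted ROI (ties broken toward the null
    shift, then smallest |dx|+|dy|, then lexicographic).  The ROI extent is
    unchanged.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if max_shift == 0:
        return roi
    toi = followup.metric_values("toi")
    candidates = []
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            try:
                shifted = roi.shifted(dx, dy, followup.grid)
            except ValueError:
                continue
            vals = [toi[pt] for pt in shifted.members if pt in toi and np.isfinite(toi[pt])]
            if not vals:
                continue
            score = float(np.mean(vals))
            rank = (-score, abs(dx) + abs(dy), dx, dy)
            candidates.append((rank, shifted))
    if not candidates:
        raise ValueError("ROI leaves the grid (or all sites missing) under every shift")
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


def tumor_mean(cmap: ChromophoreMap, roi: TumorROI) -> ChromophoreState:
    """Tumor biomarker: mean base chromophores over the ROI, composites recomputed."""
    states = [cmap.states[pt] for pt in roi.members if pt in cmap.states]
    if not states:
        raise ValueError("ROI contains no non-missing sites")
    means = {c: float(np.mean([getattr(s, c) for s in states])) for c in CHROMOPHORES}
    return ChromophoreState.from_concentrations(**means)


def percent_change(series_by_day: dict) -> dict:
    """Percent change from baseline: 100 (x_d - x_0) / x_0 for each day.

    Baseline (day 0) must be present; a zero or non-finite baseline yields
    NaN for every day, with a warning.  Invariant to the units of the
    underlying metric.
    """
    if 0 not in series_by_day:
        raise ValueError("baseline (day 0) value is required")
    x0 = series_by_day[0]
    if not np.isfinite(x0) or x0 == 0:
        warnings.warn("zero or non-finite baseline: percent change undefined (NaN)")
        return {d: math.nan for d in series_by_day}
    return {d: 100.0 * (x - x0) / x0 for d, x in sorted(series_by_day.items())}
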