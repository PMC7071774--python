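"""File formats exchanged between pipeline stages.

All stages communicate through plain-text artifacts:

* per-site frequency-domain sweep CSVs: ``frequency_MHz, amplitude, phase_deg``
* per-site broadband reflectance CSVs: ``wavelength_nm, reflectance``
* a manifest JSON listing, per measurement site: subject, visit day, grid
  coordinates, and the sweep/broadband file paths (one sweep file per laser
  wavelength)
* tidy chromophore-map CSVs: one row per (tumor, visit, grid site) with the
  four chromophores and three composites
* ROI JSON sidecars and the tidy cohort biomarker table CSV

Phase is stored in degrees on disk and converted to radians at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chromophores import ChromophoreState
from .mapping import ChromophoreMap, MeasurementGrid, TumorROI
from .photon import FDDatum
from .synthetic import PhantomMeasurements, SiteMeasurement

__all__ = [
    "write_sweep_csv",
    "read_sweep_csv",
    "write_broadband_csv",
    "read_broadband_csv",
    "write_measurements",
    "read_measurements",
    "maps_to_frame",
    "frame_to_maps",
    "write_roi_json",
    "read_roi_json",
]

STATE_COLUMNS = ["hbo2_uM", "hhb_uM", "water_pct", "lipid_pct", "thb_uM", "sto2", "toi"]


def write_sweep_csv(path, sweep) -> None:
    rows = [
        {"frequency_MHz": d.frequency, "amplitude": d.amplitude,
         "phase_deg": np.rad2deg(d.phase)}
        for d in sweep
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sweep_csv(path):
    df = pd.read_csv(path)
    return tuple(
        FDDatum(float(r.frequency_MHz), float(r.amplitude), float(np.deg2rad(r.phase_deg)))
        for r in df.itertuples()
    )


def write_broadband_csv(path, wavelengths, reflectance) -> None:
    pd.DataFrame(
        {"wavelength_nm": np.asarray(wavelengths), "reflectance": np.asarray(reflectance)}
    ).to_csv(path, index=False)


def read_broadband_csv(path):
    df = pd.read_csv(path)
    return df["wavelength_nm"].to_numpy(float), df["reflectance"].to_numpy(float)


def write_measurements(
    meas: PhantomMeasurements, out_dir, subject: str = "S001", write_truth: bool = True
) -> Path:
    """Serialize one visit's measurements; returns the manifest path.

    Layout: ``<out_dir>/site_x{X}_y{Y}/sweep_{wavelength}nm.csv`` and
    ``broadband.csv`` per site, indexed by ``manifest.json``.  The generating
    truth map, when present, is stored as a tidy CSV next to the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for (x, y), site in meas.sites.items():
        site_dir = out / f"site_x{x}_y{y}"
        site_dir.mkdir(exist_ok=True)
        sweep_files = {}
        for lam, sweep in site.fd_sweeps.items():
            p = site_dir / f"sweep_{int(round(lam))}nm.csv"
            write_sweep_csv(p, sweep)
            sweep_files[str(lam)] = str(p.relative_to(out))
        bb = site_dir / "broadband.csv"
        write_broadband_csv(bb, site.broadband_wavelengths, site.broadband_reflectance)
        entries.append(
            {
                "subject": subject,
                "visit_day": meas.visit_day,
                "grid_x": x,
                "grid_y": y,
                "sweeps": sweep_files,
                "broadband": str(bb.relative_to(out)),
            }
        )
    manifest = {
        "subject": subject,
        "visit_day": meas.visit_day,
        "grid": {"nx": meas.spec.nx, "ny": meas.spec.ny, "spacing": meas.spec.spacing},
        "sites": entries,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if write_truth and meas.truth is not None:
        maps_to_frame({"truth": {meas.visit_day: meas.truth}}).to_csv(
            out / "truth_map.csv", index=False
        )
    return mpath


def read_measurements(manifest_path) -> tuple[MeasurementGrid, dict, int, str]:
    """Read a visit manifest back: (grid, sites dict, visit_day, subject)."""
    mpath = Path(manifest_path)
    if not mpath.exists():
        raise FileNotFoundError(f"manifest not found: {mpath}")
    manifest = json.loads(mpath.read_text())
    root = mpath.parent
    grid = MeasurementGrid.rectangular(
        manifest["grid"]["nx"], manifest["grid"]["ny"], manifest["grid"]["spacing"]
    )
    sites = {}
    for e in manifest["sites"]:
        sweeps = {
            float(lam): read_sweep_csv(root / rel) for lam, rel in e["sweeps"].items()
        }
        wl, refl = read_broadband_csv(root / e["broadband"])
        sites[(e["grid_x"], e["grid_y"])] = SiteMeasurement(
            fd_sweeps=sweeps, broadband_wavelengths=wl, broadband_reflectance=refl
        )
    return grid, sites, int(manifest["visit_day"]), manifest["subject"]


def maps_to_frame(maps_by_tumor: dict) -> pd.DataFrame:
    """Tidy frame from {tumor_id: {day: ChromophoreMap}}."""
    rows = []
    for tumor_id, by_day in maps_by_tumor.items():
        for day, cmap in by_day.items():
            for (x, y), s in cmap.states.items():
                rows.append(
                    {"tumor_id": tumor_id, "visit_day": day, "grid_x": x, "grid_y": y,
                     **s.as_dict()}
                )
    return pd.DataFrame(rows)


def frame_to_maps(df: pd.DataFrame, spacing: float = 1.0) -> dict:
    """Inverse of :func:`maps_to_frame` (grid inferred from coordinate extents)."""
    out: dict = {}
    for (tumor_id, day), g in df.groupby(["tumor_id", "visit_day"]):
        nx = int(g.grid_x.max()) + 1
        ny = int(g.grid_y.max()) + 1
        grid = MeasurementGrid.rectangular(nx, ny, spacing)
        states = {
            (int(r.grid_x), int(r.grid_y)): ChromophoreState(
                r.hbo2_uM, r.hhb_uM, r.water_pct, r.lipid_pct, r.thb_uM, r.sto2, r.toi
            )
            for r in g.itertuples()
        }
        out.setdefault(tumor_id, {})[int(day)] = ChromophoreMap(
            grid=grid, states=states, visit_day=int(day)
        )
    return out


def write_roi_json(path, roi: TumorROI) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "center": list(roi.center),
                "half_extent": list(roi.half_extent),
                "members": [list(m) for m in roi.members],
            }
        )
    )


def read_roi_json(path) -> TumorROI:
    d = json.loads(Path(path).read_text())
    return TumorROI(
        center=tuple(d["center"]),
        half_extent=tuple(d["half_extent"]),
        members=tuple(tuple(m) for m in d["members"]),
    )
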