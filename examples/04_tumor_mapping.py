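"""From a gridded phantom to a tumor ROI and its longitudinal biomarker.

Simulates baseline and day-1 measurement grids over a lesion whose
oxyhemoglobin rises 40% (an MTD-responder flare), processes every site
through the full inversion chain, selects the tumor ROI by peak tissue
optical index, and prints the ROI-mean percent change.
"""

import numpy as np

import dosiflare as df
from dosiflare.pipeline import process_visit
from dosiflare.synthetic import PhantomSpec, draw_background, generate_phantom_measurements

spec = PhantomSpec(nx=7, ny=5, lesion_center=(3, 2), lesion_diameter_cm=2.5,
                   broadband_step_nm=2.0)
rng = np.random.default_rng(4)
background = draw_background(spec, rng)  # one persistent tissue realization

visits = {}
for day, scale in ((0, 1.0), (1, 1.4)):  # +40% HbO2 flare on day 1
    meas = generate_phantom_measurements(
        spec, rng=rng, background=background,
        chromophore_scale={"hbo2": scale}, visit_day=day,
    )
    visits[day] = process_visit(spec.grid, meas.sites, day, spec.geom)

roi = df.select_tumor_roi(visits[0], tumor_size_cm=2.5)
print(f"ROI centred at grid {roi.center} with {len(roi.members)} sites "
      f"(lesion truly at {spec.lesion_center})")

record = df.build_longitudinal_record(
    "T001", visits, tumor_size_cm=2.5, regimen="MTD", response3="PR", responder=True
)
d1 = record.pct_change.loc[1]
print(f"day-1 ROI-mean changes: HbO2 {d1['hbo2']:+.1f}%  HHb {d1['hhb']:+.1f}%  "
      f"water {d1['water']:+.1f}%  lipid {d1['lipid']:+.1f}%")
# HbO2 should read close to the programmed +40% flare; the other chromophores
# change only by measurement noise.
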