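"""Regimen-stratified cohort inference on a synthetic 54-tumor cohort.

Generates the default longitudinal cohort (35 maximum-tolerated-dose tumors,
19 metronomic), fits the exchangeable-correlation GEE for day-wise
oxyhemoglobin percent change, runs the day-1 post hoc contrast, and
evaluates day-1 oxyhemoglobin as a cross-validated LDA classifier of
pathologic response in each arm.
"""

import dosiflare as df
from dosiflare.pipeline import analyze_cohort

table = df.generate_cohort(seed=15, mode="fast")
res = analyze_cohort(table, seed=15)

c = res["models"]["mtd_response"].contrasts.loc[1]
print("MTD responders vs non-responders, day-1 adjusted HbO2 contrast:")
print(f"  {c.estimate:+.2f} +/- {c.se:.2f} %  (p = {c.p:.2e}, "
      f"Bonferroni level {df.bonferroni_level(0.05, 14):.4f})")
print(f"  working correlation alpha = {res['models']['mtd_response'].fit.alpha:.2f}")
print()
for arm in ("MTD", "MET"):
    roc = res["roc"][arm]
    o = roc.optimal
    print(f"{arm}: day-1 HbO2 cross-validated AUC = {roc.auc:.2f}  "
          f"(sens {o['sensitivity']:.2f}, spec {o['specificity']:.2f}, "
          f"PPV {o['ppv']:.2f}, NPV {o['npv']:.2f})")
print()
p = res["responder_proportions"]
print(f"responder proportions: MTD {p['mtd'][0]}/{p['mtd'][1]}, "
      f"MET {p['met'][0]}/{p['met'][1]}; two-proportion z-test p = {p['p_ztest']:.3f}")
# The flare separates responders only under the MTD regimen: expect a large,
# significant MTD contrast and AUC near 0.9, against a chance-level MET AUC.
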