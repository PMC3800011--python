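"""Per-region GLMs of thickness on the 7 predictors, with FDR across regions.

Simulates a cohort in which higher pain exposure thins ten designated
regions by 0.5 mm per SD, fits one Gaussian identity-link model per region
(robust standard errors) and prints the regions whose pain coefficient
survives 5% FDR, plus the ventilated-subset rerun.
"""

import numpy as np

import corthick as ct
from corthick.glm import fit_all_regions, significant_regions
from corthick.preprocess import transform_predictors
from corthick.regions import REGIONS_66

spec = ct.EffectSpec(
    region_loadings=np.array([[-0.5] * 10 + [0.0] * 56]).T,
    predictor_weights=np.array([[1.0], [0], [0], [0], [0], [0], [0]]),
    noise_sd=0.2)
clinical = ct.generate_clinical_table(ct.CohortParams(n_subjects=400, seed=9))
thickness = ct.generate_thickness_matrix(clinical, spec, seed=9)
design = transform_predictors(clinical)

table = fit_all_regions(thickness, design, q=0.05, se_type="robust")
flagged = significant_regions(table, "pain")
print(f"pain FDR-significant in {len(flagged)}/66 regions "
      f"(10 planted: {sorted(set(flagged) & set(REGIONS_66[:10])) == sorted(REGIONS_66[:10])})")
rows = table[(table.predictor == "pain") & table.fdr_significant]
for _, r in rows.sort_values("B").head(10).iterrows():
    print(f"  {r.region:28s} B={r.B:+.3f} mm per log-unit pain  p={r.p:.2g}")

vent = clinical["ventilation_days"].to_numpy() > 0
sub = fit_all_regions(thickness, design, subset=vent)
print(f"\nventilated subset (n={sub.attrs['n']}): pain significant in "
      f"{len(significant_regions(sub, 'pain'))}/66 regions")
print("\nNegative B on exactly the planted regions means the models isolate")
print("the pain effect from the six correlated clinical confounders.")
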