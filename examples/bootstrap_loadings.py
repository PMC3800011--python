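"""Bootstrap confidence intervals and FDR flags for CPCA region loadings.

Simulates a cohort with a single strong pain-driven component, bootstraps
the CPCA 300 times and prints the most significant region loadings with
their percentile CIs and FDR-corrected significance.
"""

import numpy as np

import corthick as ct
from corthick.preprocess import transform_predictors

spec = ct.EffectSpec(
    region_loadings=np.array([[-0.6] * 20 + [0.0] * 46]).T,
    predictor_weights=np.array([[1.0], [0], [0], [0], [0], [0], [0]]),
    noise_sd=0.15)
clinical = ct.generate_clinical_table(ct.CohortParams(n_subjects=300, seed=21))
thickness = ct.generate_thickness_matrix(clinical, spec, seed=22)

regions, predictors, full = ct.bootstrap_cpca(
    transform_predictors(clinical), thickness,
    ct.BootstrapConfig(n_reps=300, seed=23), k_predicted=1)

sig = regions[regions.fdr_5pct].sort_values("p").head(8)
print("top FDR-significant region loadings (component 1):")
for _, r in sig.iterrows():
    print(f"  {r.target:28s} loading {r.loading:+.2f} "
          f"CI [{r.ci_low:+.2f}, {r.ci_high:+.2f}]  p={r.p:.2g}")
n_sig = int(regions.fdr_5pct.sum())
print(f"\n{n_sig} regions FDR-significant; 20 regions carry the planted effect.")
print("CIs excluding zero and tiny p-values on planted regions (and only")
print("those) show the bootstrap correctly localizes the thinning pattern.")
print("(components are oriented with their largest region loading positive,")
print(" so 'thinning' appears as a negative pain loading below)")
print("\npredictor loadings with CIs:")
for _, r in predictors[predictors.component == 1].iterrows():
    flag = "*" if r.fdr_5pct else " "
    print(f"  {r.target:12s} {r.loading:+.2f} [{r.ci_low:+.2f}, {r.ci_high:+.2f}] {flag}")
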