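# corthick

Statistical toolkit for studying how neonatal clinical adversity relates to
regional cortical thickness in children born very preterm — and, more
generally, for asking *which part of a multivariate outcome block a set of
correlated predictors can explain, and what that part looks like*.

Infants born very preterm (24–32 weeks) spend weeks in intensive care
undergoing repeated skin-breaking procedures, mechanical ventilation,
surgery and opioid exposure, all of which are mutually confounded with
gestational age and illness severity. `corthick` implements the analysis
chain used to disentangle these exposures against 66-region cortical
thickness at school age, for biostatisticians and imaging researchers who
want the method as reusable, tested code:

* **Constrained principal component analysis (CPCA).** A multivariate
  regression of thickness `Y` on predictors `X` splits
  `Y = X(XᵀX)⁻¹XᵀY + E` into predictable and residual parts (the *external
  analysis*); PCAs with varimax/Kaiser rotation of the overall, predicted
  and residual matrices (the *internal analysis*) reveal the component
  structure of each part, with a variance-partition table, component
  loadings and predictor loadings (correlations of component scores with
  each clinical variable).
* **Bootstrap inference.** Subject resampling (default 1000×) with
  Procrustes alignment of replicate solutions yields percentile CIs and
  p-values per loading, with Benjamini–Hochberg FDR (5%) across regions.
* **Per-region GLMs.** One Gaussian identity-link model per region
  (unstandardized B, robust SEs, FDR across regions), with subset reruns
  such as ventilated-only.
* **Synthetic cohort generator.** Clinical tables calibrated to published
  very-preterm cohort statistics (skin-break median 74, IQR ≈45–136; 59.5%
  ventilated; GA–birth-weight r ≈ 0.76; morphine only when ventilated) and
  thickness matrices with planted low-rank effects, so every stage is
  testable end to end.
* **Laplacian-streamline thickness engine.** Solves Laplace's equation on a
  labelled gray-matter voxel volume and measures thickness as streamline
  arc length, with an enforced-separation boundary label that prevents
  abutting gyral banks from fusing — validated on slab, spherical-shell and
  abutting-gyri phantoms with analytic ground truth.

## Worked example

```python
import corthick as ct
from corthick.cpca import percent_of
from corthick.preprocess import transform_predictors

clinical, thickness = ct.simulate_cohort(ct.CohortParams(n_subjects=300, seed=5))
design = transform_predictors(clinical)          # log1p pain/ventilation, winsorize
res = ct.run_cpca(design, thickness, k_predicted=3, k_residual=2, k_overall=3)

vt = res.variance_table
print(percent_of(vt.loc["predictable", "total"], vt.loc["overall", "total"]))
```

Running `python examples/run_cpca.py` prints:

```
overall variance (66 z-scored regions): 66.00
predictable by 7 neonatal predictors:   34.24 (51.9% of overall)
  rotated predicted component 1: 22.40 (33.9% of overall)
  rotated predicted component 2: 6.39 (9.7% of overall)
  rotated predicted component 3: 5.01 (7.6% of overall)
```

Read: of the 66 units of variance in the standardized thickness block, the
seven neonatal predictors account for 34.2 (51.9%) in this simulated
300-subject cohort, and the first rotated predicted component alone carries
33.9% — the planted pain/illness-driven thinning dimension. The predictor
loadings printed below that identify which clinical variables drive each
component. (At this n the regression also absorbs chance covariation, so
the predictable share exceeds the planted effect size; the null expectation
is q/(n−1) ≈ 2.3%.)

The other `examples/` scripts each demonstrate one capability with a short
narrative: `simulate_cohort.py` (generator calibration),
`bootstrap_loadings.py` (CIs and FDR flags), `region_glm.py` (per-region
models and the ventilated subset), `phantom_thickness.py` (thickness engine
on analytic phantoms).

A thin CLI wraps the same library calls:

```sh
corthick simulate --n 100 --seed 1 --out-prefix cohort
corthick run --config run.yaml        # full pipeline -> TSV run directory
corthick thickness --labels labels.nii.gz --out thick.nii.gz
corthick report RUN_DIR
```

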