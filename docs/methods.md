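# Methods

`corthick` implements a two-stage statistical pipeline relating neonatal
clinical adversity to regional cortical thickness in children born very
preterm, together with the volumetric thickness measure that produces the
regional values, and a synthetic-cohort generator that makes the whole
pipeline testable without clinical data.

## Constrained principal component analysis

Let `Y` (subjects × 66 regions) be the thickness block and `X`
(subjects × 7) the neonatal predictor block: skin-breaking procedure count
(`pain`), gestational age (`ga`), days of mechanical ventilation
(`ventilation`), day-1 SNAP-II illness severity (`snap2`), number of
surgeries (`surgery`), culture-proven infection (`infection`) and cumulative
weight-adjusted morphine (`morphine`). Both blocks are z-scored
(n−1 denominator) by default, so all loadings are on the correlation scale.

**External analysis.** Multivariate least squares of `Y` on `X` gives
`Ŷ = X(XᵀX)⁻¹XᵀY` and residual `E = Y − Ŷ`. Because the projection is
orthogonal, total variance partitions additively:
`var(Y) = var(Ŷ) + var(E)` column by column; the package reports the
partition as absolute variances and as percentages of the overall total.
Rank-deficient designs fall back to the minimum-norm (pseudo-inverse)
projection with a recorded warning.

**Internal analysis.** Covariance PCA (n−1 denominator) of the overall,
predicted and residual matrices. Conventions: loadings carry the variance
(per-component sum of squared loadings = eigenvalue), scores have unit
variance, components are oriented so the largest-|loading| entry is
positive. Each retained solution is varimax-rotated with Kaiser
normalization (rows scaled by communality during the optimization,
zero-communality rows excluded with a warning); rotated components are
reordered by explained variance. Orthogonal rotation preserves both
communalities and the retained-variance total, which ties the rotated
per-component variances to the unrotated eigenvalue sum in the variance
table.

**Predictor loadings.** Pearson correlations between the predicted-solution
component scores and the predictor columns. Note these can be large for
several predictors at once even when component scores are orthogonal,
because the predictors themselves are correlated.

Component retention defaults to 3 (predicted), 2 (residual), 3 (overall);
an eigenvalue profile (`scree.tsv`) is always emitted so retention can be
judged by inspection.

Whether the two blocks were standardized before analysis is a genuinely
open choice in this family of analyses; the default here is to z-score
both. With 66 z-scored regions the overall total is exactly 66 —
correlation-scale totals slightly different from 66 in historical reports
suggest an unstandardized or differently-scaled variant, and
`standardize=False` is provided.

## Bootstrap inference

Subjects are resampled with replacement `n_reps` times (default 1000);
every replicate reruns the pipeline from scratch — z-scoring, external
regression, PCA, varimax (a full-pipeline bootstrap, not a residual
bootstrap). Replicates where the pipeline degenerates (e.g. a resampled
binary predictor becomes constant) are dropped and counted; more than 20%
of them aborts inference.

**Alignment.** A resampled PCA solution is defined only up to column
reflection/reordering, so replicate loadings must be aligned to the
full-sample solution before accumulation. Two methods are provided:

* `procrustes` (default): the orthogonal rotation minimizing
  `‖L_rep R − L_ref‖_F`. This removes the *full* rotational indeterminacy
  within the retained subspace. We measured that this matters: under a null
  cohort (no predictor–thickness association, n=100, k=3), permutation/sign
  matching leaves within-subspace rotational wobble that inflates bootstrap
  SDs by ≈1.25× relative to the true sampling SD of a loading, making
  p-values conservative (empirical type-I ≈0.02 at nominal 0.05); Procrustes
  alignment restores calibration.
* `congruence`: greedy matching of columns by largest |Tucker congruence|
  with sign flip (`align_components`), retained because it preserves each
  replicate's varimax solution exactly and is the natural tool for matching
  recovered to planted components in validation studies.

**Intervals and p-values.** CIs are percentile intervals at `ci_level`
(default 95%), reported in the sign of the full-sample loading. The default
p-value is a two-sided normal approximation, |point| / bootstrap SD: with
1000 replicates a pure sign-proportion p cannot resolve below 1/1000,
whereas small tail probabilities are routinely reported in this kind of
analysis; `sign_proportion` (floored at 1/n_reps) is available. Historical
tables of this analysis sometimes print CIs on the reflected component
(loading and CI with opposite signs); this package does not reproduce that
tabulation convention.

**Multiplicity.** Benjamini–Hochberg FDR at 5% across the 66 regions within
each component, and across the 7 predictors within each component for the
predictor-loading table. `fdr_bh` delegates to statsmodels' step-up
implementation and is cross-checked in the tests against a brute-force
implementation of the step-up definition.

## Per-region GLMs

One Gaussian identity-link model per region regresses thickness on the
seven predictors, transformed as in preprocessing (log1p pain and
ventilation; ventilation winsorized) but *not* z-scored, so `B` is mm per
unit transformed predictor. A Gaussian/identity GLM is numerically
identical to OLS, which is how it is fit; the default standard errors are
heteroskedasticity-robust (HC1 sandwich) — honouring the rationale for
using a GLM, relaxing the constant-variance requirement — with classical
(`model`) SEs available, since the exact variance estimator used by legacy
statistical packages is not knowable. FDR is applied per predictor across
regions (an `all_cells` option pools everything). A subset predicate (e.g.
`ventilation_days > 0`) restricts rows before fitting and is recorded.

## Preprocessing

* `log(1+x)` rather than `log x` for skin-breaks and ventilation days,
  because both are legitimately zero.
* Winsorization: one pass; mean and SD computed including the outlier;
  values outside mean ± 3 SD replaced by the nearest *other observed* value
  inside the band — no invented values. Winsorize-then-log when both apply.
* Binary predictors are z-scored like continuous ones for CPCA
  (correlation-scale loadings are scale-invariant); GLMs use them
  untransformed.
* Screens: per-region Pearson correlation with age at scan and two-sample
  t-tests between sexes, Bonferroni-corrected over the 66 regions. Sex and
  age at scan are generated by the cohort simulator but excluded from the
  default predictor set.

## Synthetic cohort generator

The generator emulates the *data structure* of a very-preterm NICU cohort.
Calibration targets (medians/IQRs and rates of a published cohort of this
population) and the distributional choices:

| variable | form | calibrated to |
|---|---|---|
| skin-breaks | log-normal(ln 74, 0.82), rounded | median 74, IQR ≈ 45–136 |
| gestational age | 24 + 9·Beta(1.214, 0.827) weeks | median 29.7, IQR 27.3–31.6 |
| birth weight | trunc-normal(1138, 560) on [400, 3000] g | median ≈1203 g |
| ventilation | 59.5% ventilated; days 1+NB(0.93, mean 11.3) | overall median 2, q75 ≈10 |
| SNAP-II | 30% zeros, else gamma(3.25, scale 4.11), rounded | median 8.5, q75 ≈14.75 |
| infection | Bernoulli(0.26) | 26% |
| surgery | Bernoulli(0.19), count 1+Poisson(0.3) | 19% ≥1 |
| morphine | ventilated only: days × 25.65 µg/kg × lognormal(0.8) | ventilated median ≈205 |

GA, birth weight, skin-breaks, ventilation and SNAP-II are joined through a
Gaussian copula. The latent GA–BW correlation (0.7919) is calibrated so the
*sample* Pearson correlation is ≈0.76 (the non-normal marginals attenuate
the latent value); GA–skin and GA–ventilation default to −0.5 on the latent
scale (≈−0.4 observed), infection and surgery are drawn independently.
These cross-correlation defaults are free parameters and overridable.

**Planted effects.** Thickness is `Y = baseline + Z W Lᵀ + ε` with `Z` the
z-scored raw predictors, `W` (7 × k) predictor weights, `L` (66 × k) signed
region loadings, and isotropic Gaussian noise (diagonal residual
covariance — real cortical thickness has spatially correlated residuals,
which this deliberately does not model). Values are clamped to (0.1, 9.9)
mm; with defaults this touches <0.1% of entries. The three-component
*reference* effect has negative loadings on frontal/central/parietal
regions (component 1, pain/illness-driven), negative parietal/temporal/
occipital loadings (component 2, surgery-driven), and positive cingulate
loadings (component 3, morphine/ventilation-driven).

A design point worth recording: planting `W` directly as the desired
predictor-loading pattern produces highly *correlated* component scores
(the severity predictors are mutually correlated), which no orthogonal
rotation can recover and which misrepresents the structure being emulated —
in a varimax-rotated PCA solution the component scores are orthogonal, and
large loadings on many predictors arise from predictor inter-correlation,
not score correlation. `reference_effect_spec` therefore whitens the weight
columns under the frozen large-sample predictor correlation matrix, making
planted scores uncorrelated while preserving the dominant sign pattern;
recovered-vs-planted Tucker congruence is then ≈0.97 at n=500, noise 0.2 mm.

**What passing tests show.** The generator reproduces marginal quantiles,
one pairwise correlation structure and a linear low-rank effect. It does
not emulate spatial autocorrelation between regions, non-linear
dose–response, measurement artifacts, or missingness; pipeline performance
on it bounds only statistical correctness (calibration, recovery, FDR
control), not robustness to those real-data features.

## Laplacian-streamline thickness

The cortical mantle is a labelled voxel grid (0 background, 1 inner/white,
2 gray, 3 outer/pial-CSF, 4 enforced-separation wall), isotropic spacing.
Laplace's equation is solved on gray voxels with Dirichlet ψ=0 on inner and
ψ=1 on outer *and* wall labels, by red-black Gauss–Seidel on the 6-neighbour
stencil (background neighbours excluded — zero-flux), stopping when the
largest per-sweep update ≤ `tol` (default 1e-6, max 10 000 sweeps). The
discrete maximum principle keeps ψ in [0,1].

Thickness at a gray voxel is the arc length of the gradient streamline
traced from the voxel centre downhill to the inner boundary plus uphill to
the outer/wall boundary: classical RK4 with fixed step 0.25 voxel on the
normalized trilinearly-interpolated gradient (the potential is extended to
background by nearest-neighbour fill so interpolation at the domain edge is
defined). A trace terminates when the nearest voxel is any Dirichlet
boundary; the final partial step is refined by bisection of the last chord
(22 iterations), which removes the step-quantization bias — a 5-voxel slab
measures 5.000 mm. Traces that leave the labelled domain or exceed the
length cap (3 grid diagonals) are `truncated`; voxels whose starting
gradient is below 1e-4 are `boundary` and excluded from statistics.

**Topology enforcement.** Where two gyral banks abut, the vanished CSF gap
lets gray domains fuse and streamlines cross into the neighbouring bank,
overestimating thickness. Labelling the touching interface with the wall
label reinstates a Dirichlet surface: no smoothing or streamline crosses
it, and enforcement can only decrease (or preserve) any voxel's thickness.
The mesh-based coupled-surface variant of this idea is out of scope; the
voxel wall expresses the same contract at phantom scale. In the abutting
phantom the far bank deliberately has no white boundary once walled off:
its voxels report `boundary` status rather than a silently wrong number.

**Accuracy.** Validated on phantoms with analytic truth: slab exact; shell
(R1=8, R2=12 mm, 1 mm spacing) median 4.04 mm vs 4 mm, improving to
4.01 mm at 0.5 mm spacing; abutting banks 8.00 mm fused vs 4.00 mm walled.
One discretization limit is documented rather than hidden: with 0/1
Dirichlet at voxel centres, the voxelized sphere's boundary jaggedness
(~half a voxel) times the potential gradient produces pointwise potential
errors up to ~0.1 near mid-shell at 1 mm; the tests assert the 1/r closed
form at that discretization-justified tolerance plus convergence under
spacing refinement. Reported thickness is the raw arc length with no
half-voxel correction (bias O(spacing), removed in practice by the
bisection refinement for flat interfaces).

## Pipeline, determinism, problem sizes

One global seed spawns per-stage seeds (simulation, thickness noise,
bootstrap) through `numpy.random.SeedSequence`; all seeds are recorded in
`settings.json`, all tables are written as TSV with fixed float formatting,
and rerunning a configuration reproduces every numeric artifact
byte-for-byte.

Validation problem sizes were chosen to give stable Monte-Carlo estimates
at desk scale: generator calibration at n=4200; three-component recovery
over 20 cohorts of n=500 (noise 0.2 mm); GLM recovery/FDR over 50 cohorts
of n=400; bootstrap type-I calibration over 200 null cohorts of n=100 with
200 replicates each. The null-calibration cohorts use n=100 rather than a
42-subject cohort because with ~1 positive case of a binary predictor most
resamples are degenerate, which the >20%-degenerate guard (correctly)
turns into an inference failure — itself a caution against bootstrapping
rare binary predictors at very small n.

## Known limitations

* Diagonal residual noise between regions; no spatial covariance.
* The reference effect's small-magnitude weight entries can flip sign under
  the whitening transform; only the dominant sign pattern is preserved.
* Bootstrap CIs are percentile (no BCa/studentized); no permutation tests;
  no oblique rotations or weighted CPCA variants.
* The thickness engine handles voxel labels only — no surface
  reconstruction, registration or real-MRI segmentation — and assumes
  isotropic spacing.
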