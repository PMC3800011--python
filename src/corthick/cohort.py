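"""Synthetic neonatal cohort generator.

Emulates the clinical data structure of a very-preterm NICU cohort: seven
neonatal predictors (skin-breaking procedure count, gestational age, days of
mechanical ventilation, SNAP-II illness severity, surgeries, culture-proven
infection, cumulative weight-adjusted morphine) plus demographics, and a
matching subjects x 66-region cortical-thickness matrix carrying a planted
low-rank predictor-to-thickness effect.

Distributional choices and their calibration targets:

* skin-breaks: log-normal (median 74, IQR ~[45, 136]), rounded to counts;
* gestational age: scaled Beta on [24, 33] weeks (median 29.71,
  IQR ~[27.29, 31.57]);
* birth weight: truncated normal on [400, 3000] g (median ~1203 g);
* GA and BW joined through a Gaussian copula whose latent correlation
  (default 0.7919) yields a sample Pearson r of ~0.76;
* ventilation: zero-inflated (59.5% ventilated), ventilated days
  1 + negative binomial;
* SNAP-II: zero-inflated discretized gamma (median ~8.5, IQR ~[0, 15]);
* infection and surgery: Bernoulli indicators (26% / 19%);
* morphine: only for ventilated subjects, proportional to ventilated days
  with multiplicative log-normal noise (ventilated-subgroup median ~205
  ug/kg cumulative).

The thickness generator plants ``Y = baseline + Z W L' + noise`` where Z is
the z-scored predictor block, W the predictor-to-component weights and L the
region loadings, so every downstream stage has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SchemaError, ShapeError
from .regions import N_REGIONS, REGIONS_66

#: Canonical predictor names, in the order used by every design matrix.
PREDICTORS = ("pain", "ga", "ventilation", "snap2", "surgery", "infection", "morphine")

#: Map from predictor name to its clinical-table column.
PREDICTOR_COLUMNS = {
    "pain": "skin_breaks",
    "ga": "gestational_age",
    "ventilation": "ventilation_days",
    "snap2": "snap2",
    "surgery": "n_surgeries",
    "infection": "infection",
    "morphine": "morphine_cum",
}

# Latent (copula) correlations among the continuous severity variables that
# are not exposed as CohortParams fields: (bw, skin), (bw, vent), (bw, snap),
# (skin, vent), (skin, snap), (vent, snap), (ga, snap).
_BW_SKIN = -0.38
_BW_VENT = -0.38
_BW_SNAP = -0.23
_SKIN_VENT = 0.45
_SKIN_SNAP = 0.35
_VENT_SNAP = 0.35
_GA_SNAP = -0.30


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the clinical-table generator.

    The defaults are calibrated so that, for large cohorts, the sample
    marginals reproduce the targets listed in the module docstring.
    ``ga_bw_corr`` is the latent Gaussian-copula correlation; its default is
    chosen so that the *observed* GA-BW Pearson correlation is ~0.76.
    """

    n_subjects: int = 42
    seed: int = 0
    # skin-breaking procedures (log scale)
    skin_break_log_mean: float = float(np.log(74.0))
    skin_break_log_sd: float = 0.82
    # gestational age: 24 + 9 * Beta(a, b) weeks
    ga_beta_a: float = 1.2136
    ga_beta_b: float = 0.8275
    ga_min_weeks: float = 24.0
    ga_max_weeks: float = 33.0
    # birth weight: truncated normal, grams
    bw_mean_g: float = 1138.11
    bw_sd_g: float = 560.07
    bw_min_g: float = 400.0
    bw_max_g: float = 3000.0
    # cross-predictor latent correlations (Gaussian copula scale)
    ga_bw_corr: float = 0.7919
    ga_skin_corr: float = -0.5
    ga_vent_corr: float = -0.5
    # ventilation: zero inflation + shifted negative binomial for day counts
    p_ventilated: float = 0.595
    vent_nb_size: float = 0.9292
    vent_nb_mean: float = 11.2592
    # SNAP-II illness severity: zero-inflated discretized gamma
    snap_zero_p: float = 0.30
    snap_gamma_shape: float = 3.2512
    snap_gamma_scale: float = 4.1087
    # infection / surgery indicators
    p_infection: float = 0.26
    p_surgery: float = 0.19
    surgery_extra_mean: float = 0.3
    # morphine, ug/kg cumulative: days * rate * lognormal noise
    morphine_per_vent_day: float = 25.65
    morphine_log_sd: float = 0.8
    # demographics (generated, not part of the default predictor set)
    p_male: float = 16.0 / 42.0
    scan_age_mean: float = 7.9
    scan_age_sd: float = 0.25

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        for name in ("p_ventilated", "p_infection", "p_surgery", "snap_zero_p", "p_male"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        for name in ("ga_bw_corr", "ga_skin_corr", "ga_vent_corr"):
            r = getattr(self, name)
            if not abs(r) < 1.0:
                raise ParameterError(f"{name}={r} must satisfy |r| < 1")
        if self.skin_break_log_sd < 0 or self.vent_nb_size <= 0 or self.vent_nb_mean <= 0:
            raise ParameterError("dispersion/scale parameters must be positive")
        np.linalg.cholesky(self.latent_correlation())  # raises if not PD

    def latent_correlation(self) -> np.ndarray:
        """5x5 latent correlation among (ga, bw, skin, vent, snap)."""
        r = self.ga_bw_corr
        c = np.array([
            [1.0, r, self.ga_skin_corr, self.ga_vent_corr, _GA_SNAP],
            [r, 1.0, _BW_SKIN, _BW_VENT, _BW_SNAP],
            [self.ga_skin_corr, _BW_SKIN, 1.0, _SKIN_VENT, _SKIN_SNAP],
            [self.ga_vent_corr, _BW_VENT, _SKIN_VENT, 1.0, _VENT_SNAP],
            [_GA_SNAP, _BW_SNAP, _SKIN_SNAP, _VENT_SNAP, 1.0],
        ])
        return c

    def with_(self, **kwargs) -> "CohortParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def generate_clinical_table(params: CohortParams) -> pd.DataFrame:
    """Draw a synthetic clinical table.

    Deterministic for a fixed ``params`` (including its seed).  Morphine is
    zero whenever ventilation is zero, by construction.
    """
    params.validate()
    n = params.n_subjects
    rng = np.random.default_rng(params.seed)

    corr = params.latent_correlation()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 5)) @ chol.T
    u = stats.norm.cdf(z)
    u_ga, u_bw, u_skin, u_vent, u_snap = u.T

    ga = params.ga_min_weeks + (params.ga_max_weeks - params.ga_min_weeks) * stats.beta.ppf(
        u_ga, params.ga_beta_a, params.ga_beta_b
    )
    a = (params.bw_min_g - params.bw_mean_g) / params.bw_sd_g
    b = (params.bw_max_g - params.bw_mean_g) / params.bw_sd_g
    bw = np.round(
        stats.truncnorm.ppf(u_bw, a, b, loc=params.bw_mean_g, scale=params.bw_sd_g)
    ).astype(int)

    skin = np.maximum(
        1,
        np.round(np.exp(params.skin_break_log_mean + params.skin_break_log_sd * z[:, 2])),
    ).astype(int)

    ventilated = u_vent > 1.0 - params.p_ventilated
    vent_days = np.zeros(n, dtype=int)
    if ventilated.any():
        # conditional uniform within the ventilated upper tail of the copula
        u_cond = (u_vent[ventilated] - (1.0 - params.p_ventilated)) / params.p_ventilated
        u_cond = np.clip(u_cond, 1e-12, 1.0 - 1e-12)
        size = params.vent_nb_size
        p_nb = size / (size + params.vent_nb_mean)
        vent_days[ventilated] = 1 + stats.nbinom.ppf(u_cond, size, p_nb).astype(int)

    snap = np.zeros(n)
    pos = u_snap >= params.snap_zero_p
    u_cond = np.clip((u_snap[pos] - params.snap_zero_p) / (1.0 - params.snap_zero_p),
                     1e-12, 1.0 - 1e-12)
    snap[pos] = np.round(
        stats.gamma.ppf(u_cond, params.snap_gamma_shape, scale=params.snap_gamma_scale)
    )
    snap = snap.astype(int)

    infection = (rng.uniform(size=n) < params.p_infection).astype(int)
    has_surgery = rng.uniform(size=n) < params.p_surgery
    n_surgeries = np.where(
        has_surgery, 1 + rng.poisson(params.surgery_extra_mean, size=n), 0
    ).astype(int)

    morphine = np.zeros(n)
    morphine[ventilated] = (
        vent_days[ventilated]
        * params.morphine_per_vent_day
        * np.exp(params.morphine_log_sd * rng.standard_normal(int(ventilated.sum())))
    )

    sex = np.where(rng.uniform(size=n) < params.p_male, "M", "F")
    age_at_scan = params.scan_age_mean + params.scan_age_sd * rng.standard_normal(n)

    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "sex": sex,
        "age_at_scan": age_at_scan,
        "birth_weight": bw,
        "skin_breaks": skin,
        "gestational_age": ga,
        "ventilation_days": vent_days,
        "snap2": snap,
        "n_surgeries": n_surgeries,
        "infection": infection,
        "morphine_cum": morphine,
    })


@dataclass(frozen=True)
class EffectSpec:
    """Planted predictor-to-thickness effect structure.

    ``region_loadings`` is regions x components (signed, mm per unit
    component score); ``predictor_weights`` is predictors x components on the
    z-scored predictor scale.  A null spec (all-zero weights) makes thickness
    independent of the predictors.
    """

    region_loadings: np.ndarray
    predictor_weights: np.ndarray
    noise_sd: float = 0.2
    baseline_mm: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, 2.7))

    def __post_init__(self):
        object.__setattr__(self, "region_loadings",
                           np.atleast_2d(np.asarray(self.region_loadings, dtype=float)))
        object.__setattr__(self, "predictor_weights",
                           np.atleast_2d(np.asarray(self.predictor_weights, dtype=float)))
        object.__setattr__(self, "baseline_mm",
                           np.asarray(self.baseline_mm, dtype=float))

    @property
    def n_components(self) -> int:
        return self.region_loadings.shape[1]

    def validate(self, n_predictors: int = len(PREDICTORS),
                 n_regions: int = N_REGIONS) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.region_loadings.shape != (n_regions, self.n_components):
            raise ShapeError(
                f"region_loadings shape {self.region_loadings.shape} does not match "
                f"({n_regions}, k)")
        if self.predictor_weights.shape != (n_predictors, self.n_components):
            raise ShapeError(
                f"predictor_weights shape {self.predictor_weights.shape} does not "
                f"match ({n_predictors}, {self.n_components})")
        if self.baseline_mm.shape != (n_regions,):
            raise ShapeError("baseline_mm must have one entry per region")


def null_effect_spec(n_components: int = 1, noise_sd: float = 0.2) -> EffectSpec:
    """All-zero effect: thickness independent of the predictors."""
    return EffectSpec(
        region_loadings=np.zeros((N_REGIONS, n_components)),
        predictor_weights=np.zeros((len(PREDICTORS), n_components)),
        noise_sd=noise_sd,
    )


# Region loading patterns of the three-component reference effect: negative
# frontal/central/parietal loadings on component 1 (procedural pain and
# illness), negative parietal/temporal/occipital loadings on component 2
# (surgery-related), positive cingulate loadings on component 3 (morphine).
_COMP1_LOADINGS = {
    "l_precentral": -0.65, "l_superior_frontal": -0.62, "r_superior_frontal": -0.54,
    "l_superior_parietal": -0.60, "l_inferior_parietal": -0.56, "l_postcentral": -0.50,
    "r_superior_parietal": -0.52, "l_supramarginal": -0.44, "r_inferior_parietal": -0.52,
    "l_frontal_pole": -0.54, "l_precuneus": -0.48, "r_rostral_middle_frontal": -0.49,
    "l_rostral_middle_frontal": -0.47, "r_pars_orbitalis": -0.49,
    "r_middle_temporal": -0.51, "l_caudal_middle_frontal": -0.50,
    "r_caudal_middle_frontal": -0.57, "r_supramarginal": -0.48, "r_precuneus": -0.44,
    "r_inferior_temporal": -0.43, "r_pars_opercularis": -0.44,
    "r_superior_temporal": -0.48, "l_paracentral": -0.57, "r_paracentral": -0.54,
    "r_precentral": -0.55, "l_pars_triangularis": -0.38, "l_middle_temporal": -0.38,
    "r_postcentral": -0.44, "r_lateral_orbitofrontal": -0.37,
    "l_pars_opercularis": -0.33, "r_pars_triangularis": -0.41, "l_entorhinal": -0.37,
}
_COMP2_LOADINGS = {
    "l_inferior_parietal": -0.48, "l_inferior_temporal": -0.46,
    "r_inferior_parietal": -0.51, "r_lateral_occipital": -0.54,
    "l_supramarginal": -0.55, "l_precuneus": -0.31, "l_medial_orbitofrontal": -0.44,
    "l_superior_parietal": -0.38, "r_superior_parietal": -0.39,
    "r_inferior_temporal": -0.36,
}
_COMP3_LOADINGS = {
    "l_caudal_anterior_cingulate": 0.56, "l_lingual": 0.54, "r_pars_opercularis": 0.42,
    "r_caudal_anterior_cingulate": 0.57, "l_posterior_cingulate": 0.38,
    "l_rostral_anterior_cingulate": 0.46, "r_rostral_middle_frontal": 0.38,
    "l_lateral_orbitofrontal": 0.33, "r_pars_triangularis": 0.32, "l_fusiform": 0.37,
    "l_inferior_temporal": 0.30,
}

# Desired score-predictor correlation pattern (PREDICTORS order, 3 components):
# pain-related stress dominates components 1-2, surgery component 2, morphine
# and ventilation component 3, gestational age negative throughout.
_REFERENCE_WEIGHTS = np.array([
    # comp1  comp2  comp3
    [0.67, 0.57, -0.06],   # pain
    [-0.48, -0.64, 0.02],  # ga
    [0.32, 0.63, 0.57],    # ventilation
    [0.75, 0.32, 0.36],    # snap2
    [0.05, 0.92, 0.28],    # surgery
    [0.47, 0.04, 0.001],   # infection
    [0.38, 0.62, 0.59],    # morphine
])

# Large-sample correlation matrix of the 7 raw predictors under the default
# CohortParams (n = 3e5 draw), used to orthogonalize the planted component
# scores.  PREDICTORS order.
_PREDICTOR_CORR = np.array([
    [1.000, -0.413, 0.373, 0.294, -0.002, -0.001, 0.247],
    [-0.413, 1.000, -0.418, -0.280, -0.001, 0.003, -0.279],
    [0.373, -0.418, 1.000, 0.295, -0.002, -0.003, 0.668],
    [0.294, -0.280, 0.295, 1.000, -0.001, 0.000, 0.198],
    [-0.002, -0.001, -0.002, -0.001, 1.000, 0.000, -0.001],
    [-0.001, 0.003, -0.003, 0.000, 0.000, 1.000, 0.000],
    [0.247, -0.279, 0.668, 0.198, -0.001, 0.000, 1.000],
])


def _inv_sqrt_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return v @ np.diag(1.0 / np.sqrt(np.maximum(w, 1e-12))) @ v.T


def reference_effect_spec(noise_sd: float = 0.2) -> EffectSpec:
    """Three-component planted effect with the reference sign pattern.

    Components 1-2 thin (negative loadings) frontal/parietal respectively
    parietal/temporal/occipital cortex and are driven mainly by pain-related
    and surgery-related predictors; component 3 thickens cingulate regions
    and is driven mainly by morphine and ventilation.

    The predictor weights are chosen so the planted component scores are
    mutually uncorrelated (whitened under the large-sample predictor
    correlation) — mirroring the orthogonality of the rotated PCA components
    they emulate — while their correlations with the predictors keep the
    reference sign pattern.
    """
    loadings = np.zeros((N_REGIONS, 3))
    for k, pattern in enumerate((_COMP1_LOADINGS, _COMP2_LOADINGS, _COMP3_LOADINGS)):
        for name, value in pattern.items():
            loadings[REGIONS_66.index(name), k] = value
    w = np.linalg.solve(_PREDICTOR_CORR, _REFERENCE_WEIGHTS)
    weights = w @ _inv_sqrt_psd(_REFERENCE_WEIGHTS.T @ w)
    return EffectSpec(region_loadings=loadings, predictor_weights=weights,
                      noise_sd=noise_sd)


def predictor_matrix(clinical: pd.DataFrame) -> pd.DataFrame:
    """Extract the 7 canonical predictor columns (raw scale)."""
    missing = [c for c in PREDICTOR_COLUMNS.values() if c not in clinical.columns]
    if missing:
        raise SchemaError(f"clinical table is missing predictor columns: {missing}")
    return pd.DataFrame(
        {name: clinical[col].to_numpy(dtype=float) for name, col in PREDICTOR_COLUMNS.items()},
        index=clinical.index,
    )


def _safe_zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1, axis=0)
    centered = x - x.mean(axis=0)
    out = np.zeros_like(centered)
    nz = sd > 0
    out[:, nz] = centered[:, nz] / sd[nz]
    return out


def generate_thickness_matrix(clinical: pd.DataFrame, spec: EffectSpec,
                              seed: int) -> pd.DataFrame:
    """Draw a thickness matrix with the planted effect structure.

    Thickness for subject i, region j is
    ``baseline_j + sum_c (Z W)_{ic} L_{jc} + noise``, with Z the z-scored
    predictor block (constant predictor columns contribute nothing).
    Values are clamped to the physiologic range (0.1, 9.9) mm; with the
    default baseline and effect scale this touches well under 0.1% of
    entries (extreme morphine/ventilation outliers).
    """
    spec.validate()
    z = _safe_zscore(predictor_matrix(clinical).to_numpy())
    rng = np.random.default_rng(seed)
    scores = z @ spec.predictor_weights
    y = (spec.baseline_mm[None, :]
         + scores @ spec.region_loadings.T
         + spec.noise_sd * rng.standard_normal((len(clinical), N_REGIONS)))
    np.clip(y, 0.1, 9.9, out=y)
    out = pd.DataFrame(y, columns=list(REGIONS_66), index=clinical.index)
    out.insert(0, "subject_id", clinical["subject_id"].to_numpy())
    return out


def simulate_cohort(params: CohortParams, spec: EffectSpec | None = None,
                    thickness_seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: clinical table plus matching thickness matrix."""
    if spec is None:
        spec = reference_effect_spec()
    clinical = generate_clinical_table(params)
    if thickness_seed is None:
        thickness_seed = params.seed + 1_000_003
    thickness = generate_thickness_matrix(clinical, spec, seed=thickness_seed)
    return clinical, thickness
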