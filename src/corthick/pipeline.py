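"""End-to-end orchestration: configuration, I/O and report rendering.

A run takes either a pair of input tables (clinical TSV + thickness TSV) or
a simulation request, then executes: predictor transforms -> preliminary
age/sex screens -> CPCA -> bootstrap inference -> per-region GLMs (with an
optional ventilated-subset rerun and an optional birth-weight sensitivity
CPCA), writing every table as TSV plus a JSON settings record and a log.
Reruns with the same configuration reproduce every artifact byte for byte:
one global seed deterministically spawns the per-stage seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import BootstrapConfig, bootstrap_cpca
from .cohort import (CohortParams, EffectSpec, generate_clinical_table,
                     generate_thickness_matrix, null_effect_spec,
                     reference_effect_spec)
from .cpca import run_cpca
from .errors import JoinError, ParameterError, ReportError, SchemaError
from .glm import fit_all_regions
from .preprocess import screen_univariate, transform_predictors
from .regions import REGIONS_66

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``clinical_path``/``thickness_path`` (both) or
    ``simulate`` may be used.
    """

    out_dir: str = "corthick_run"
    seed: int = 0
    clinical_path: str | None = None
    thickness_path: str | None = None
    simulate: dict | None = None          # CohortParams overrides
    effect: str | None = None             # "reference", "null" or JSON path
    log_cols: tuple[str, ...] = ("pain", "ventilation")
    winsor_cols: tuple[str, ...] = ("ventilation",)
    k_predicted: int = 3
    k_residual: int = 2
    k_overall: int = 3
    n_boot: int = 1000
    ci_level: float = 0.95
    p_method: str = "normal_approx"
    glm_q: float = 0.05
    se_type: str = "robust"
    ventilated_subset: bool = False
    birth_weight_sensitivity: bool = False

    def validate(self) -> None:
        from_files = self.clinical_path is not None or self.thickness_path is not None
        if from_files and self.simulate is not None:
            raise ParameterError(
                "config must give either input paths or a simulation spec, not both")
        if from_files and (self.clinical_path is None or self.thickness_path is None):
            raise ParameterError("both clinical_path and thickness_path are required")
        if not from_files and self.simulate is None:
            raise ParameterError("config must give input paths or a simulation spec")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("log_cols", "winsor_cols"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def effect_spec_from_json(path) -> EffectSpec:
    with open(path) as fh:
        raw = json.load(fh)
    return EffectSpec(region_loadings=np.asarray(raw["region_loadings"]),
                      predictor_weights=np.asarray(raw["predictor_weights"]),
                      noise_sd=float(raw.get("noise_sd", 0.2)),
                      baseline_mm=np.asarray(raw.get("baseline_mm",
                                                     np.full(len(REGIONS_66), 2.7))))


def effect_spec_to_json(spec: EffectSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump({"region_loadings": spec.region_loadings.tolist(),
                   "predictor_weights": spec.predictor_weights.tolist(),
                   "noise_sd": spec.noise_sd,
                   "baseline_mm": spec.baseline_mm.tolist()}, fh, indent=2)


def _resolve_effect(effect: str | None) -> EffectSpec:
    if effect in (None, "reference"):
        return reference_effect_spec()
    if effect == "null":
        return null_effect_spec()
    return effect_spec_from_json(effect)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_tables(clinical_path, thickness_path
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate the clinical and thickness tables.

    Subject IDs must match one-to-one (thickness rows are reordered to the
    clinical order); the thickness columns must be exactly the packaged
    66-region list.
    """
    clinical = pd.read_csv(clinical_path, sep="\t")
    thickness = pd.read_csv(thickness_path, sep="\t")
    for name, df in (("clinical", clinical), ("thickness", thickness)):
        if "subject_id" not in df.columns:
            raise SchemaError(f"{name} table has no subject_id column")
    have = [c for c in thickness.columns if c != "subject_id"]
    missing = sorted(set(REGIONS_66) - set(have))
    unknown = sorted(set(have) - set(REGIONS_66))
    if missing or unknown:
        raise SchemaError(f"thickness columns do not match the 66-region "
                          f"list; missing={missing} unknown={unknown}")
    cids = set(clinical["subject_id"])
    tids = set(thickness["subject_id"])
    if cids != tids:
        raise JoinError(f"unmatched subjects; clinical-only="
                        f"{sorted(cids - tids)} thickness-only={sorted(tids - cids)}")
    thickness = (thickness.set_index("subject_id")
                 .loc[clinical["subject_id"]]
                 .reset_index())
    return clinical, thickness[["subject_id", *REGIONS_66]]


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("simulate_clinical", "simulate_thickness", "bootstrap", "spare")
    return {n: int(s) & 0x7FFFFFFF for n, s in zip(names, state)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all artifacts to the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log: list[str] = [f"corthick {__version__}", f"global seed {config.seed}",
                      f"stage seeds {seeds}"]

    if config.simulate is not None:
        params = CohortParams(**{**config.simulate,
                                 "seed": seeds["simulate_clinical"]})
        spec = _resolve_effect(config.effect)
        clinical = generate_clinical_table(params)
        thickness = generate_thickness_matrix(clinical, spec,
                                              seed=seeds["simulate_thickness"])
        write_tsv(clinical, out / "clinical.tsv")
        write_tsv(thickness, out / "thickness.tsv")
        log.append(f"simulated cohort n={params.n_subjects}")
    else:
        clinical, thickness = read_tables(config.clinical_path,
                                          config.thickness_path)
        log.append(f"loaded tables n={len(clinical)}")

    # --- preprocess -------------------------------------------------------
    design = transform_predictors(clinical, log_cols=config.log_cols,
                                  winsor_cols=config.winsor_cols)
    write_tsv(design.data, out / "design.tsv")
    (out / "design_transforms.json").write_text(design.sidecar_json())

    screen_age = screen_univariate(thickness, clinical["age_at_scan"],
                                   mode="correlation")
    screen_sex = screen_univariate(thickness, clinical["sex"],
                                   mode="two_sample_t")
    write_tsv(screen_age, out / "screen_age.tsv")
    write_tsv(screen_sex, out / "screen_sex.tsv")
    log.append(f"screens: {int(screen_age['significant'].sum())} age / "
               f"{int(screen_sex['significant'].sum())} sex regions "
               "Bonferroni-significant")

    # --- CPCA + bootstrap -------------------------------------------------
    boot_cfg = BootstrapConfig(n_reps=config.n_boot, seed=seeds["bootstrap"],
                               ci_level=config.ci_level,
                               p_method=config.p_method, fdr_q=config.glm_q)
    region_inf, predictor_inf, cpca = bootstrap_cpca(
        design, thickness, boot_cfg, k_predicted=config.k_predicted,
        k_residual=config.k_residual, k_overall=config.k_overall)
    write_tsv(cpca.variance_table.reset_index(), out / "variance_table.tsv")
    write_tsv(cpca.scree.reset_index(names="component"), out / "scree.tsv")
    for label, sol in cpca.solutions.items():
        df = pd.DataFrame(sol.loadings, index=cpca.settings["regions"],
                          columns=[f"comp{j + 1}" for j in range(sol.k)])
        write_tsv(df.reset_index(names="region"), out / f"loadings_{label}.tsv")
    write_tsv(cpca.predictor_loadings.reset_index(names="predictor"),
              out / "predictor_loadings.tsv")
    write_tsv(region_inf, out / "region_inference.tsv")
    write_tsv(predictor_inf, out / "predictor_inference.tsv")
    from .cpca import percent_of
    vt = cpca.variance_table
    pct = percent_of(vt.loc["predictable", "total"], vt.loc["overall", "total"])
    log.append(f"CPCA: predictors account for {pct}% of overall variance")

    # --- per-region GLMs --------------------------------------------------
    glm_design = design  # transformed, unstandardized
    glm = fit_all_regions(thickness, glm_design, q=config.glm_q,
                          se_type=config.se_type)
    write_tsv(glm, out / "glm_table.tsv")
    n_pain = int(glm[(glm["predictor"] == "pain")]["fdr_significant"].sum())
    log.append(f"GLM: pain FDR-significant in {n_pain}/66 regions")

    if config.ventilated_subset:
        mask = clinical["ventilation_days"].to_numpy() > 0
        glm_vent = fit_all_regions(thickness, glm_design, q=config.glm_q,
                                   se_type=config.se_type, subset=mask)
        glm_vent.attrs["subset"] = "ventilation_days > 0"
        write_tsv(glm_vent, out / "glm_ventilated.tsv")
        log.append(f"ventilated-subset GLM on n={int(mask.sum())}")

    if config.birth_weight_sensitivity:
        design_bw = design.data.copy()
        design_bw["bw"] = clinical["birth_weight"].to_numpy(dtype=float)
        cpca_bw = run_cpca(design_bw, thickness, k_predicted=config.k_predicted,
                           k_residual=config.k_residual,
                           k_overall=config.k_overall)
        pct_raw = vt.loc["predictable", "total_pct_overall"]
        pct_bw = cpca_bw.variance_table.loc["predictable", "total_pct_overall"]
        sens = pd.DataFrame({"model": ["7 predictors", "7 predictors + BW"],
                             "predictable_pct_overall": [pct_raw, pct_bw],
                             "delta_pct": [0.0, pct_bw - pct_raw]})
        write_tsv(sens, out / "sensitivity_bw.tsv")
        log.append(f"+BW sensitivity: predictable {pct_bw:.1f}% "
                   f"({pct_bw - pct_raw:+.1f} points)")

    settings = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()},
                "stage_seeds": seeds, "version": __version__}
    (out / "settings.json").write_text(json.dumps(settings, indent=2))
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out


def render_reports(run_dir) -> str:
    """Human-readable summary shaped like the classic variance-partition,
    loading and significant-region tables."""
    run = Path(run_dir)
    needed = ["variance_table.tsv", "region_inference.tsv", "glm_table.tsv"]
    for name in needed:
        if not (run / name).exists():
            raise ReportError(f"run directory is missing {name}")

    lines = []
    vt = pd.read_csv(run / "variance_table.tsv", sep="\t").set_index("solution")
    comp_cols = [c for c in vt.columns
                 if c.startswith("comp") and not c.endswith(("_pct_overall",
                                                             "_pct_of_row"))]
    lines.append("Variance partition (absolute; % rows in parentheses)")
    header = ["solution", "total", *comp_cols, "retained_sum"]
    lines.append("\t".join(header))
    for sol in ("overall", "predictable", "residual"):
        row = vt.loc[sol]
        vals = [f"{row[c]:.2f}" if pd.notna(row[c]) else "" for c in header[1:]]
        lines.append("\t".join([sol, *vals]))
        pct = [f"({row[f'{c}_pct_overall']:.2f}%)" if pd.notna(row[c]) else ""
               for c in header[1:]]
        lines.append("\t".join([f"% of overall", *pct]))

    inf = pd.read_csv(run / "region_inference.tsv", sep="\t")
    sig = inf[inf["fdr_5pct"]].sort_values(["component", "p"])
    lines.append("")
    lines.append(f"Predicted-solution region loadings with FDR<5% "
                 f"({len(sig)} rows)")
    lines.append("component\tregion\tloading\tp\tci_low\tci_high")
    for _, r in sig.iterrows():
        lines.append(f"{int(r['component'])}\t{r['target']}\t{r['loading']:.2f}"
                     f"\t{r['p']:.4g}\t{r['ci_low']:.2f}\t{r['ci_high']:.2f}")

    glm = pd.read_csv(run / "glm_table.tsv", sep="\t")
    pain = glm[(glm["predictor"] == "pain") & glm["fdr_significant"]]
    pain = pain.sort_values("B")
    lines.append("")
    lines.append(f"Regions with FDR-significant pain coefficients "
                 f"({len(pain)}/66)")
    lines.append("region\tB\tp")
    for _, r in pain.iterrows():
        lines.append(f"{r['region']}\t{r['B']:.2f}\t{r['p']:.4g}")
    return "\n".join(lines) + "\n"
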