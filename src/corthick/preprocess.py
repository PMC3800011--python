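"""Predictor transforms and preliminary screens.

Right-skewed count predictors (skin-breaks, ventilation days) are mapped
through ``log(1 + x)`` — rather than ``log x`` — because both can be zero.
Winsorization replaces values outside mean +/- 3 SD (mean and SD computed on
the column as given, in a single pass) with the nearest other observed value
inside that range, so it never invents values absent from the data.  When a
column is both winsorized and log-transformed, winsorization runs first.

The screens mirror the usual pre-modelling checks on a developmental-imaging
cohort: per-region correlation of thickness with age at scan, and per-region
two-sample t-tests between the sexes, both Bonferroni-corrected across the
66 regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PREDICTORS, predictor_matrix
from .errors import DegenerateDataError, ParameterError, ShapeError
from .regions import REGIONS_66


@dataclass
class DesignMatrix:
    """Subjects x predictors block with a record of applied transforms."""

    data: pd.DataFrame
    transforms: dict[str, list[str]] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def history(self, column: str) -> list[str]:
        return self.transforms.get(column, ["raw"])

    def sidecar_json(self) -> str:
        """Transform provenance, serializable next to the design TSV."""
        return json.dumps({c: self.history(c) for c in self.columns}, indent=2)


def winsorize_column(x: np.ndarray) -> np.ndarray:
    """Replace values beyond mean +/- 3 SD by the nearest in-range observed value.

    Single pass: the mean and SD include any outliers.  Raises if every value
    is out of range (cannot happen for SD > 0 with n >= 2).
    """
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std(ddof=1)
    lo, hi = mu - 3.0 * sd, mu + 3.0 * sd
    inside = (x >= lo) & (x <= hi)
    if inside.all():
        return x.copy()
    if not inside.any():
        raise DegenerateDataError("no observations inside the +/-3 SD band")
    out = x.copy()
    candidates = np.unique(x[inside])
    for i in np.flatnonzero(~inside):
        out[i] = candidates[np.argmin(np.abs(candidates - x[i]))]
    return out


def transform_predictors(table: pd.DataFrame,
                         log_cols: tuple[str, ...] = ("pain", "ventilation"),
                         winsor_cols: tuple[str, ...] = ("ventilation",),
                         ) -> DesignMatrix:
    """Build the 7-column design matrix with the default transform recipe.

    ``table`` is a clinical table (raw columns) or an already-extracted
    predictor frame with columns named as in :data:`PREDICTORS`.
    """
    if set(PREDICTORS).issubset(table.columns):
        pred = table[list(PREDICTORS)].astype(float).copy()
    else:
        pred = predictor_matrix(table)
    unknown = (set(log_cols) | set(winsor_cols)) - set(pred.columns)
    if unknown:
        raise ParameterError(f"unknown predictor columns: {sorted(unknown)}")
    if pred.isna().any().any():
        raise ParameterError("missing values in predictor columns are not supported")

    transforms: dict[str, list[str]] = {c: ["raw"] for c in pred.columns}
    for c in winsor_cols:
        pred[c] = winsorize_column(pred[c].to_numpy())
        transforms[c].append("winsorized")
    for c in log_cols:
        x = pred[c].to_numpy()
        if (x < 0).any():
            raise ParameterError(f"column {c!r} has negative values; log1p undefined")
        pred[c] = np.log1p(x)
        transforms[c].append("log1p")
    return DesignMatrix(data=pred, transforms=transforms)


def zscore_columns(design: DesignMatrix) -> DesignMatrix:
    """Center and scale every column to unit (n-1) variance."""
    df = design.data
    if len(df) < 2:
        raise ParameterError("need at least 2 subjects to z-score")
    out = df.copy()
    transforms = {c: list(design.history(c)) for c in df.columns}
    for c in df.columns:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError(f"zero variance in column {c!r}")
        out[c] = (x - x.mean()) / sd
        transforms[c].append("z-scored")
    return DesignMatrix(data=out, transforms=transforms)


def thickness_values(thickness: pd.DataFrame) -> np.ndarray:
    """Region block of a thickness table as a subjects x regions array."""
    cols = [c for c in thickness.columns if c in REGIONS_66]
    return thickness[cols].to_numpy(dtype=float)


def screen_univariate(thickness: pd.DataFrame, covariate, mode: str,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-region association screen with Bonferroni correction.

    mode='correlation': Pearson r of each region with a numeric covariate.
    mode='two_sample_t': independent t-test between the two covariate groups.
    """
    regions = [c for c in thickness.columns if c in REGIONS_66]
    y = thickness[regions].to_numpy(dtype=float)
    cov = np.asarray(covariate)
    if len(cov) != len(y):
        raise ShapeError("covariate length does not match subject count")
    m = len(regions)

    rows = []
    if mode == "correlation":
        cov = cov.astype(float)
        if cov.std(ddof=1) == 0:
            raise DegenerateDataError("constant covariate: correlation undefined")
        for j, name in enumerate(regions):
            r, p = stats.pearsonr(cov, y[:, j])
            rows.append((name, r, p))
        stat_name = "r"
    elif mode == "two_sample_t":
        groups = pd.unique(cov)
        if len(groups) != 2:
            raise ParameterError(
                f"two_sample_t requires exactly 2 groups, got {len(groups)}")
        g0, g1 = (cov == groups[0]), (cov == groups[1])
        for j, name in enumerate(regions):
            t, p = stats.ttest_ind(y[g0, j], y[g1, j])
            rows.append((name, t, p))
        stat_name = "t"
    else:
        raise ParameterError(f"unknown screen mode {mode!r}")

    report = pd.DataFrame(rows, columns=["region", stat_name, "p"])
    report["p_bonferroni"] = np.minimum(1.0, report["p"] * m)
    report["significant"] = report["p_bonferroni"] < alpha
    report.attrs["m"] = m
    report.attrs["mode"] = mode
    return report
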