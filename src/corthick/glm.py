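"""Per-region generalized linear models of cortical thickness.

One Gaussian identity-link model per region regresses thickness on the seven
neonatal predictors (transformed as in :mod:`corthick.preprocess` but *not*
z-scored, so coefficients are unstandardized: mm change per unit predictor).
A Gaussian/identity GLM is numerically identical to ordinary least squares,
so the fits use OLS; heteroskedasticity-robust (sandwich, HC1) standard
errors are the default, honouring the motivation for a GLM — relaxing the
constant-variance requirement — while model-based standard errors remain
available.

Benjamini-Hochberg FDR at 5% is applied per predictor across the 66 regions
(the correction is "between brain regions"); an all-cells variant pools every
(region, predictor) p-value.  A subset predicate (e.g. ventilated subjects
only) restricts the rows before fitting and is recorded in the table
metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bootstrap import fdr_bh
from .errors import ParameterError, ShapeError
from .regions import REGIONS_66


def fit_region_glm(y, design, se_type: str = "robust") -> pd.DataFrame:
    """Fit one region's thickness on the predictor block.

    Returns a frame with one row per predictor (plus the intercept):
    unstandardized coefficient ``B``, standard error and Wald p-value.
    ``se_type='model'`` gives classical OLS standard errors; ``'robust'``
    gives HC1 sandwich standard errors.
    """
    if se_type not in ("model", "robust"):
        raise ParameterError(f"unknown se_type {se_type!r}")
    x_df = getattr(design, "data", design)
    x = np.asarray(x_df.to_numpy() if hasattr(x_df, "to_numpy") else x_df,
                   dtype=float)
    names = list(x_df.columns) if hasattr(x_df, "columns") else \
        [f"x{i}" for i in range(x.shape[1])]
    yv = np.asarray(y, dtype=float).ravel()
    if len(yv) != x.shape[0]:
        raise ShapeError("y and design must have equal subject counts")
    if len(yv) < x.shape[1] + 2:
        raise ParameterError(
            f"need at least {x.shape[1] + 2} subjects for {x.shape[1]} predictors")
    xc = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [(names[i], names[j])
                 for i in range(len(names)) for j in range(i + 1, len(names))
                 if abs(corr[i, j]) > 1.0 - 1e-10]
        raise ParameterError(f"design matrix is rank deficient; collinear "
                             f"columns: {pairs or names}")
    model = sm.OLS(yv, xc)
    res = model.fit() if se_type == "model" else model.fit(cov_type="HC1")
    return pd.DataFrame({
        "predictor": ["intercept"] + names,
        "B": res.params,
        "se": res.bse,
        "p": res.pvalues,
    }).reset_index(drop=True)


def fit_all_regions(thickness: pd.DataFrame, design, q: float = 0.05,
                    se_type: str = "robust", subset=None,
                    fdr_scope: str = "per_predictor") -> pd.DataFrame:
    """Fit every region and flag FDR-significant cells.

    ``subset`` is an optional boolean mask or a predicate applied to the
    design frame's index positions; it must leave enough subjects to fit.
    Returns a long frame (region x predictor rows) with columns
    ``B, se, p, fdr_significant`` and run metadata in ``.attrs``.
    """
    if not 0.0 < q < 1.0:
        raise ParameterError("q must be in (0, 1)")
    if fdr_scope not in ("per_predictor", "all_cells"):
        raise ParameterError(f"unknown fdr_scope {fdr_scope!r}")
    x_df = getattr(design, "data", design)
    regions = [c for c in thickness.columns if c in REGIONS_66]
    if not regions:  # fall back to all non-id columns (toy inputs)
        regions = [c for c in thickness.columns if c != "subject_id"]
    if len(thickness) != len(x_df):
        raise ShapeError("thickness and design subject counts differ")

    if subset is None:
        mask = np.ones(len(x_df), dtype=bool)
        subset_desc = "all subjects"
    else:
        mask = np.asarray(subset(x_df) if callable(subset) else subset,
                          dtype=bool)
        if mask.shape != (len(x_df),):
            raise ShapeError("subset mask length does not match subject count")
        subset_desc = getattr(subset, "__name__", "custom mask") \
            if callable(subset) else "boolean mask"
    n_sub = int(mask.sum())
    if n_sub == 0:
        raise ParameterError("subset leaves no subjects")
    ncols = x_df.shape[1]
    if n_sub < ncols + 2:
        raise ParameterError(
            f"subset leaves {n_sub} subjects; need at least {ncols + 2}")

    x_sub = x_df.iloc[mask] if hasattr(x_df, "iloc") else x_df[mask]
    rows = []
    for region in regions:
        fit = fit_region_glm(thickness[region].to_numpy()[mask], x_sub,
                             se_type=se_type)
        fit = fit[fit["predictor"] != "intercept"].copy()
        fit.insert(0, "region", region)
        rows.append(fit)
    table = pd.concat(rows, ignore_index=True)

    table["fdr_significant"] = False
    if fdr_scope == "per_predictor":
        for pred in table["predictor"].unique():
            sel = table["predictor"] == pred
            table.loc[sel, "fdr_significant"] = fdr_bh(table.loc[sel, "p"], q)
    else:
        table["fdr_significant"] = fdr_bh(table["p"], q)

    table.attrs.update(family="gaussian", link="identity", se_type=se_type,
                       q=q, fdr_scope=fdr_scope, subset=subset_desc, n=n_sub)
    return table


def significant_regions(table: pd.DataFrame, predictor: str) -> list[str]:
    """Regions FDR-flagged for one predictor, sorted by |B| descending."""
    sel = table[(table["predictor"] == predictor) & table["fdr_significant"]]
    return list(sel.reindex(sel["B"].abs().sort_values(ascending=False).index)
                ["region"])
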