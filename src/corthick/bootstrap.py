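"""Monte-Carlo bootstrap inference for CPCA loadings.

Subjects are resampled with replacement, the full CPCA (including the
external regression and varimax rotation) is rerun on each resample, and the
resampled predicted-solution components are aligned to the full-sample
solution before accumulation — a resampled PCA is only defined up to column
reflection and reordering, so each bootstrap component is greedily matched to
the reference component with which it has the largest |Tucker congruence|
and sign-flipped to positive congruence.

Confidence intervals are percentile intervals.  The default p-value is a
normal approximation (two-sided, point estimate over bootstrap SD): with
1000 replicates a pure sign-proportion p cannot fall below 1/1000, whereas
the normal approximation can resolve smaller tail probabilities; the
sign-proportion method is retained as an option.  Benjamini-Hochberg FDR is
applied across regions within each component (and across predictors within
each component for the predictor-loading table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cpca import CPCAResult, predicted_solution, run_cpca, tucker_congruence
from .errors import CorthickError, InferenceError, ParameterError, ShapeError


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    p_method: str = "normal_approx"  # or "sign_proportion"
    align_method: str = "procrustes"  # or "congruence"
    fdr_q: float = 0.05

    def validate(self) -> None:
        if self.n_reps < 100:
            raise ParameterError("n_reps must be >= 100 for inference output")
        if not 0.0 < self.ci_level < 1.0:
            raise ParameterError("ci_level must be in (0, 1)")
        if self.p_method not in ("normal_approx", "sign_proportion"):
            raise ParameterError(f"unknown p_method {self.p_method!r}")
        if self.align_method not in ("procrustes", "congruence"):
            raise ParameterError(f"unknown align_method {self.align_method!r}")


def align_components(reference: np.ndarray, candidate: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Match candidate columns to reference columns by |Tucker congruence|.

    Greedy: the largest |congruence| pair is matched first.  Returns
    ``(permutation, signs)`` such that ``candidate[:, permutation] * signs``
    is aligned with the reference.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape:
        raise ShapeError(f"reference {ref.shape} and candidate {cand.shape} differ")
    k = ref.shape[1]
    c = np.array([[tucker_congruence(ref[:, i], cand[:, j]) for j in range(k)]
                  for i in range(k)])
    perm = np.empty(k, dtype=int)
    signs = np.empty(k)
    absc = np.abs(c).copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(absc), absc.shape)
        perm[i] = j
        signs[i] = 1.0 if c[i, j] >= 0 else -1.0
        absc[i, :] = -1.0
        absc[:, j] = -1.0
    return perm, signs


def procrustes_rotation(reference: np.ndarray, candidate: np.ndarray
                        ) -> np.ndarray:
    """Orthogonal rotation aligning candidate loadings onto the reference.

    Minimizes ``||candidate @ R - reference||_F`` over orthonormal R.  Unlike
    permutation/sign matching, this removes the full rotational
    indeterminacy within the retained subspace, which otherwise inflates the
    bootstrap spread of individual loadings when eigenvalues are close.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape:
        raise ShapeError(f"reference {ref.shape} and candidate {cand.shape} differ")
    u, _, vt = np.linalg.svd(cand.T @ ref)
    return u @ vt


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _p_values(point: np.ndarray, boots: np.ndarray, method: str,
              n_reps: int) -> np.ndarray:
    """Two-sided p-values for H0: loading = 0, from the bootstrap draws."""
    if method == "normal_approx":
        sd = boots.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, np.abs(point) / sd, np.inf)
        p = 2.0 * stats.norm.sf(z)
        return np.clip(p, np.finfo(float).tiny, 1.0)
    # sign_proportion: fraction of bootstrap mass on each side of zero
    frac_le = (boots <= 0).mean(axis=0)
    frac_ge = (boots >= 0).mean(axis=0)
    p = 2.0 * np.minimum(frac_le, frac_ge)
    return np.clip(p, 1.0 / n_reps, 1.0)


def _inference_table(point: np.ndarray, boots: np.ndarray, names,
                     config: BootstrapConfig, n_valid: int) -> pd.DataFrame:
    """Per-(target, component) loading inference table.

    ``point``: targets x k, ``boots``: reps x targets x k.
    """
    alpha = 1.0 - config.ci_level
    lo = np.quantile(boots, alpha / 2.0, axis=0)
    hi = np.quantile(boots, 1.0 - alpha / 2.0, axis=0)
    k = point.shape[1]
    frames = []
    for j in range(k):
        p = _p_values(point[:, j], boots[:, :, j], config.p_method, n_valid)
        frames.append(pd.DataFrame({
            "target": names,
            "component": j + 1,
            "loading": point[:, j],
            "ci_low": lo[:, j],
            "ci_high": hi[:, j],
            "p": p,
            "fdr_5pct": fdr_bh(p, config.fdr_q),
            "n_valid_reps": n_valid,
        }))
    return pd.concat(frames, ignore_index=True)


def bootstrap_cpca(design, thickness, config: BootstrapConfig,
                   k_predicted: int = 3, k_residual: int = 2,
                   k_overall: int = 3, kaiser: bool = True,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, CPCAResult]:
    """Bootstrap the predicted-solution region and predictor loadings.

    Returns ``(region_table, predictor_table, full_sample_result)``.  Each
    replicate resamples (design, thickness) rows jointly and reruns the
    predicted-solution pipeline from scratch — z-scoring, external
    regression, PCA and varimax included (a full-pipeline bootstrap, not a
    residual bootstrap).  Replicates that collapse (e.g. a resample with a
    constant predictor column) are dropped and counted; more than 20%
    degenerate replicates aborts the inference.
    """
    config.validate()
    x_df = getattr(design, "data", design)
    x_df = x_df if hasattr(x_df, "columns") else pd.DataFrame(np.asarray(x_df))
    if hasattr(thickness, "columns"):
        y_df = thickness.drop(columns=["subject_id"], errors="ignore")
    else:
        y_df = pd.DataFrame(np.asarray(thickness))
    n = len(x_df)
    if n < 10:
        raise ParameterError("bootstrap requires at least 10 subjects")
    if len(y_df) != n:
        raise ShapeError("design and thickness subject counts differ")

    full = run_cpca(x_df, y_df, k_predicted=k_predicted, k_residual=k_residual,
                    k_overall=k_overall, kaiser=kaiser)
    ref_regions = full.solutions["predicted"].loadings
    ref_pred = full.predictor_loadings.to_numpy()

    rng = np.random.default_rng(config.seed)
    xv = x_df.to_numpy(dtype=float)
    yv = y_df.to_numpy(dtype=float)
    boots_r = np.empty((config.n_reps, *ref_regions.shape))
    boots_p = np.empty((config.n_reps, *ref_pred.shape))
    n_valid = 0
    for _ in range(config.n_reps):
        idx = rng.integers(0, n, size=n)
        try:
            loadings, _, ploads = predicted_solution(xv[idx], yv[idx],
                                                     k_predicted, kaiser=kaiser)
        except (CorthickError, np.linalg.LinAlgError):
            continue
        if config.align_method == "procrustes":
            rot = procrustes_rotation(ref_regions, loadings)
            boots_r[n_valid] = loadings @ rot
            boots_p[n_valid] = ploads @ rot
        else:
            perm, signs = align_components(ref_regions, loadings)
            boots_r[n_valid] = loadings[:, perm] * signs
            boots_p[n_valid] = ploads[:, perm] * signs
        n_valid += 1

    if n_valid < 0.8 * config.n_reps:
        raise InferenceError(
            f"{config.n_reps - n_valid}/{config.n_reps} bootstrap replicates "
            "were degenerate (>20%); inference aborted")

    region_table = _inference_table(ref_regions, boots_r[:n_valid],
                                    full.settings["regions"], config, n_valid)
    predictor_table = _inference_table(ref_pred, boots_p[:n_valid],
                                       list(full.predictor_loadings.index),
                                       config, n_valid)
    return region_table, predictor_table, full
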