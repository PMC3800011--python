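"""Constrained principal component analysis (CPCA).

CPCA partitions the variance of a multivariate outcome block (here,
subjects x 66 regional cortical-thickness values) into the part that a set
of predictors can account for and the part it cannot, then examines the
component structure of each part:

* **external analysis** — multivariate least-squares regression of the
  outcome block on the predictor block, producing predicted (fitted) and
  residual matrices that sum to the input and are mutually orthogonal;
* **internal analysis** — a PCA of the overall, predicted and residual
  matrices, each varimax-rotated (with Kaiser normalization) over its
  retained components;
* **predictor loadings** — Pearson correlations between the predicted
  solution's component scores and each predictor, identifying which clinical
  variables drive each predictable-thickness dimension.

Conventions.  PCA uses the column covariance with an n-1 denominator;
loadings carry the variance (the sum of squared loadings of a component
equals its eigenvalue) and scores have unit variance, so per-component
variances are directly comparable with the matrix totals in the variance
partition.  Each component is oriented so its largest-|loading| entry is
positive; rotated components are reordered by decreasing explained variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError, ShapeError

_SOLUTION_LABELS = ("overall", "predicted", "residual")


@dataclass
class ExternalSolution:
    """Predicted/residual decomposition from the multivariate regression."""

    predicted: np.ndarray
    residual: np.ndarray
    hat_rank: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class PCASolution:
    """One internal-analysis PCA, after varimax rotation.

    ``eigenvalues`` are the unrotated top-k covariance eigenvalues;
    ``loadings`` (variables x k) and ``scores`` (subjects x k) are rotated.
    """

    eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    loadings: np.ndarray
    rotation: np.ndarray
    scores: np.ndarray
    k: int
    solution_label: str = ""

    @property
    def component_variances(self) -> np.ndarray:
        """Explained variance per rotated component (column sums of squares)."""
        return (self.loadings ** 2).sum(axis=0)


@dataclass
class CPCAResult:
    external: ExternalSolution
    solutions: dict[str, PCASolution]
    variance_table: pd.DataFrame
    predictor_loadings: pd.DataFrame
    scree: pd.DataFrame
    settings: dict


def external_analysis(design: np.ndarray, thickness: np.ndarray) -> ExternalSolution:
    """Project each outcome column onto the design's column space.

    Expects both blocks column-centered (typically z-scored); the projection
    is then the least-squares fit without an intercept.  Rank-deficient
    designs fall back to the minimum-norm (pseudo-inverse) projection with a
    recorded warning instead of failing.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(thickness, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ShapeError(
            f"design {x.shape} and outcome {y.shape} must share the subject axis")
    rank = np.linalg.matrix_rank(x)
    notes = []
    if rank < x.shape[1]:
        msg = (f"design matrix is rank deficient (rank {rank} < {x.shape[1]} "
               "columns); using minimum-norm projection")
        warnings.warn(msg)
        notes.append(msg)
    beta = np.linalg.pinv(x) @ y
    predicted = x @ beta
    return ExternalSolution(predicted=predicted, residual=y - predicted,
                            hat_rank=int(rank), warnings=notes)


def _orient(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-|loading| entry is positive."""
    loadings = loadings.copy()
    scores = scores.copy()
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return loadings, scores


def pca_svd(matrix: np.ndarray, k: int, label: str = "") -> PCASolution:
    """Unrotated covariance PCA of a subjects x variables matrix.

    Eigenvalues use the n-1 denominator; loadings are scaled so each
    component's sum of squared loadings equals its eigenvalue, and scores
    have unit variance.  The matrix is column-centered internally.
    """
    m = np.asarray(matrix, dtype=float)
    n, p = m.shape
    if not 1 <= k <= min(n - 1, p):
        raise ParameterError(f"k={k} must be in [1, min(n-1, p)] = "
                             f"[1, {min(n - 1, p)}]")
    mc = m - m.mean(axis=0)
    u, s, vt = np.linalg.svd(mc, full_matrices=False)
    eig_all = s ** 2 / (n - 1)
    scale = s[:k] / np.sqrt(n - 1)
    # guard exact-zero singular values (rank < k is allowed but scores are 0)
    safe = np.where(s[:k] > 0, s[:k], 1.0)
    loadings = vt[:k].T * scale
    scores = u[:, :k] * np.sqrt(n - 1) * (s[:k] / safe)
    loadings, scores = _orient(loadings, scores)
    return PCASolution(eigenvalues=eig_all[:k].copy(), all_eigenvalues=eig_all,
                       loadings=loadings, rotation=np.eye(k), scores=scores,
                       k=k, solution_label=label)


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    b2 = np.asarray(loadings) ** 2
    return float(np.sum(b2.var(axis=0)))


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-12,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, orthonormal rotation).

    With ``kaiser=True``, rows are normalized by their communality before
    optimizing and denormalized afterwards (zero-communality rows are left
    out of the normalization with a warning).  k=1 is returned unchanged.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ShapeError("loadings must be a 2-D variables x components array")
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)

    comm = np.sqrt((L ** 2).sum(axis=1))
    if kaiser:
        zero = comm <= 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-communality rows excluded "
                          "from Kaiser normalization")
        scale = np.where(comm > 0, comm, 1.0)
        A = L / scale[:, None]
    else:
        A = L.copy()

    R = np.eye(k)
    last = 0.0
    for _ in range(max_iter):
        B = A @ R
        grad = A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        obj = s.sum()
        if obj < last * (1.0 + tol) + tol:
            break
        last = obj

    rotated = (A @ R)
    if kaiser:
        rotated = rotated * scale[:, None]
    return rotated, R


def rotate_solution(sol: PCASolution, kaiser: bool = True) -> PCASolution:
    """Varimax-rotate a PCA solution, reordering components by variance.

    The returned ``rotation`` includes the reordering and sign orientation,
    so ``unrotated.loadings @ rotation == rotated.loadings`` holds exactly.
    """
    rotated, R = varimax(sol.loadings, kaiser=kaiser)
    scores = sol.scores @ R
    order = np.argsort(-(rotated ** 2).sum(axis=0))
    rotated, scores, R = rotated[:, order], scores[:, order], R[:, order]
    signs = np.array([1.0 if col[np.argmax(np.abs(col))] >= 0 else -1.0
                      for col in rotated.T])
    rotated = rotated * signs
    scores = scores * signs
    R = R * signs
    return PCASolution(eigenvalues=sol.eigenvalues, all_eigenvalues=sol.all_eigenvalues,
                       loadings=rotated, rotation=R, scores=scores, k=sol.k,
                       solution_label=sol.solution_label)


def variance_partition(ext: ExternalSolution, pcas: dict) -> pd.DataFrame:
    """Variance-partition summary table.

    Rows: overall / predictable / residual.  Columns: total variance,
    per-component rotated variances, retained sum, plus percent-of-row and
    percent-of-overall derivations.
    """
    for label in _SOLUTION_LABELS:
        if label not in pcas:
            raise ParameterError(f"missing PCA solution for {label!r}")

    overall = ext.predicted + ext.residual
    totals = {
        "overall": _total_variance(overall),
        "predictable": _total_variance(ext.predicted),
        "residual": _total_variance(ext.residual),
    }
    key = {"overall": "overall", "predictable": "predicted", "residual": "residual"}

    rows = []
    kmax = max(p.k for p in pcas.values())
    for name, total in totals.items():
        comp = pcas[key[name]].component_variances
        row = {"solution": name, "total": total}
        for j in range(kmax):
            row[f"comp{j + 1}"] = comp[j] if j < len(comp) else np.nan
        row["retained_sum"] = comp.sum()
        rows.append(row)
    table = pd.DataFrame(rows).set_index("solution")

    ov = table.loc["overall", "total"]
    value_cols = [c for c in table.columns]
    pct_overall = table[value_cols] / ov * 100.0
    pct_row = table[value_cols].div(table["total"], axis=0) * 100.0
    for c in value_cols:
        table[f"{c}_pct_overall"] = pct_overall[c]
        table[f"{c}_pct_of_row"] = pct_row[c]
    return table


def _total_variance(matrix: np.ndarray) -> float:
    return float(np.var(matrix, axis=0, ddof=1).sum())


def percent_of(part: float, whole: float, decimals: int = 1) -> float:
    """Share of ``part`` in ``whole`` as a percentage rounded for reporting."""
    if whole == 0:
        raise ParameterError("whole must be nonzero")
    return round(100.0 * part / whole, decimals)


def predictor_loadings(scores: np.ndarray, design: pd.DataFrame | np.ndarray
                       ) -> pd.DataFrame:
    """Pearson correlation of each predictor with each component score."""
    if hasattr(design, "to_numpy"):
        x = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) \
            else design.to_numpy()
        names = list(design.columns) if isinstance(design, pd.DataFrame) else \
            [f"x{i}" for i in range(x.shape[1])]
    else:
        x = np.asarray(design, dtype=float)
        names = [f"x{i}" for i in range(x.shape[1])]
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != x.shape[0]:
        raise ShapeError("scores and design must have equal subject counts")
    if (s.std(ddof=1, axis=0) == 0).any() or (x.std(ddof=1, axis=0) == 0).any():
        raise DegenerateDataError("constant score or predictor column: "
                                  "correlation undefined")
    sc = (s - s.mean(axis=0)) / s.std(ddof=1, axis=0)
    xc = (x - x.mean(axis=0)) / x.std(ddof=1, axis=0)
    corr = xc.T @ sc / (len(s) - 1)
    return pd.DataFrame(corr, index=names,
                        columns=[f"comp{j + 1}" for j in range(s.shape[1])])


def run_cpca(design, thickness, k_predicted: int = 3, k_residual: int = 2,
             k_overall: int = 3, kaiser: bool = True,
             standardize: bool = True,
             region_names: list[str] | None = None) -> CPCAResult:
    """Full CPCA: external regression, three rotated PCAs, variance partition
    and predictor loadings.

    ``design``/``thickness`` may be DataFrames (or a
    :class:`~corthick.preprocess.DesignMatrix`) or plain arrays.  With
    ``standardize=True`` (default) both blocks are z-scored (n-1 SD) before
    the analysis, so loadings are on the correlation scale.
    """
    x_df = getattr(design, "data", design)
    x = np.asarray(x_df.to_numpy() if hasattr(x_df, "to_numpy") else x_df, dtype=float)
    pred_names = list(x_df.columns) if hasattr(x_df, "columns") else \
        [f"x{i}" for i in range(x.shape[1])]

    if hasattr(thickness, "columns"):
        region_names = region_names or [c for c in thickness.columns
                                        if c != "subject_id"]
        y = thickness[region_names].to_numpy(dtype=float)
    else:
        y = np.asarray(thickness, dtype=float)
        region_names = region_names or [f"region{j}" for j in range(y.shape[1])]

    if standardize:
        x = _zscore_or_raise(x, pred_names)
        y = _zscore_or_raise(y, region_names)

    ext = external_analysis(x, y)
    raw = {
        "overall": pca_svd(y, k_overall, "overall"),
        "predicted": pca_svd(ext.predicted, k_predicted, "predicted"),
        "residual": pca_svd(ext.residual, k_residual, "residual"),
    }
    sols = {label: rotate_solution(sol, kaiser=kaiser) for label, sol in raw.items()}
    table = variance_partition(ext, sols)
    ploads = predictor_loadings(sols["predicted"].scores,
                                pd.DataFrame(x, columns=pred_names))
    scree = pd.DataFrame({
        label: pd.Series(sol.all_eigenvalues) for label, sol in sols.items()
    })
    settings = dict(k_predicted=k_predicted, k_residual=k_residual,
                    k_overall=k_overall, kaiser=kaiser, standardize=standardize,
                    n_subjects=int(y.shape[0]), regions=list(region_names),
                    predictors=pred_names, external_warnings=ext.warnings)
    return CPCAResult(external=ext, solutions=sols, variance_table=table,
                      predictor_loadings=ploads, scree=scree, settings=settings)


def _zscore_or_raise(m: np.ndarray, names) -> np.ndarray:
    sd = m.std(ddof=1, axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateDataError(
            f"zero variance in column(s) {[names[i] for i in bad]}")
    return (m - m.mean(axis=0)) / sd


def predicted_solution(x: np.ndarray, y: np.ndarray, k: int,
                       kaiser: bool = True
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Light-weight core of one CPCA predicted solution.

    z-scores both blocks, projects y onto x's column space, extracts and
    varimax-rotates the k-component PCA of the predicted matrix, and
    correlates the component scores with the predictors.  This is the exact
    sequence :func:`run_cpca` performs for the predicted solution, without
    the overall/residual solutions and report tables; the bootstrap reruns
    it on every resample.  Returns (region loadings, scores, predictor
    loadings).
    """
    x = _zscore_or_raise(np.asarray(x, dtype=float), range(x.shape[1]))
    y = _zscore_or_raise(np.asarray(y, dtype=float), range(y.shape[1]))
    try:
        beta = np.linalg.solve(x.T @ x, x.T @ y)
    except np.linalg.LinAlgError:
        beta = np.linalg.pinv(x) @ y
    predicted = x @ beta
    sol = rotate_solution(pca_svd(predicted, k, "predicted"), kaiser=kaiser)
    s = sol.scores
    ssd = s.std(ddof=1, axis=0)
    if (ssd == 0).any():
        raise DegenerateDataError("constant component score in replicate")
    sc = (s - s.mean(axis=0)) / ssd
    ploads = x.T @ sc / (len(x) - 1)  # x is already z-scored
    return sol.loadings, sol.scores, ploads


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two loading vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
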