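"""COMPARE: logistic-regression sparse-matrix completion of methylation
tendencies.

The model assigns every cell ``(i, j)`` of an aggregation matrix a
*methylation tendency* — the probability that position ``j`` of region
``i`` would be methylated if it carried a CpG — via a column-specific
logistic regression on three leave-one-out row features:

``B``  1 iff the rest of the row (or block window) has no observed value,
``X``  the leave-one-out row mean (0 when ``B = 1``),
``Y``  the leave-one-out proportion of missing cells.

For column ``j`` with coefficients ``(b_j, x_j, y_j, z_j)``::

    M_ij = 1 / (1 + exp(-(b_j B_ij + x_j X_ij + y_j Y_ij + z_j)))

fitted by maximizing a fractional-response (quasi-binomial)
cross-entropy over the column's observed cells, with a small ridge
penalty on the slope terms for stability on separable columns.  Columns
with fewer than ``min_obs`` observations (default 10) are left unfitted.
Because ``Y`` enters the prediction, the inferred tendencies are
decoupled from CpG availability, removing the Yule-Simpson bias from
any downstream ``C``/``R``/``M`` comparison.

Every fit also runs a 10-fold per-column cross-validation: held-out
observed values are predicted from models trained on the remaining
cells, and the pooled (observed, inferred) pairs are scored with a
total-least-squares line — the first principal component of the centered
(but not standardized) point cloud — whose slope should be near 1 for a
well-calibrated model.  Both observed and inferred values carry error,
which is why a perpendicular-distance line is used rather than ordinary
regression.

The public surface follows the Model/Results convention:
``CompareModel(matrix).fit()`` returns a :class:`CompareResults` with the
coefficient table, the completed matrix, the CV report and a
``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .errors import ConvergenceError, ValidationError
from .matrix import AggregationMatrix, SummaryStats, summary_stats

__all__ = [
    "CompareFeatures", "ColumnModel", "CVReport", "CompareResults",
    "CompareModel", "compute_features", "fit_column", "predict_cell",
    "complete_matrix", "cross_validate", "fit_fractional_logistic",
    "tls_line",
]


@dataclass
class CompareFeatures:
    """Per-cell feature grids ``B``, ``X``, ``Y`` (each ``n x m``)."""

    B: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    block: int = None  # half-width in columns; None = whole row

    def design(self, rows, j) -> np.ndarray:
        """Design matrix ``[B, X, Y, 1]`` for the given rows of column j."""
        return np.column_stack([
            self.B[rows, j], self.X[rows, j], self.Y[rows, j],
            np.ones_like(self.B[rows, j], dtype=float)])


def compute_features(matrix: AggregationMatrix,
                     block: int = None) -> CompareFeatures:
    """Leave-one-out row features for every cell.

    ``block`` restricts the row to a window of columns within ``block``
    columns of the target column (truncated at the matrix edges) before
    excluding the target cell; ``None`` uses the whole row.  At site
    resolution one column is one base pair, so ``block=100`` reproduces
    the "restricted region around each relative location (e.g. 100 bp)"
    meta-region mode.
    """
    mask = matrix.mask
    vals = np.where(mask, matrix.values, 0.0)
    n, m = mask.shape

    if block is None:
        lo = np.zeros(m, dtype=int)
        hi = np.full(m, m, dtype=int)
    else:
        if block < 1:
            raise ValidationError("block must be >= 1 column")
        j = np.arange(m)
        lo = np.maximum(0, j - block)
        hi = np.minimum(m, j + block + 1)

    cs_mask = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(mask, axis=1)], axis=1)
    cs_vals = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(vals, axis=1)], axis=1)

    win_cnt = cs_mask[:, hi] - cs_mask[:, lo]          # (n, m)
    win_sum = cs_vals[:, hi] - cs_vals[:, lo]
    cnt_excl = win_cnt - mask
    sum_excl = win_sum - vals
    cells_excl = (hi - lo - 1).astype(float)[None, :]  # window size minus j

    B = (cnt_excl == 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(B == 1, 0.0,
                     sum_excl / np.maximum(cnt_excl, 1))
        Y = np.where(cells_excl > 0,
                     (cells_excl - cnt_excl) / np.maximum(cells_excl, 1),
                     1.0)
    return CompareFeatures(B=B, X=X, Y=Y, block=block)


# ---------------------------------------------------------------------------
# Fractional-response logistic fit
# ---------------------------------------------------------------------------

_PENALIZED = np.array([1.0, 1.0, 1.0, 0.0])  # ridge on (b, x, y), not z


def fit_fractional_logistic(y, D, ridge: float = 1e-6, weights=None,
                            tol: float = 1e-8, max_iter: int = 100):
    """Maximize the fractional-response cross-entropy likelihood.

    ``y`` holds rates in [0, 1] treated as fractional successes under a
    logistic mean ``expit(D @ beta)``; ``weights`` (e.g. read coverage)
    scale each observation's contribution.  Newton/IRLS with step
    halving, falling back to L-BFGS-B when the Newton system is
    ill-conditioned.  Returns ``(beta, n_iter, converged)``; raises
    :class:`~methcompare.errors.ConvergenceError` if both strategies
    fail to produce finite coefficients.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(D, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    pen = ridge * _PENALIZED[: D.shape[1]]

    def objective(beta):
        eta = D @ beta
        # -sum w*(y*eta - log(1 + e^eta)), stable via logaddexp
        nll = -np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
        return nll + 0.5 * np.sum(pen * beta ** 2)

    def gradient(beta):
        mu = expit(D @ beta)
        return D.T @ (w * (mu - y)) + pen * beta

    p0 = np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6)
    beta = np.zeros(D.shape[1])
    beta[-1] = logit(p0)

    obj = objective(beta)
    converged = False
    for it in range(1, max_iter + 1):
        mu = expit(D @ beta)
        wt = w * mu * (1.0 - mu)
        H = D.T @ (D * wt[:, None]) + np.diag(pen)
        g = gradient(beta)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # backtracking line search
        t = 1.0
        new_obj = objective(beta + t * step)
        halvings = 0
        while not (np.isfinite(new_obj) and new_obj <= obj + 1e-12) \
                and halvings < 30:
            t *= 0.5
            halvings += 1
            new_obj = objective(beta + t * step)
        if not np.isfinite(new_obj):
            break
        beta = beta + t * step
        if abs(obj - new_obj) <= tol * (1.0 + abs(new_obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if converged and np.all(np.isfinite(beta)):
        return beta, it, True

    res = optimize.minimize(objective, beta, jac=gradient,
                            method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12})
    if not np.all(np.isfinite(res.x)):
        raise ConvergenceError("logistic fit produced non-finite "
                               "coefficients")
    return res.x, max_iter, bool(res.success)


@dataclass
class ColumnModel:
    """Fitted logistic coefficients for one matrix column."""

    j: int
    n_obs: int
    fitted: bool
    b: float = float("nan")
    x: float = float("nan")
    y: float = float("nan")
    z: float = float("nan")

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.b, self.x, self.y, self.z])


def fit_column(j: int, features: CompareFeatures,
               matrix: AggregationMatrix, min_obs: int = 10,
               ridge: float = 1e-6, weights=None) -> ColumnModel:
    """Fit one column's model on its observed cells.

    Columns with fewer than ``min_obs`` observations are returned with
    ``fitted=False`` — too few training points for a stable
    position-specific inference.  ``weights`` optionally supplies an
    ``n``-vector of per-row observation weights (e.g. read coverage).
    """
    obs = np.flatnonzero(matrix.mask[:, j])
    n_obs = obs.size
    if n_obs < min_obs:
        return ColumnModel(j=j, n_obs=n_obs, fitted=False)
    y = matrix.values[obs, j]
    D = features.design(obs, j)
    w = None if weights is None else np.asarray(weights, float)[obs]
    try:
        beta, _, _ = fit_fractional_logistic(y, D, ridge=ridge, weights=w)
    except ConvergenceError as exc:
        raise ConvergenceError(f"column {j}: {exc}") from None
    return ColumnModel(j=j, n_obs=n_obs, fitted=True,
                       b=float(beta[0]), x=float(beta[1]),
                       y=float(beta[2]), z=float(beta[3]))


def predict_cell(model: ColumnModel, B, X, Y):
    """Evaluate the logistic completion formula; strictly in (0, 1)."""
    if not model.fitted:
        raise ValidationError(f"column {model.j} model is not fitted")
    return expit(model.b * np.asarray(B) + model.x * np.asarray(X)
                 + model.y * np.asarray(Y) + model.z)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def tls_line(x, y):
    """Total-least-squares line through centered points.

    Returns ``(slope, variance_explained)`` where the line is the first
    principal component of the centered two-dimensional cloud (raw axes,
    no standardization) and ``variance_explained`` is the share of total
    variance along it, i.e. ``1 - perpendicular SS / total SS``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    S = np.array([[xc @ xc, xc @ yc],
                  [xc @ yc, yc @ yc]])
    evals, evecs = np.linalg.eigh(S)
    total = evals.sum()
    if total <= 0:
        return float("nan"), float("nan")
    v = evecs[:, -1]  # largest eigenvalue
    slope = float(v[1] / v[0]) if v[0] != 0 else float("inf")
    return slope, float(evals[-1] / total)


@dataclass
class CVReport:
    """Pooled 10-fold cross-validation diagnostics.

    ``observed``/``inferred`` hold every observed cell of each
    cross-validated column exactly once.  ``tls_slope`` near 1 and a
    high ``variance_explained`` indicate calibrated inferences; the
    variance-explained formalization (first-PC eigenvalue share) is this
    package's reading of "variance explained compared to a random line".
    """

    fold_count: int
    observed: np.ndarray = field(repr=False)
    inferred: np.ndarray = field(repr=False)
    tls_slope: float
    variance_explained: float
    seed: object
    skipped_columns: list

    @property
    def n_pairs(self) -> int:
        return int(self.observed.size)

    @property
    def pooled_pairs(self) -> pd.DataFrame:
        return pd.DataFrame({"observed": self.observed,
                             "inferred": self.inferred})

    @property
    def pearson_r(self) -> float:
        if self.observed.size < 2:
            return float("nan")
        return float(np.corrcoef(self.observed, self.inferred)[0, 1])


def cross_validate(matrix: AggregationMatrix, block: int = None, k: int = 10,
                   seed=None, min_obs: int = 10,
                   ridge: float = 1e-6, weights=None,
                   features: CompareFeatures = None) -> CVReport:
    """Per-column k-fold CV of the completion model.

    Each column's observed cells are split into ``k`` folds (assignment
    drawn from a per-column generator spawned from one master seed);
    each fold is predicted by a model trained on the remaining cells.
    Columns that would leave fewer than ``min_obs`` training points in
    some fold are skipped with a warning.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if features is None:
        features = compute_features(matrix, block=block)
    m = matrix.m
    children = np.random.SeedSequence(seed).spawn(m)
    obs_all, inf_all, skipped = [], [], []
    for j in range(m):
        obs = np.flatnonzero(matrix.mask[:, j])
        if obs.size < min_obs:
            continue
        folds = np.array_split(
            np.random.default_rng(children[j]).permutation(obs),
            min(k, obs.size))
        max_fold = max(len(f) for f in folds)
        if obs.size - max_fold < min_obs:
            skipped.append(j)
            warnings.warn(
                f"column {j}: a fold would leave fewer than "
                f"{min_obs} training points; column skipped in CV")
            continue
        w = None if weights is None else np.asarray(weights, float)
        for fold in folds:
            train = np.setdiff1d(obs, fold, assume_unique=True)
            ytr = matrix.values[train, j]
            Dtr = features.design(train, j)
            wtr = None if w is None else w[train]
            beta, _, _ = fit_fractional_logistic(ytr, Dtr, ridge=ridge,
                                                 weights=wtr)
            Dte = features.design(fold, j)
            inf_all.append(expit(Dte @ beta))
            obs_all.append(matrix.values[fold, j])
    if not obs_all:
        raise ValidationError("no column eligible for cross-validation")
    observed = np.concatenate(obs_all)
    inferred = np.concatenate(inf_all)
    slope, ve = tls_line(observed, inferred)
    return CVReport(fold_count=k, observed=observed, inferred=inferred,
                    tls_slope=slope, variance_explained=ve, seed=seed,
                    skipped_columns=skipped)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class CompareModel:
    """Column-wise logistic completion model for one aggregation matrix.

    Parameters
    ----------
    matrix : AggregationMatrix
        The sparse matrix to complete.
    block : int, optional
        Half-width of the feature window in columns; ``None`` (default)
        uses the whole row.
    min_obs : int
        Minimum observed cells for a column to be fitted (default 10).
    ridge : float
        L2 penalty on the slope coefficients (default 1e-6); keeps
        coefficients finite on separable columns.
    weights : array-like, optional
        Per-row observation weights (e.g. read coverage); unweighted by
        default.
    """

    def __init__(self, matrix: AggregationMatrix, block: int = None,
                 min_obs: int = 10, ridge: float = 1e-6, weights=None):
        if min_obs < 1:
            raise ValidationError("min_obs must be >= 1")
        self.matrix = matrix
        self.block = block
        self.min_obs = min_obs
        self.ridge = ridge
        self.weights = None if weights is None \
            else np.asarray(weights, float)
        self.features = compute_features(matrix, block=block)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "CompareModel":
        from .io import read_matrix
        return cls(read_matrix(path), **kwargs)

    def fit(self, cv_folds: int = 10, seed=None,
            keep_observed: bool = False) -> "CompareResults":
        """Fit every eligible column and complete the matrix.

        ``cv_folds >= 2`` also runs the cross-validation analysis in the
        same call (set ``cv_folds=0`` to skip it).  With
        ``keep_observed=True`` observed cells retain their measured
        values in the completed matrix; by default the model predicts at
        every cell of a fitted column.
        """
        mat = self.matrix
        models = [fit_column(j, self.features, mat, min_obs=self.min_obs,
                             ridge=self.ridge, weights=self.weights)
                  for j in range(mat.m)]
        if not any(cm.fitted for cm in models):
            raise ValidationError(
                f"no column has >= {self.min_obs} observations; "
                "nothing to fit")

        completed = np.full((mat.n, mat.m), np.nan)
        all_rows = np.arange(mat.n)
        for cm in models:
            if not cm.fitted:
                continue
            D = self.features.design(all_rows, cm.j)
            completed[:, cm.j] = expit(D @ cm.coef)
            if keep_observed:
                obs = mat.mask[:, cm.j]
                completed[obs, cm.j] = mat.values[obs, cm.j]

        cv = None
        if cv_folds and cv_folds >= 2:
            cv = cross_validate(mat, block=self.block, k=cv_folds,
                                seed=seed, min_obs=self.min_obs,
                                ridge=self.ridge, weights=self.weights,
                                features=self.features)
        return CompareResults(model=self, column_models=models,
                              completed=AggregationMatrix(
                                  completed,
                                  row_labels=list(mat.row_labels),
                                  orientation=mat.orientation),
                              cv=cv, keep_observed=keep_observed)


@dataclass
class CompareResults:
    """Estimates from a :class:`CompareModel` fit."""

    model: CompareModel
    column_models: list
    completed: AggregationMatrix
    cv: CVReport
    keep_observed: bool = False

    @property
    def params(self) -> pd.DataFrame:
        """Per-column coefficient table."""
        return pd.DataFrame(
            [{"column": cm.j, "n_obs": cm.n_obs, "fitted": cm.fitted,
              "b": cm.b, "x": cm.x, "y": cm.y, "z": cm.z}
             for cm in self.column_models]).set_index("column")

    @property
    def n_fitted_columns(self) -> int:
        return sum(cm.fitted for cm in self.column_models)

    def predict(self, B, X, Y, j: int):
        """Tendency for arbitrary features under column ``j``'s model."""
        return predict_cell(self.column_models[j], B, X, Y)

    def naive_stats(self) -> SummaryStats:
        return summary_stats(self.model.matrix)

    def completed_stats(self) -> SummaryStats:
        return summary_stats(self.completed)

    def summary(self) -> str:
        mat = self.model.matrix
        naive = self.naive_stats()
        corr = self.completed_stats()
        lines = [
            "COMPARE logistic matrix completion",
            "=" * 50,
            f"matrix              : {mat.n} regions x {mat.m} positions, "
            f"{mat.n_observed} observed",
            f"block               : "
            f"{self.model.block if self.model.block else 'whole-row'}",
            f"min_obs / ridge     : {self.model.min_obs} / "
            f"{self.model.ridge:g}",
            f"fitted columns      : {self.n_fitted_columns} / {mat.m}",
            "",
            f"naive     C={naive.C:.4f}  R={naive.R:.4f}  M={naive.M:.4f}",
            f"completed C={corr.C:.4f}  R={corr.R:.4f}  M={corr.M:.4f}",
        ]
        if self.cv is not None:
            lines += [
                "",
                f"{self.cv.fold_count}-fold CV ({self.cv.n_pairs} pairs)"
                f": TLS slope = {self.cv.tls_slope:.4f}, "
                f"variance explained = {self.cv.variance_explained:.4f}, "
                f"Pearson r = {self.cv.pearson_r:.4f}",
            ]
        lines += ["", "per-column coefficients:",
                  self.params.to_string(float_format=lambda v: f"{v: .4f}")]
        return "\n".join(lines) + "\n"


def complete_matrix(matrix: AggregationMatrix, block: int = None,
                    min_obs: int = 10, seed=None, ridge: float = 1e-6,
                    cv_folds: int = 10,
                    keep_observed: bool = False) -> CompareResults:
    """Functional shorthand for ``CompareModel(matrix, ...).fit(...)``."""
    return CompareModel(matrix, block=block, min_obs=min_obs,
                        ridge=ridge).fit(cv_folds=cv_folds, seed=seed,
                                         keep_observed=keep_observed)
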