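"""Penalized regression suite with repeated, nested cross-validation.

The model family is the elastic net under the fixed objective convention

    (1/N) * ||y - b0 - X b||_2^2  +  lam * [ a*||b||_1 + (1-a)*||b||_2^2 ]

with mixing a in [0, 1] (a = 0 ridge, a = 1 LASSO). The penalty strength
``lam`` is chosen by the one-standard-error rule on a k-fold
cross-validation curve over a 100-point log-spaced grid from ``lam_max``
down to ``lam_max * 1e-3``. Least-angle regression (LARS) and random
forests are provided as benchmarks.

The inner coordinate-descent / ridge solvers are delegated to
scikit-learn; the mapping between the convention above and scikit-learn's
parametrization is

    alpha_sklearn = lam * (1 - a/2),    l1_ratio = a / (2 - a)

which the unit tests verify against closed-form and quadratic-programming
oracles derived directly from the objective.

``repeated_cv_evaluate`` is the evaluation engine used throughout: R
repeats of k-fold cross-validation, each repeat pooling out-of-fold
predictions into one RMSE and one adjusted R^2. Standardization statistics
and the penalty strength are computed inside each training split only, so
no information from held-out subjects leaks into a fit. Fold partitions
depend only on the master seed and the repeat index, never on the feature
columns — this makes paired comparisons between feature sets (common
random numbers) exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge, enet_path, lars_path
from sklearn.model_selection import KFold

from .features import ScalingRecord, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "FitResult",
    "CVResult",
    "fit_elastic_net",
    "lambda_max",
    "lambda_grid",
    "choose_lambda_1se",
    "lambda_path_cv",
    "fit_lars",
    "fit_random_forest",
    "adjusted_r2",
    "repeated_cv_evaluate",
]


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty: mixing ``alpha`` in [0,1], strength ``lam`` >= 0."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class FitResult:
    """One penalized fit on standardized features."""

    intercept: float
    coefficients: pd.Series
    penalty: PenaltySpec | None = None
    scaling: ScalingRecord | None = None

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(self.coefficients.index[self.coefficients != 0.0])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients.index)
        Xa = np.ascontiguousarray(X[cols].to_numpy(dtype=float))
        return self.intercept + Xa @ self.coefficients.to_numpy()

    def raw_scale(self) -> tuple[float, pd.Series]:
        """Intercept and coefficients on the original (unstandardized) scale."""
        if self.scaling is None:
            return self.intercept, self.coefficients
        return self.scaling.inverse_transform_coefficients(
            self.intercept, self.coefficients
        )


def _sklearn_penalty(alpha: float, lam: float) -> tuple[float, float]:
    """Map (alpha, lam) of the package's objective onto scikit-learn's
    (alpha, l1_ratio). Exact algebraic correspondence; alpha > 0 only."""
    return lam * (1.0 - alpha / 2.0), alpha / (2.0 - alpha)


def fit_elastic_net(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    spec: PenaltySpec,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> FitResult:
    """Minimize the stated elastic-net objective at a fixed penalty.

    ``X`` should be standardized (see :func:`reachrank.features.standardize`);
    the intercept is always unpenalized. Raises ``RuntimeError`` if the
    coordinate-descent solver reports non-convergence at ``max_iter``.
    """
    Xa = np.ascontiguousarray(X.to_numpy(dtype=float))
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if Xa.shape[0] != n or n < 3:
        raise ValueError("X rows must match y and n must be >= 3")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("X must be all-finite")

    if spec.lam == 0.0 or spec.alpha == 0.0:
        # pure ridge (or OLS at lam=0): closed-form solver, exact
        model = Ridge(alpha=n * spec.lam * (1 - spec.alpha), solver="svd")
        model.fit(Xa, ya)
    else:
        a_skl, l1 = _sklearn_penalty(spec.alpha, spec.lam)
        model = ElasticNet(alpha=a_skl, l1_ratio=l1, tol=tol, max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(Xa, ya)
            except ConvergenceWarning as w:  # pragma: no cover - defensive
                raise RuntimeError(f"elastic net failed to converge: {w}") from w
    coefs = pd.Series(model.coef_, index=X.columns)
    return FitResult(float(model.intercept_), coefs, penalty=spec)


def lambda_max(X: pd.DataFrame | np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty that zeroes every coefficient:
    max_j |2 x_j'(y - ybar)| / (N * alpha), with alpha floored at 0.01 so
    ridge-like mixings still get a finite grid anchor."""
    Xa = np.ascontiguousarray(np.asarray(X, dtype=float))
    ya = np.asarray(y, dtype=float)
    r = ya - ya.mean()
    return float(np.max(np.abs(2.0 * Xa.T @ r)) / (len(ya) * max(alpha, 0.01)))


def lambda_grid(
    lam_max: float, n_lambdas: int = 100, min_ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced penalty grid from lam_max to lam_max*min_ratio."""
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def choose_lambda_1se(
    grid: np.ndarray, mean_error: np.ndarray, se: np.ndarray
) -> float:
    """One-standard-error rule: the largest penalty whose mean CV error is
    within one standard error of the minimum mean error."""
    grid = np.asarray(grid, dtype=float)
    mean_error = np.asarray(mean_error, dtype=float)
    i_min = int(np.nanargmin(mean_error))
    threshold = mean_error[i_min] + se[i_min]
    ok = np.nonzero(mean_error <= threshold)[0]
    return float(grid[ok[np.argmax(grid[ok])]])


def _enet_coef_path(
    Xc: np.ndarray, yc: np.ndarray, alpha: float, lams: np.ndarray
) -> np.ndarray:
    """(p, n_lambdas) coefficient path for centered data at the given
    penalties, under the package's objective convention."""
    if alpha == 0.0:
        # ridge path via one SVD: b = V diag(s/(s^2 + N*lam)) U' y
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        uty = U.T @ yc
        n = len(yc)
        coefs = np.empty((Xc.shape[1], len(lams)))
        for i, lam in enumerate(lams):
            coefs[:, i] = Vt.T @ (s / (s**2 + n * lam) * uty)
        return coefs
    a_skl = lams * (1.0 - alpha / 2.0)
    l1 = alpha / (2.0 - alpha)
    with warnings.catch_warnings():
        # the smallest grid penalties on p > n designs legitimately stop at
        # max_iter; the 1-SE rule never selects down there
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(Xc, yc, l1_ratio=l1, alphas=a_skl)
    return coefs


def lambda_path_cv(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha: float,
    k: int = 4,
    seed: int = 0,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """k-fold cross-validation curve over the penalty grid.

    Within each fold the features are re-standardized on that fold's
    training rows. Returns (grid, mean fold MSE, standard error, chosen
    lambda by the 1-SE rule). Folds whose training outcome is constant are
    skipped with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ya = np.asarray(y, dtype=float)
    Xs_all, _ = standardize(X)
    grid = lambda_grid(lambda_max(Xs_all, ya, alpha), n_lambdas, min_ratio)

    kf = KFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    fold_mse = []
    for train, test in kf.split(np.arange(len(ya))):
        if np.ptp(ya[train]) == 0:
            logger.warning("degenerate CV fold (constant outcome); skipped")
            continue
        Xs, _ = standardize(X, X.index[train])
        # C-contiguous copies: reduction order must not depend on the
        # parent table's block layout (paired-arm bit reproducibility)
        Xtr = np.ascontiguousarray(Xs.iloc[train].to_numpy())
        Xte = np.ascontiguousarray(Xs.iloc[test].to_numpy())
        ytr = ya[train]
        mu_x = Xtr.mean(axis=0)
        mu_y = ytr.mean()
        coefs = _enet_coef_path(Xtr - mu_x, ytr - mu_y, alpha, grid)
        preds = mu_y + (Xte - mu_x) @ coefs
        fold_mse.append(np.mean((ya[test, None] - preds) ** 2, axis=0))
    if not fold_mse:
        raise RuntimeError("all CV folds degenerate")
    errs = np.vstack(fold_mse)
    mean_error = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
    return grid, mean_error, se, choose_lambda_1se(grid, mean_error, se)


def fit_lars(
    X: pd.DataFrame, y: np.ndarray | pd.Series, max_steps: int | None = None
) -> list[FitResult]:
    """Least-angle regression path on standardized features.

    Returns one :class:`FitResult` per step of the equiangular forward
    path (step 0 is the intercept-only model); the first active feature is
    the one most correlated with the outcome.
    """
    ya = np.asarray(y, dtype=float)
    Xa = X.to_numpy(dtype=float)
    mu_x = Xa.mean(axis=0)
    max_iter = max_steps if max_steps is not None else 500
    # lars_path assumes centered data; the intercept is restored afterwards
    _, _, coefs = lars_path(
        Xa - mu_x, ya - ya.mean(), method="lar", max_iter=max_iter
    )
    results = []
    for step in range(coefs.shape[1]):
        b = pd.Series(coefs[:, step], index=X.columns)
        b0 = float(ya.mean() - mu_x @ coefs[:, step])
        results.append(FitResult(b0, b))
    return results


def fit_random_forest(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_trees: int = 50_000,
    seed: int = 0,
    max_features: float | str = 0.333,
) -> tuple[RandomForestRegressor, pd.Series]:
    """Bootstrap regression-tree ensemble; predictions are tree means.

    The default ensemble size is deliberately large so that every feature
    is used often enough for impurity importances to stabilize, though at
    cohort-scale n those importances remain unreliable and are reported as
    diagnostics only.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=seed % 2**31,
        n_jobs=1,
    )
    model.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    return model, pd.Series(model.feature_importances_, index=X.columns)


def adjusted_r2(
    y_true: np.ndarray, y_pred: np.ndarray, n_selected: int
) -> float:
    """Adjusted coefficient of determination,
    1 - (1 - R^2) (n - 1)/(n - n_selected - 1); NaN when the degrees of
    freedom are exhausted."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_true)
    if n - n_selected - 1 <= 0:
        logger.warning("adjusted R^2 undefined: n=%d, selected=%d", n, n_selected)
        return np.nan
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_selected - 1)


@dataclass
class CVResult:
    """Full distributions from repeated k-fold cross-validation."""

    rmse: np.ndarray                      # one entry per successful repeat
    r2: np.ndarray
    adj_r2: np.ndarray
    chosen_lambda: list[list[float]]      # [repeat][fold]
    selected: list[list[frozenset[str]]]  # [repeat][fold]
    n_failed: int = 0
    family: str = "lasso"
    k: int = 4
    fit_results: list[list[FitResult]] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.rmse)

    def summary(self) -> dict[str, float]:
        return {
            "rmse_mean": float(np.mean(self.rmse)),
            "rmse_sd": float(np.std(self.rmse, ddof=1)) if len(self.rmse) > 1 else 0.0,
            "adj_r2_mean": float(np.nanmean(self.adj_r2)),
            "adj_r2_sd": float(np.nanstd(self.adj_r2, ddof=1)) if len(self.adj_r2) > 1 else 0.0,
            "r2_mean": float(np.mean(self.r2)),
            "n_repeats": self.n_repeats,
            "n_failed": self.n_failed,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"repeat": np.arange(self.n_repeats), "rmse": self.rmse,
             "r2": self.r2, "adj_r2": self.adj_r2}
        )


def _repeat_seed(master_seed: int, repeat: int, tag: int = 0) -> int:
    return int(
        np.random.SeedSequence([master_seed, tag, repeat]).generate_state(1)[0]
        % 2**31
    )


def repeated_cv_evaluate(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    family: str = "lasso",
    alpha: float | None = None,
    k: int = 4,
    repeats: int = 100,
    master_seed: int = 0,
    inner_k: int = 4,
    n_lambdas: int = 100,
    rf_trees: int = 500,
    keep_fits: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation of one model family.

    Families: ``lasso`` (mixing 1), ``ridge`` (mixing 0), ``enet`` (pass
    ``alpha``), ``lars``, ``rf``, ``intercept``. For the penalized
    families the penalty strength is chosen by an inner ``inner_k``-fold
    1-SE cross-validation on each training split (nested selection), and
    standardization statistics come from the training split only. Each
    repeat pools its out-of-fold predictions into a single RMSE and
    adjusted R^2 (model size = mean number of selected features across the
    k folds).

    Fold partitions are a deterministic function of ``master_seed`` and the
    repeat index alone, so runs on different feature subsets are paired.
    """
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for {k}-fold CV")
    if family == "enet":
        if alpha is None:
            raise ValueError("family 'enet' requires alpha")
        mix = float(alpha)
    elif family == "lasso":
        mix = 1.0
    elif family == "ridge":
        mix = 0.0
    elif family not in ("lars", "rf", "intercept"):
        raise ValueError(f"unknown model family {family!r}")

    rmse_l, r2_l, adj_l = [], [], []
    lams_l, sel_l, fits_l = [], [], []
    n_failed = 0
    for r in range(repeats):
        fold_seed = _repeat_seed(master_seed, r, tag=0)
        kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
        y_pred = np.empty(n)
        lams_r, sel_r, fits_r = [], [], []
        try:
            for f, (train, test) in enumerate(kf.split(np.arange(n))):
                if family == "rf":
                    model, _ = fit_random_forest(
                        X.iloc[train], ya[train], n_trees=rf_trees,
                        seed=_repeat_seed(master_seed, r, tag=2 + f),
                    )
                    y_pred[test] = model.predict(X.iloc[test].to_numpy(dtype=float))
                    sel_r.append(frozenset(X.columns))
                    lams_r.append(np.nan)
                    continue
                if family == "intercept":
                    y_pred[test] = ya[train].mean()
                    sel_r.append(frozenset())
                    lams_r.append(np.nan)
                    continue
                Xs, record = standardize(X, X.index[train])
                Xtr, Xte = Xs.iloc[train], Xs.iloc[test]
                if family == "lars":
                    fit = _lars_cv_fit(
                        Xtr, ya[train], inner_k,
                        _repeat_seed(master_seed, r, tag=1),
                    )
                    lam = float(len(fit.selected))
                else:
                    _, _, _, lam = lambda_path_cv(
                        Xtr, ya[train], mix, k=inner_k,
                        seed=_repeat_seed(master_seed, r, tag=1),
                        n_lambdas=n_lambdas,
                    )
                    fit = fit_elastic_net(Xtr, ya[train], PenaltySpec(mix, lam))
                fit.scaling = record
                y_pred[test] = fit.predict(Xte)
                lams_r.append(lam)
                sel_r.append(fit.selected)
                if keep_fits:
                    fits_r.append(fit)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("repeat %d failed and was excluded: %s", r, exc)
            continue
        resid = ya - y_pred
        rmse_l.append(float(np.sqrt(np.mean(resid**2))))
        ss_tot = float(np.sum((ya - ya.mean()) ** 2))
        r2_l.append(1.0 - float(np.sum(resid**2)) / ss_tot)
        mean_size = int(round(np.mean([len(s) for s in sel_r])))
        adj_l.append(adjusted_r2(ya, y_pred, mean_size))
        lams_l.append(lams_r)
        sel_l.append(sel_r)
        if keep_fits:
            fits_l.append(fits_r)

    return CVResult(
        rmse=np.array(rmse_l), r2=np.array(r2_l), adj_r2=np.array(adj_l),
        chosen_lambda=lams_l, selected=sel_l, n_failed=n_failed,
        family=family, k=k, fit_results=fits_l,
    )


def _lars_cv_fit(
    Xtr: pd.DataFrame, ytr: np.ndarray, inner_k: int, seed: int
) -> FitResult:
    """LARS with the number of path steps chosen by the inner 1-SE rule
    (fewest steps whose mean CV error is within 1 SE of the minimum)."""
    max_steps = min(Xtr.shape[1], max(len(ytr) - 2, 1))
    kf = KFold(n_splits=inner_k, shuffle=True, random_state=seed)
    errs = np.full((inner_k, max_steps + 1), np.nan)
    for f, (tr, te) in enumerate(kf.split(np.arange(len(ytr)))):
        path = fit_lars(Xtr.iloc[tr], ytr[tr], max_steps=max_steps)
        for s, fit in enumerate(path[: max_steps + 1]):
            pred = fit.predict(Xtr.iloc[te])
            errs[f, s] = np.mean((ytr[te] - pred) ** 2)
    mean_e = np.nanmean(errs, axis=0)
    se = np.nanstd(errs, axis=0, ddof=1) / np.sqrt(inner_k)
    # treat "fewer steps" as "stronger penalty" for the 1-SE rule
    steps_grid = -np.arange(max_steps + 1).astype(float)
    best = -int(choose_lambda_1se(steps_grid, mean_e, se))
    path = fit_lars(Xtr, ytr, max_steps=max_steps)
    return path[min(best, len(path) - 1)]
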