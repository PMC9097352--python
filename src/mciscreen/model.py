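"""L1-penalized logistic regression with cross-validated shrinkage.

The classifier minimizes mean binomial negative log-likelihood plus
``lambda * sum(|beta_j|)`` with an unpenalized intercept.  Predictors are
standardized to zero mean / unit variance internally (within training folds
during cross-validation, so no information leaks from held-out folds into
the scaling) and coefficients are reported back on the original feature
scale, so a coefficient reads as log-odds per original unit — e.g. per year
of age.  The shrinkage weight is chosen by stratified tenfold
cross-validation to minimize mean held-out binomial deviance; the
one-standard-error rule is available as an option.

The solver is scikit-learn's saga coordinate method behind this module's
surface; the penalty parametrization is converted so that ``lambda`` here is
on the mean-log-likelihood scale (``C = 1 / (n * lambda)``).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LassoScreeningClassifier",
    "fit_lasso_logistic",
    "predict_probability",
    "coefficient_contribution",
    "save_model",
    "load_model",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return arr, None


def _standardize(
    X: np.ndarray, warn: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = scale == 0
    if constant.any():
        if warn:
            warnings.warn(
                f"{int(constant.sum())} constant column(s); their coefficients are fixed at 0",
                stacklevel=3,
            )
        scale = np.where(constant, 1.0, scale)
    return (X - center) / scale, center, scale


def _lambda_max(Xs: np.ndarray, y: np.ndarray) -> float:
    # smallest penalty at which the all-zero slope vector is optimal
    r = y - y.mean()
    return float(np.max(np.abs(Xs.T @ r)) / len(y))


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


class LassoScreeningClassifier(ClassifierMixin, BaseEstimator):
    """LASSO logistic risk model for screening-style prediction.

    Parameters
    ----------
    lambda_grid : sequence of float, optional
        Penalty weights to evaluate (mean-NLL scale).  Default: ``n_lambdas``
        log-spaced values from the data-derived ``lambda_max`` (the smallest
        penalty that zeroes every slope) down to ``lambda_max * lambda_min_ratio``.
    n_lambdas, lambda_min_ratio : grid shape when ``lambda_grid`` is None.
    folds : int
        Cross-validation folds, stratified by outcome (default 10).
    selection : {"min", "1se"}
        ``min`` picks the deviance-minimizing penalty; ``1se`` the largest
        penalty within one standard error of that minimum.
    random_state : int
        Seeds fold assignment and the solver.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : coefficients on the original feature scale.
    lambda_ : selected penalty; lambda_grid_, cv_deviance_mean_,
        cv_deviance_se_ : the cross-validation trace.
    center_, scale_ : the internal standardization of the final refit.
    """

    def __init__(
        self,
        lambda_grid: Sequence[float] | None = None,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        folds: int = 10,
        selection: str = "min",
        random_state: int = 0,
        tol: float = 1e-7,
        max_iter: int = 5000,
        cv_tol: float = 1e-4,
        cv_max_iter: int = 1000,
    ):
        self.lambda_grid = lambda_grid
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.folds = folds
        self.selection = selection
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter
        self.cv_tol = cv_tol
        self.cv_max_iter = cv_max_iter

    # -- core solvers -------------------------------------------------------

    def _fit_at_lambda(
        self,
        Xs: np.ndarray,
        y: np.ndarray,
        lam: float,
        tol: float,
        warm: LogisticRegression | None = None,
        max_iter: int | None = None,
    ) -> tuple[np.ndarray, float, LogisticRegression | None]:
        """Slopes and intercept on the standardized scale at one penalty."""
        n = len(y)
        if lam >= _lambda_max(Xs, y):
            # analytic solution: all slopes zero, intercept = log-odds of mean(y)
            ybar = y.mean()
            if ybar in (0.0, 1.0):
                raise ValueError("y must contain both classes")
            return np.zeros(Xs.shape[1]), float(np.log(ybar / (1 - ybar))), warm
        if lam == 0.0:
            est = LogisticRegression(
                penalty=None, solver="lbfgs", tol=1e-12, max_iter=20000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xs, y)
            return est.coef_.ravel().copy(), float(est.intercept_[0]), warm
        if warm is None:
            warm = LogisticRegression(
                penalty="l1", solver="saga", warm_start=True,
                max_iter=max_iter or self.max_iter, random_state=self.random_state,
            )
        warm.set_params(C=1.0 / (n * lam), tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warm.fit(Xs, y)
        return warm.coef_.ravel().copy(), float(warm.intercept_[0]), warm

    def _path_deviances(
        self, X_tr: np.ndarray, y_tr: np.ndarray,
        X_te: np.ndarray, y_te: np.ndarray, grid: np.ndarray,
    ) -> np.ndarray:
        Xs, center, scale = _standardize(X_tr, warn=False)
        Xt = (X_te - center) / scale
        devs = np.empty(len(grid))
        warm = None
        for k, lam in enumerate(grid):
            coef, icpt, warm = self._fit_at_lambda(
                Xs, y_tr, lam, self.cv_tol, warm, max_iter=self.cv_max_iter
            )
            eta = Xt @ coef + icpt
            devs[k] = _deviance(y_te, 1.0 / (1.0 + np.exp(-eta)))
        return devs

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y) -> "LassoScreeningClassifier":
        Xm, names = _as_matrix(X)
        y = np.asarray(y)
        if Xm.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if np.isnan(Xm).any():
            raise ValueError("X contains missing values")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(f"y must be binary 0/1 with both classes present, got {classes}")
        y = y.astype(float)
        if len(y) < self.folds:
            raise ValueError("need at least as many rows as folds")
        if self.selection not in ("min", "1se"):
            raise ValueError(f"unknown selection rule: {self.selection!r}")

        Xs_full, center, scale = _standardize(Xm)
        if self.lambda_grid is not None:
            grid = np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
        else:
            lmax = _lambda_max(Xs_full, y)
            grid = np.geomspace(lmax, lmax * self.lambda_min_ratio, self.n_lambdas)

        skf = StratifiedKFold(
            n_splits=self.folds, shuffle=True, random_state=self.random_state
        )
        fold_devs = np.empty((self.folds, len(grid)))
        for f, (tr, te) in enumerate(skf.split(Xm, y)):
            fold_devs[f] = self._path_deviances(Xm[tr], y[tr], Xm[te], y[te], grid)
        mean = fold_devs.mean(axis=0)
        se = fold_devs.std(axis=0, ddof=1) / np.sqrt(self.folds)
        k_min = int(np.argmin(mean))
        if self.selection == "1se":
            within = np.flatnonzero(mean <= mean[k_min] + se[k_min])
            k_sel = int(within[0])  # grid is descending: first index = largest penalty
        else:
            k_sel = k_min
        lam = float(grid[k_sel])

        coef_std, icpt_std, _ = self._fit_at_lambda(Xs_full, y, lam, self.tol, None)
        self.coef_ = coef_std / scale
        self.intercept_ = float(icpt_std - np.sum(coef_std * center / scale))
        self.center_, self.scale_ = center, scale
        self.lambda_ = lam
        self.lambda_grid_ = grid
        self.cv_deviance_mean_ = mean
        self.cv_deviance_se_ = se
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = Xm.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def _validate_columns(self, X) -> np.ndarray:
        Xm, names = _as_matrix(X)
        if names is not None and hasattr(self, "feature_names_in_"):
            expected = list(self.feature_names_in_)
            if names != expected:
                missing = [c for c in expected if c not in names]
                extra = [c for c in names if c not in expected]
                raise ValueError(
                    f"feature schema mismatch: missing={missing}, extra={extra}, "
                    f"order must match the fitted schema"
                )
        if Xm.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xm.shape[1]} features; model was fitted with {self.n_features_in_}"
            )
        return Xm

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        Xm = self._validate_columns(X)
        return Xm @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        eta = np.clip(self.decision_function(X), -700, 700)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        # strictly inside (0, 1): extreme linear predictors must not
        # saturate to an impossible certainty
        p1 = np.clip(p1, 1e-15, 1 - 1e-15)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)

    # -- introspection ------------------------------------------------------

    def retained_features(self) -> list[str]:
        """Features with nonzero coefficients (the LASSO-selected subset)."""
        names = getattr(
            self, "feature_names_in_",
            np.array([f"x{j}" for j in range(self.n_features_in_)], dtype=object),
        )
        return [str(n) for n, c in zip(names, self.coef_) if c != 0.0]

    def coefficient_table(self) -> pd.DataFrame:
        names = getattr(
            self, "feature_names_in_",
            np.array([f"x{j}" for j in range(self.n_features_in_)], dtype=object),
        )
        tab = pd.DataFrame({"feature": names, "coefficient": self.coef_})
        return tab[tab.coefficient != 0].reindex(
            tab[tab.coefficient != 0].coefficient.abs().sort_values(ascending=False).index
        ).reset_index(drop=True)


def fit_lasso_logistic(
    X,
    y,
    lambda_grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> LassoScreeningClassifier:
    """Fit the L1 logistic screening model (wrapper over the estimator class)."""
    return LassoScreeningClassifier(
        lambda_grid=lambda_grid, folds=folds, random_state=seed, **kwargs
    ).fit(X, y)


def predict_probability(model: LassoScreeningClassifier, X) -> np.ndarray:
    """Per-row probability of MCI at index date."""
    return model.predict_proba(X)[:, 1]


def coefficient_contribution(model: LassoScreeningClassifier, feature: str, value: float) -> float:
    """Original-scale contribution ``coefficient * value`` to the linear predictor.

    For a per-year age coefficient of 0.023, a 70-year-old contributes
    0.023 * 70 = 1.61 to the log-odds.
    """
    names = [str(n) for n in getattr(model, "feature_names_in_", [])]
    if feature not in names:
        raise KeyError(f"unknown feature: {feature!r}")
    return float(model.coef_[names.index(feature)] * value)


# -- flat-file serialization ------------------------------------------------

def save_model(model: LassoScreeningClassifier, path: str | Path) -> None:
    names = getattr(model, "feature_names_in_", None)
    payload = {
        "format": "mciscreen-lasso-logistic-1",
        "feature_names": None if names is None else [str(n) for n in names],
        "n_features": int(model.n_features_in_),
        "intercept": model.intercept_,
        "coefficients": model.coef_.tolist(),
        "center": model.center_.tolist(),
        "scale": model.scale_.tolist(),
        "lambda": model.lambda_,
        "lambda_grid": model.lambda_grid_.tolist(),
        "cv_deviance_mean": model.cv_deviance_mean_.tolist(),
        "cv_deviance_se": model.cv_deviance_se_.tolist(),
        "params": model.get_params(),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> LassoScreeningClassifier:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "mciscreen-lasso-logistic-1":
        raise ValueError(f"{path}: not a serialized model file")
    params = payload["params"]
    model = LassoScreeningClassifier(**params)
    model.coef_ = np.asarray(payload["coefficients"], dtype=float)
    model.intercept_ = float(payload["intercept"])
    model.center_ = np.asarray(payload["center"], dtype=float)
    model.scale_ = np.asarray(payload["scale"], dtype=float)
    model.lambda_ = float(payload["lambda"])
    model.lambda_grid_ = np.asarray(payload["lambda_grid"], dtype=float)
    model.cv_deviance_mean_ = np.asarray(payload["cv_deviance_mean"], dtype=float)
    model.cv_deviance_se_ = np.asarray(payload["cv_deviance_se"], dtype=float)
    model.n_features_in_ = int(payload["n_features"])
    model.classes_ = np.array([0, 1])
    if payload["feature_names"] is not None:
        model.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
    return model
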