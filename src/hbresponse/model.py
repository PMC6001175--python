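"""Logistic response model fitted by maximum likelihood.

The probability that a patient responds (Miller-Payne 4-5) given predictors
x₁…x_k is modelled as

    pr(Y=1 | x) = 1 / (1 + exp(-(β₀ + Σ βₙ xₙ)))

with β estimated by maximizing the Bernoulli log-likelihood via iteratively
reweighted least squares (Newton-Raphson with step halving). The estimator
follows the scikit-learn protocol (``fit`` / ``predict_proba`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) so it
composes with sklearn pipelines and model selection, but the likelihood
maximization is implemented here, not delegated.

Small cohorts with strong predictors can be perfectly separated, in which
case the MLE diverges; this is detected and flagged rather than hidden.
Optional ridge and Firth (Jeffreys-prior) stabilization are available, both
off by default to match plain maximum likelihood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.special import expit
from scipy.stats import norm

try:  # estimator base classes; the fitter itself never calls into sklearn
    from sklearn.base import BaseEstimator as _BaseEstimator
    from sklearn.base import ClassifierMixin as _ClassifierMixin
except ImportError:  # pragma: no cover - sklearn absent
    _BaseEstimator = object

    class _ClassifierMixin:
        pass

__all__ = [
    "LogisticResponseModel",
    "LogisticFit",
    "SeparationWarning",
    "fit_logistic",
    "predict_prob",
    "classify",
    "wald_test",
]


class SeparationWarning(UserWarning):
    """Emitted when the likelihood appears unbounded (separated data)."""


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = Σ yη − log(1+e^η), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(Xd: np.ndarray, names: list[str]) -> None:
    _, _, piv = qr(Xd, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        dependent = sorted(piv[rank:])
        labels = [("intercept" if j == 0 else names[j - 1]) for j in dependent]
        raise ValueError(f"design matrix is rank deficient; dependent columns: {labels}")


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, covariance, and diagnostics."""

    beta: np.ndarray  # (k+1,), intercept first
    cov: np.ndarray  # (k+1, k+1), inverse observed information
    loglik: float
    converged: bool
    n_iter: int
    separation_flag: bool
    feature_names: list[str] = field(default_factory=list)
    penalty: str = "none"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": dict(
                    zip(["intercept"] + list(self.feature_names), self.beta.tolist())
                ),
                "se": dict(
                    zip(["intercept"] + list(self.feature_names), self.se.tolist())
                ),
                "loglik": self.loglik,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "separation_flag": self.separation_flag,
                "penalty": self.penalty,
            },
            indent=1,
        )


class LogisticResponseModel(_ClassifierMixin, _BaseEstimator):
    """Binary logistic regression by maximum likelihood (IRLS).

    Parameters
    ----------
    threshold : float, default 0.5
        Classification cut: predicted responder iff probability > threshold
        (strictly; a probability exactly at the threshold is a non-responder).
    max_iter : int, default 100
        Newton-Raphson iteration cap.
    tol : float, default 1e-8
        Convergence declared when the log-likelihood improves by less than
        this between iterations.
    penalty : {"none", "ridge", "firth"}, default "none"
        Plain MLE, ridge-stabilized MLE, or Firth bias-reduced fit.
    alpha : float, default 1e-4
        Ridge strength (on standardized predictors) when ``penalty="ridge"``.
    divergence_bound : float, default 15.0
        A coefficient exceeding this on the standardized scale without
        convergence marks the fit as separated.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : slope vector and intercept on the natural scale.
    covariance_ : inverse observed information (natural scale).
    loglik_, converged_, n_iter_, separation_flag_ : fit diagnostics.
    classes_ : array([0, 1]).
    """

    def __init__(
        self,
        threshold: float = 0.5,
        max_iter: int = 100,
        tol: float = 1e-8,
        penalty: str = "none",
        alpha: float = 1e-4,
        divergence_bound: float = 15.0,
    ):
        self.threshold = threshold
        self.max_iter = max_iter
        self.tol = tol
        self.penalty = penalty
        self.alpha = alpha
        self.divergence_bound = divergence_bound

    # sklearn protocol ----------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "threshold": self.threshold,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "penalty": self.penalty,
            "alpha": self.alpha,
            "divergence_bound": self.divergence_bound,
        }

    def set_params(self, **params) -> "LogisticResponseModel":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # fitting -------------------------------------------------------------
    def fit(self, X, y) -> "LogisticResponseModel":
        X, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("design matrix or outcome contains missing values")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError("outcome must be coded 0/1")
        if classes.size < 2:
            raise ValueError("outcome has a single class; cannot fit")
        if self.penalty not in ("none", "ridge", "firth"):
            raise ValueError(f"unknown penalty {self.penalty!r}")

        n, k = X.shape
        Xd = np.column_stack([np.ones(n), X])
        _check_rank(Xd, names)

        # standardized predictor scales, for the divergence bound and ridge
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mu = X.mean(axis=0)

        def _standardized(b: np.ndarray) -> np.ndarray:
            # coefficients as they would read on centered/scaled predictors
            return np.concatenate([[b[0] + b[1:] @ mu], b[1:] * sd])

        ridge = np.zeros(k + 1)
        if self.penalty == "ridge":
            ridge[1:] = self.alpha / sd**2  # α on the standardized scale

        beta = np.zeros(k + 1)
        eta = Xd @ beta
        ll = _log_likelihood(eta, y) - 0.5 * float(ridge @ beta**2)
        converged = False
        separated = False
        n_iter = 0

        for n_iter in range(1, self.max_iter + 1):
            p = expit(eta)
            w = p * (1.0 - p)
            resid = y - p
            if self.penalty == "firth":
                # Jeffreys-prior score adjustment via hat-matrix diagonals
                WX = Xd * w[:, None]
                info = Xd.T @ WX
                h = np.einsum(
                    "ij,ij->i", Xd @ np.linalg.inv(info), WX
                )
                resid = resid + h * (0.5 - p)
                grad = Xd.T @ resid
            else:
                info = Xd.T @ (Xd * w[:, None]) + np.diag(ridge)
                grad = Xd.T @ resid - ridge * beta
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                separated = True
                break
            # step halving: never accept a likelihood decrease
            new_ll = -np.inf
            for _ in range(30):
                candidate = beta + step
                eta_c = Xd @ candidate
                new_ll = _log_likelihood(eta_c, y) - 0.5 * float(
                    ridge @ candidate**2
                )
                if new_ll >= ll - 1e-12 or self.penalty == "firth":
                    break
                step = step / 2.0
            beta, eta = beta + step, Xd @ (beta + step)
            if abs(new_ll - ll) < self.tol:
                ll = new_ll
                converged = True
                break
            ll = new_ll

        # The likelihood flattens out near a divergent "MLE at infinity" too,
        # so a small Δloglik alone does not certify an interior maximum: a
        # coefficient escaping the divergence bound (standardized scale)
        # marks the fit as separated, and separated fits never count as
        # converged.
        if np.any(np.abs(_standardized(beta)) > self.divergence_bound):
            separated = True
            converged = False
        if separated:
            warnings.warn(
                "apparent separation: maximum-likelihood coefficients diverge",
                SeparationWarning,
                stacklevel=2,
            )

        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = Xd.T @ (Xd * w[:, None]) + np.diag(ridge)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((k + 1, k + 1), np.nan)

        self.feature_names_in_ = names
        self.n_features_in_ = k
        self.classes_ = np.array([0, 1])
        self.beta_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.covariance_ = cov
        self.loglik_ = _log_likelihood(Xd @ beta, y)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.separation_flag_ = separated
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "beta_"):
            raise AttributeError("model is not fitted; call fit first")

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        X, _ = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} predictors, got {X.shape[1]}"
            )
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > self.threshold).astype(int)

    def score(self, X, y) -> float:
        """Classification accuracy at the model's threshold."""
        y = np.asarray(y).ravel()
        return float(np.mean(self.predict(X) == y))

    def result_(self) -> LogisticFit:
        """The fit as a serializable :class:`LogisticFit`."""
        self._check_fitted()
        return LogisticFit(
            beta=self.beta_.copy(),
            cov=self.covariance_.copy(),
            loglik=self.loglik_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            separation_flag=self.separation_flag_,
            feature_names=list(self.feature_names_in_),
            penalty=self.penalty,
        )


def fit_logistic(X, y, **params) -> LogisticFit:
    """Fit the logistic response model and return a :class:`LogisticFit`."""
    return LogisticResponseModel(**params).fit(X, y).result_()


def predict_prob(fit: LogisticFit, x) -> float | np.ndarray:
    """Evaluate pr(Y=1 | x) = 1/(1+exp(−(β₀+Σβₙxₙ))) for one predictor vector
    (returns a scalar) or a matrix of rows (returns a vector)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    X = x[None, :] if scalar else x
    if X.shape[1] != fit.beta.size - 1:
        raise ValueError(
            f"predictor vector has {X.shape[1]} entries, fit expects {fit.beta.size - 1}"
        )
    p = expit(fit.beta[0] + X @ fit.beta[1:])
    return float(p[0]) if scalar else p


def classify(prob: float, threshold: float = 0.5) -> int:
    """Responder (1) iff probability strictly exceeds the threshold."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return int(prob > threshold)


def wald_test(fit: LogisticFit, index: int) -> float:
    """Two-sided Wald p-value for coefficient ``index`` (0 = intercept).

    If the fit is flagged as separated the p-value is still returned but a
    validity warning is emitted — Wald inference is unreliable there.
    """
    if fit.separation_flag:
        warnings.warn(
            "Wald p-value from a separated fit is unreliable",
            SeparationWarning,
            stacklevel=2,
        )
    z = fit.beta[index] / fit.se[index]
    return float(2.0 * norm.sf(abs(z)))
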