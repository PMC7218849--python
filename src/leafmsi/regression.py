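"""Regression of reference chlorophyll readings (SPAD) on image features.

Two model families: a simple linear fit of leaf-mean NDVI against the
reference value, and multiple linear regression of the four band means
with all pairwise interaction terms, evaluated by leave-one-out
cross-validation (LOOCV).  LOOCV R² is 1 − SSE_cv / SST; the squared-
correlation alternative is deliberately not used (it hides bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm


@dataclass
class RegressionResult:
    """Fit summary: named coefficients, evaluated predictions, R², RMSE."""

    coefficients: dict[str, float]
    predictions: np.ndarray
    r2: float
    rmse: float
    n: int
    design: str
    cv_scheme: str = "none"

    def to_json(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "r2": self.r2,
            "rmse": self.rmse,
            "n": self.n,
            "design": self.design,
            "cv_scheme": self.cv_scheme,
        }


def _score(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = y - pred
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return r2, rmse


def linear_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y ~ intercept + x, scored in-sample."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; a slope cannot be estimated")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = np.asarray(fit.fittedvalues)
    r2, rmse = _score(y, pred)
    coefs = {"intercept": float(fit.params[0]), "slope": float(fit.params[1])}
    return RegressionResult(coefs, pred, r2, rmse, x.size, "y ~ 1 + x")


def interaction_design(X: np.ndarray, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + main effects + all pairwise products."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names or [f"x{i + 1}" for i in range(p)]
    cols = [np.ones(n)] + [X[:, i] for i in range(p)]
    labels = ["intercept"] + list(names)
    for i, j in combinations(range(p), 2):
        cols.append(X[:, i] * X[:, j])
        labels.append(f"{names[i]}:{names[j]}")
    return np.column_stack(cols), labels


def _check_rank(D: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(D, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(D.shape) * np.finfo(float).eps
        bad = [labels[piv[i]] for i in range(len(labels)) if i >= rank or diag[min(i, len(diag) - 1)] < tol]
        dependent = sorted(set(labels[p] for p in piv[rank:]))
        raise ValueError(f"rank-deficient design (rank {rank} of {D.shape[1]}); collinear columns: {dependent}")


def mlr_interaction_loocv(
    X: np.ndarray, y: np.ndarray, names: list[str] | None = None
) -> RegressionResult:
    """MLR with pairwise interactions, scored by leave-one-out CV.

    ``X`` is n × 4 (band means).  The design holds an intercept, 4 main
    effects and 6 pairwise products (11 columns); n must exceed 11.  Each
    observation is predicted by a model fitted on the other n − 1; R² and
    RMSE are computed over these held-out predictions.  Reported
    coefficients come from the full-data fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n x p)")
    n = X.shape[0]
    D, labels = interaction_design(X, names)
    p = D.shape[1]
    if n <= p:
        raise ValueError(f"need n > {p} observations for LOOCV of a {p}-column design, got {n}")
    _check_rank(D, labels)

    # exact LOOCV for OLS via the hat matrix: e_cv,i = e_i / (1 − h_ii)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ beta
    H_diag = np.einsum("ij,ji->i", D, np.linalg.pinv(D))
    resid = y - fitted
    denom = 1.0 - H_diag
    if np.any(denom <= 1e-10):
        raise ValueError("leverage of 1 encountered; an observation determines its own prediction")
    cv_pred = y - resid / denom

    r2, rmse = _score(y, cv_pred)
    coefs = {lbl: float(b) for lbl, b in zip(labels, beta)}
    return RegressionResult(
        coefs, cv_pred, r2, rmse, n, "y ~ 1 + mains + pairwise interactions", "loocv"
    )


def in_sample_rmse(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> float:
    """In-sample RMSE of the full interaction model (for overfit checks)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    D, labels = interaction_design(X, names)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return float(np.sqrt(np.mean((y - D @ beta) ** 2)))
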