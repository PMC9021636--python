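"""Partial least squares (PLS1) calibration with PRESS-based factor choice.

The fitted engine is NIPALS with mean-centering only (no autoscaling, the
usual choice for NIR absorbance features).  NIPALS is used rather than an
off-the-shelf fit because leave-one-out PRESS and the variable-stability
statistic downstream both need the nested coefficient vectors b_1..b_K from
a single deflation pass.

Factor selection follows the PRESS-ratio stopping rule: scanning k = 2..K,
the first k-1 with PRESS(k)/PRESS(k-1) above the ratio threshold (default
0.9) is kept; if no ratio exceeds the threshold, K itself is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSCalibration",
    "PressCurve",
    "fit_pls",
    "press_loo",
    "select_factor",
    "rmse",
    "corr_coeff",
]

_RANK_TOL = 1e-12


def nipals_coefficients(Xc: np.ndarray, yc: np.ndarray, n_factors: int) -> np.ndarray:
    """Nested PLS1 coefficient vectors for 1..n_factors components.

    Operates on centered data; returns an array of shape (k_eff, p) where
    row k-1 predicts ``yc`` as ``Xc @ b_k``.  Stops early (k_eff < n_factors)
    when the deflated covariance vanishes (rank exhausted).
    """
    X = np.array(Xc, dtype=float)
    y = np.array(yc, dtype=float)
    n, p = X.shape
    x_scale = np.abs(Xc).max() * np.abs(yc).max() if n else 0.0
    W = np.empty((n_factors, p))
    P = np.empty((n_factors, p))
    q = np.empty(n_factors)
    coefs = []
    for k in range(n_factors):
        s = X.T @ y
        s_norm = np.linalg.norm(s)
        if s_norm <= _RANK_TOL * max(x_scale, 1e-300):
            break
        w = s / s_norm
        t = X @ w
        tt = t @ t
        if tt <= _RANK_TOL:
            break
        P[k] = (X.T @ t) / tt
        q[k] = (y @ t) / tt
        W[k] = w
        X -= np.outer(t, P[k])
        y = y - q[k] * t
        # b_k = W_k (P_k^T W_k)^{-1} q_k ; the k x k system is tiny.
        R = P[: k + 1] @ W[: k + 1].T  # (P^T W) in column convention; unit triangular
        beta = np.linalg.solve(R, q[: k + 1])
        coefs.append(W[: k + 1].T @ beta)
    if not coefs:
        return np.zeros((1, p))
    return np.stack(coefs)


@dataclass(frozen=True)
class PLSCalibration:
    """A fitted PLS1 model: coefficients plus centering statistics."""

    n_factors: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    fitted: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_pls(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSCalibration:
    """Fit a PLS1 model with ``n_factors`` latent variables.

    Mean-centers X and y internally.  If the requested factor count exceeds
    what the data can support (min(n-1, p), or the effective rank reached by
    NIPALS), it is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per element of y")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples to calibrate, got {n}")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    cap = min(n - 1, p)
    if n_factors > cap:
        warnings.warn(
            f"n_factors={n_factors} exceeds min(n-1, p)={cap}; reduced to {cap}",
            UserWarning,
            stacklevel=2,
        )
        n_factors = cap
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    coefs = nipals_coefficients(X - x_mean, y - y_mean, n_factors)
    k_eff = coefs.shape[0]
    if k_eff < n_factors:
        warnings.warn(
            f"rank exhausted after {k_eff} factors (requested {n_factors})",
            UserWarning,
            stacklevel=2,
        )
    coef = coefs[-1]
    fitted = (X - x_mean) @ coef + y_mean
    return PLSCalibration(k_eff, coef, x_mean, y_mean, fitted)


@dataclass(frozen=True)
class PressCurve:
    """Leave-one-out PRESS per factor count 1..K."""

    factors: np.ndarray
    press: np.ndarray

    def __post_init__(self):
        factors = np.asarray(self.factors, dtype=int)
        press = np.asarray(self.press, dtype=float)
        if factors.shape != press.shape or factors.ndim != 1:
            raise ValueError("factors and press must be 1-D of equal length")
        if not np.array_equal(factors, np.arange(1, factors.size + 1)):
            raise ValueError("factor grid must be 1..K consecutive")
        if np.any(press < 0):
            raise ValueError("PRESS values must be nonnegative")
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "press", press)


def press_loo(X: np.ndarray, y: np.ndarray, max_factors: int) -> PressCurve:
    """Leave-one-out PRESS curve over factor counts 1..max_factors.

    For each left-out sample one NIPALS pass yields the nested coefficient
    vectors for every factor count, so the cost is n fits, not n*K.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 4:
        raise ValueError(f"leave-one-out PRESS needs at least 4 samples, got {n}")
    cap = min(n - 2, p)
    if max_factors > cap:
        warnings.warn(
            f"max_factors={max_factors} infeasible for n={n}, p={p}; clipped to {cap}",
            UserWarning,
            stacklevel=2,
        )
        max_factors = cap
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    press = np.zeros(max_factors)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        coefs = nipals_coefficients(Xi - x_mean, yi - y_mean, max_factors)
        preds = coefs @ (X[i] - x_mean) + y_mean  # one prediction per factor count
        if coefs.shape[0] < max_factors:  # rank-exhausted: carry the last model
            preds = np.concatenate([preds, np.repeat(preds[-1], max_factors - preds.size)])
        press += (y[i] - preds) ** 2
        mask[i] = True
    return PressCurve(np.arange(1, max_factors + 1), press)


def select_factor(curve, ratio_threshold: float = 0.9, k_max: int = 20) -> int:
    """Apply the PRESS-ratio stopping rule and return the factor count.

    Scans k = 2..k_max; the first k-1 whose successor satisfies
    PRESS(k)/PRESS(k-1) > ratio_threshold is returned.  A zero PRESS(k-1)
    means the improvement is exhausted, so k-1 is returned.  If the curve
    keeps improving faster than the threshold throughout, k_max is used.
    """
    press = curve.press if isinstance(curve, PressCurve) else np.asarray(curve, dtype=float)
    if press.size == 0:
        raise ValueError("empty PRESS curve")
    k_max = min(int(k_max), press.size)
    if k_max < 2:
        return 1
    for k in range(2, k_max + 1):
        prev = press[k - 2]
        if prev == 0.0 or press[k - 1] / prev > ratio_threshold:
            return k - 1
    return k_max


def rmse(observed, predicted) -> float:
    """Root-mean-square error between two equal-length vectors."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size:
        raise ValueError(f"length mismatch: {observed.size} vs {predicted.size}")
    if observed.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def corr_coeff(observed, predicted) -> float:
    """Pearson correlation between reference and predicted values."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size:
        raise ValueError(f"length mismatch: {observed.size} vs {predicted.size}")
    if observed.size < 2 or np.std(observed) == 0 or np.std(predicted) == 0:
        raise ValueError("correlation undefined for constant or single-point vectors")
    return float(np.corrcoef(observed, predicted)[0, 1])
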