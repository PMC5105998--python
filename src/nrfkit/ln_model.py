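"""LN baseline: L1-regularized linear STRF plus a 4-parameter sigmoid.

The linear (L) stage predicts the PSTH as a lasso-regularized linear
function of the lagged cochleagram,

    a(t) = sum_{f,tau} w_ft * x_ft(t) + b,

minimizing ``||y - a||^2 + lambda * sum|w_ft|`` with an unpenalized bias.
The nonlinear (N) stage maps the activation through a logistic sigmoid

    yhat(t) = rho1 / (1 + exp(-(a(t) - rho3)/rho2)) + rho4

whose four parameters are fitted by multi-start quasi-Newton least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.linear_model import Lasso

__all__ = [
    "STRF",
    "SigmoidParams",
    "fit_linear_lasso",
    "predict_linear",
    "fit_output_sigmoid",
    "sigmoid",
    "predict_ln",
]


@dataclass
class STRF:
    """Linear spectrotemporal receptive field: F x H weights plus bias."""

    w: np.ndarray  # (F, H)
    b: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("STRF parameters must be finite")


@dataclass
class SigmoidParams:
    """Output nonlinearity parameters (canonical form has rho2 > 0)."""

    rho1: float  # output range
    rho2: float  # slope scale
    rho3: float  # midpoint activation
    rho4: float  # output offset

    def __post_init__(self) -> None:
        if self.rho1 <= 0:
            raise ValueError("rho1 must be positive")
        if self.rho2 == 0:
            raise ValueError("rho2 must be nonzero")


def _design(X) -> np.ndarray:
    """Flatten lagged windows (T, F, H) -> (T, F*H); pass 2-D through."""
    X = X.windows if hasattr(X, "windows") else np.asarray(X, dtype=float)
    if X.ndim == 3:
        return X.reshape(X.shape[0], -1)
    return X


def fit_linear_lasso(X, y, lam: float, tol: float = 1e-7,
                     max_iter: int = 100000) -> STRF:
    """Minimize ``||y - Xw - b||^2 + lam * sum|w|`` (bias unpenalized).

    Solved by coordinate descent (scikit-learn's lasso, whose objective
    ``(1/2n)||y - Xw - b||^2 + alpha*||w||_1`` matches with
    ``alpha = lam / (2n)``).  ``lam = 0`` falls back to ordinary least
    squares.  Deterministic for fixed inputs.
    """
    D = _design(X)
    y = np.asarray(y, dtype=float).ravel()
    if D.shape[0] != y.size:
        raise ValueError(f"X has {D.shape[0]} bins but y has {y.size}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    shape = _strf_shape(X, D)
    n = y.size
    if lam == 0:
        A = np.column_stack([D, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return STRF(w=coef[:-1].reshape(shape), b=float(coef[-1]))
    model = Lasso(alpha=lam / (2.0 * n), fit_intercept=True, tol=tol,
                  max_iter=max_iter, precompute=True)
    model.fit(D, y)
    return STRF(w=model.coef_.reshape(shape), b=float(model.intercept_))


def _strf_shape(X, D):
    if hasattr(X, "windows"):
        return X.windows.shape[1:]
    X = np.asarray(X)
    return X.shape[1:] if X.ndim == 3 else (1, D.shape[1])


def lambda_max_linear(X, y) -> float:
    """Smallest lambda that shrinks every weight to zero.

    For the objective ``||y - Xw - b||^2 + lam*sum|w|`` this is
    ``2 * max|X_c' (y - mean(y))|`` with ``X_c`` column-centered.
    """
    D = _design(X)
    y = np.asarray(y, dtype=float).ravel()
    Dc = D - D.mean(axis=0)
    return float(2.0 * np.max(np.abs(Dc.T @ (y - y.mean()))))


def predict_linear(strf: STRF, X) -> np.ndarray:
    """Linear activation a(t) = sum w_ft x_ft(t) + b (the L-model output)."""
    D = _design(X)
    return D @ strf.w.ravel() + strf.b


def sigmoid(a, p: SigmoidParams) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return p.rho1 / (1.0 + np.exp(-(a - p.rho3) / p.rho2)) + p.rho4


def fit_output_sigmoid(a, y) -> SigmoidParams:
    """Least-squares fit of the 4-parameter sigmoid mapping a(t) -> y(t).

    The error surface is multimodal, so the quasi-Newton (L-BFGS-B) solve is
    repeated from several starts (rho1 = range(y), rho4 = min(y),
    rho3 = median(a), rho2 in {+-sd(a), +-sd(a)/4}) and the best kept; the
    returned error never exceeds that of the best start.  Positive-slope
    starts are tried first, so on tied error the canonical rho2 > 0 form
    wins; a genuinely decreasing relationship is returned with rho2 < 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if a.size != y.size:
        raise ValueError("a and y must have equal length")
    if np.ptp(y) == 0:
        raise ValueError("constant target: sigmoid fit is degenerate")

    def err(theta):
        p = theta_to_params(theta)
        r = sigmoid(a, p) - y
        return 0.5 * float(r @ r)

    def theta_to_params(theta):
        r1, r2, r3, r4 = theta
        return SigmoidParams(rho1=max(r1, 1e-12), rho2=r2 if r2 != 0 else 1e-12,
                             rho3=r3, rho4=r4)

    sd_a = a.std() if a.std() > 0 else 1.0
    # positive-slope starts first: on a tie the canonical rho2 > 0 fit wins
    starts = []
    for r2 in (sd_a, sd_a / 4, -sd_a, -sd_a / 4):
        starts.append([np.ptp(y), r2, float(np.median(a)), float(y.min())])
    best, best_err = None, np.inf
    bounds = [(1e-12, None), (None, None), (None, None), (None, None)]
    for s in starts:
        res = minimize(err, s, method="L-BFGS-B", bounds=bounds)
        e = min(res.fun, err(s))
        theta = res.x if res.fun <= err(s) else np.asarray(s)
        if e < best_err - 1e-12:
            best, best_err = theta, e
    return theta_to_params(best)


def predict_ln(strf: STRF, sig: SigmoidParams, X) -> np.ndarray:
    """Full LN prediction: sigmoid(predict_linear), bounded in (rho4, rho4+rho1)."""
    return sigmoid(predict_linear(strf, X), sig)
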