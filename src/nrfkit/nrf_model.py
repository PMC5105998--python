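"""The network receptive field (NRF): a sparse single-hidden-layer perceptron.

Each of ``J`` hidden units (HUs) is itself an LN-like element: a linear
spectrotemporal filter over the lagged cochleagram followed by a fixed
saturating nonlinearity

    g(zeta) = rho1 * tanh(zeta / rho2),   rho1 = 1/tanh(2/3), rho2 = 3/2,

chosen so that g(+-1) = +-1.  A single output unit (OU) takes a weighted
sum of HU outputs through the same nonlinearity and predicts the (rescaled)
PSTH.  Fitting minimizes

    E = 1/2 sum_t (yhat(t) - y(t))^2 + lambda * (sum|w_jft| + sum|w_j|)

(biases unpenalized).  The L1 term prunes redundant HUs: their weights
shrink to (exactly) zero, leaving a small set of "effective" sub-receptive-
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "RHO1",
    "RHO2",
    "NRFParams",
    "NRFHyper",
    "ForwardTrace",
    "activation_g",
    "activation_g_prime",
    "forward",
    "objective",
    "smooth_loss_and_grad",
    "init_params",
    "train",
]

#: fixed activation-function constants: g(+-1) = +-1
RHO1 = 1.0 / np.tanh(2.0 / 3.0)
RHO2 = 1.5

#: weights with |w| below this are reported as pruned (exact-zero bookkeeping)
PRUNE_TOL = 1e-8


@dataclass
class NRFParams:
    """All free parameters of the network."""

    w_in: np.ndarray     # (J, F, H) hidden weights w_jft
    b_hidden: np.ndarray  # (J,)
    w_out: np.ndarray    # (J,)
    b_out: float

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_in.ndim != 3:
            raise ValueError("w_in must have shape (J, F, H)")
        J = self.w_in.shape[0]
        if self.b_hidden.shape != (J,) or self.w_out.shape != (J,):
            raise ValueError("inconsistent hidden-unit count")

    @property
    def J(self) -> int:
        return self.w_in.shape[0]

    @property
    def shape(self):
        return self.w_in.shape[1:]

    def pruned_mask(self):
        """Per-HU flag: every input and output weight below the prune tolerance."""
        flat = np.abs(self.w_in.reshape(self.J, -1)).max(axis=1)
        return (flat < PRUNE_TOL) & (np.abs(self.w_out) < PRUNE_TOL)


@dataclass
class NRFHyper:
    """Hyperparameters of the network and its optimizer."""

    J: int = 20
    lam: float = 0.0
    max_iter: int = 40       # outer optimizer iterations
    inner_iter: int = 25     # L-BFGS-B iterations per outer iteration
    rel_tol: float = 1e-6    # convergence on relative objective change
    seed: int = 0
    rho1: float = RHO1
    rho2: float = RHO2

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.J < 1:
            raise ValueError("J must be >= 1")


@dataclass
class ForwardTrace:
    a_hidden: np.ndarray  # (T, J)
    z_hidden: np.ndarray  # (T, J)
    a_out: np.ndarray     # (T,)
    y_hat: np.ndarray     # (T,) rescaled units


def activation_g(zeta, rho1: float = RHO1, rho2: float = RHO2):
    """g(zeta) = rho1 * tanh(zeta/rho2); odd, bounded in (-rho1, rho1)."""
    return rho1 * np.tanh(np.asarray(zeta, dtype=float) / rho2)


def activation_g_prime(zeta, rho1: float = RHO1, rho2: float = RHO2):
    t = np.tanh(np.asarray(zeta, dtype=float) / rho2)
    return (rho1 / rho2) * (1.0 - t * t)


def _design(X) -> np.ndarray:
    X = X.windows if hasattr(X, "windows") else np.asarray(X, dtype=float)
    return X.reshape(X.shape[0], -1) if X.ndim == 3 else X


def forward(params: NRFParams, X) -> ForwardTrace:
    """Run the network on lagged stimulus windows.

    a_j(t) = sum_{f,tau} w_jft x_ft(t) + b_j ; z_j = g(a_j)
    a_o(t) = sum_j w_j z_j(t) + b_o          ; yhat = g(a_o)
    """
    D = _design(X)
    W = params.w_in.reshape(params.J, -1).T  # (F*H, J)
    a_h = D @ W + params.b_hidden
    z = activation_g(a_h)
    a_o = z @ params.w_out + params.b_out
    return ForwardTrace(a_hidden=a_h, z_hidden=z, a_out=a_o,
                        y_hat=activation_g(a_o))


def objective(params: NRFParams, X, y_rescaled, lam: float) -> float:
    """E = 1/2 sum (yhat - y)^2 + lam * (sum|w_in| + sum|w_out|)."""
    y = np.asarray(y_rescaled, dtype=float).ravel()
    r = forward(params, X).y_hat - y
    penalty = lam * (np.abs(params.w_in).sum() + np.abs(params.w_out).sum())
    return 0.5 * float(r @ r) + penalty


def smooth_loss_and_grad(params: NRFParams, X, y_rescaled):
    """Squared-error part of E and its analytic gradient (backpropagation)."""
    D = _design(X)
    y = np.asarray(y_rescaled, dtype=float).ravel()
    tr = forward(params, D)
    r = tr.y_hat - y
    loss = 0.5 * float(r @ r)
    delta_o = r * activation_g_prime(tr.a_out)          # (T,)
    g_b_out = float(delta_o.sum())
    g_w_out = tr.z_hidden.T @ delta_o                   # (J,)
    delta_h = delta_o[:, None] * params.w_out[None, :] \
        * activation_g_prime(tr.a_hidden)               # (T, J)
    g_b_hidden = delta_h.sum(axis=0)
    g_w_in = (D.T @ delta_h).T.reshape(params.w_in.shape)
    return loss, NRFParams(w_in=g_w_in, b_hidden=g_b_hidden,
                           w_out=g_w_out, b_out=g_b_out)


def init_params(hyper: NRFHyper, F: int, H: int,
                rng: np.random.Generator | None = None) -> NRFParams:
    """Uniform +-1/M initialization, M = incoming weights + biases per unit.

    Hidden units draw from +-1/(F*H + 1); the output unit from +-1/(J + 1).
    Deterministic given the hyperparameter seed.
    """
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    J = hyper.J
    m_hidden = F * H + 1
    m_out = J + 1
    w_in = rng.uniform(-1.0 / m_hidden, 1.0 / m_hidden, size=(J, F, H))
    b_hidden = rng.uniform(-1.0 / m_hidden, 1.0 / m_hidden, size=J)
    w_out = rng.uniform(-1.0 / m_out, 1.0 / m_out, size=J)
    b_out = float(rng.uniform(-1.0 / m_out, 1.0 / m_out))
    return NRFParams(w_in=w_in, b_hidden=b_hidden, w_out=w_out, b_out=b_out)


def _pack(params: NRFParams):
    """Variable layout for the bound-constrained solve: w = u - v, u,v >= 0."""
    w_in = params.w_in.ravel()
    w_out = params.w_out
    return np.concatenate([
        np.clip(w_in, 0, None), np.clip(-w_in, 0, None),
        np.clip(w_out, 0, None), np.clip(-w_out, 0, None),
        params.b_hidden, [params.b_out]])


def _unpack(theta, J, F, H) -> NRFParams:
    n_in = J * F * H
    u_in = theta[:n_in]
    v_in = theta[n_in:2 * n_in]
    off = 2 * n_in
    u_out = theta[off:off + J]
    v_out = theta[off + J:off + 2 * J]
    off += 2 * J
    b_hidden = theta[off:off + J]
    b_out = theta[off + J]
    return NRFParams(w_in=(u_in - v_in).reshape(J, F, H), b_hidden=b_hidden,
                     w_out=u_out - v_out, b_out=float(b_out))


def train(X, y_rescaled, hyper: NRFHyper,
          init: NRFParams | None = None,
          history: list | None = None) -> NRFParams:
    """Fit the network by penalized least squares.

    The L1-penalized objective is solved as a smooth bound-constrained
    problem by splitting every weight into positive and negative parts
    (``w = u - v`` with ``u, v >= 0`` and penalty ``lam * sum(u + v)``) and
    running L-BFGS-B, which drives redundant weights exactly to the zero
    bound.  Up to ``max_iter`` outer iterations of ``inner_iter`` solver
    steps are run; convergence is declared early when the relative objective
    change over an outer iteration falls below ``rel_tol``.  Deterministic
    given the seed; the returned objective never exceeds the initial one.

    ``history``, if given, collects the objective at initialization and
    after every outer iteration.
    """
    D = _design(X)
    y = np.asarray(y_rescaled, dtype=float).ravel()
    if D.shape[0] != y.size:
        raise ValueError("stimulus and target lengths differ")
    if hasattr(X, "windows"):
        F, H = X.windows.shape[1:]
    else:
        Xa = np.asarray(X)
        F, H = Xa.shape[1:] if Xa.ndim == 3 else (1, D.shape[1])
    J, lam = hyper.J, hyper.lam
    if init is None:
        init = init_params(hyper, F, H)
    theta = _pack(init)
    n_w = 2 * J * F * H + 2 * J
    bounds = [(0.0, None)] * n_w + [(None, None)] * (J + 1)
    pen_mask = np.zeros(theta.size)
    pen_mask[:n_w] = lam

    def fun(t):
        p = _unpack(t, J, F, H)
        loss, g = smooth_loss_and_grad(p, D, y)
        if not np.isfinite(loss):
            raise FloatingPointError("objective diverged (non-finite loss)")
        g_in = g.w_in.ravel()
        grad = np.concatenate([g_in + lam, -g_in + lam,
                               g.w_out + lam, -g.w_out + lam,
                               g.b_hidden, [g.b_out]])
        return loss + float(pen_mask @ t), grad

    e_prev = fun(theta)[0]
    if history is not None:
        history.append(e_prev)
    best_theta, best_e = theta.copy(), e_prev
    for _ in range(hyper.max_iter):
        res = minimize(fun, theta, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": hyper.inner_iter, "ftol": 0.0,
                                "gtol": 1e-12})
        theta = res.x
        e = res.fun
        if history is not None:
            history.append(min(e, best_e))
        if e < best_e:
            best_theta, best_e = theta.copy(), e
        if e_prev - e <= hyper.rel_tol * max(abs(e_prev), 1.0):
            break
        e_prev = e
    out = _unpack(best_theta, J, F, H)
    # snap sub-tolerance magnitudes left by the bounded solve to exact zero
    out.w_in[np.abs(out.w_in) < PRUNE_TOL] = 0.0
    out.w_out[np.abs(out.w_out) < PRUNE_TOL] = 0.0
    return out
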