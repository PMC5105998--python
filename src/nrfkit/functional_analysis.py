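"""Functional probes of a fitted network: gain control and feature conjunction.

Two analyses interrogate what the excitatory/inhibitory interplay in a
fitted NRF does computationally.  For bi-feature fits (one effective
excitatory and one effective inhibitory HU) the OU firing rate is swept
against excitatory drive at several fixed inhibitory activation levels; a
sigmoidal OU makes the inhibition divisive (it scales down the gain, the
steepest slope of each curve) rather than subtractive.  For multi-feature
fits, "reduced" models that retain a single excitatory HU (all others
clamped below threshold) test whether the full model's supra-threshold
responses require feature conjunctions: the peak time ratio compares how
often the summed reduced responses exceed the observed 2-sigma peak
threshold relative to the full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import PeakWindow, peak_window
from .nrf_model import RHO1, RHO2, NRFParams, activation_g, forward
from .responses import unrescale_targets
from .rf_analysis import adjust_network, effective_hus

__all__ = [
    "GainCurves",
    "ConjunctionReport",
    "gain_analysis",
    "reduced_forward",
    "peak_time_ratio",
]

#: number of inhibitory activation levels in the gain analysis
N_LEVELS = 7
#: excitatory sweep resolution (central-difference slope estimation)
N_SWEEP = 201


@dataclass
class GainCurves:
    exc_axis: np.ndarray        # normalized excitatory activation (0 = 1st
                                # centile, 1 = 99th centile)
    inh_levels: np.ndarray      # normalized inhibitory activations (7,)
    curves: np.ndarray          # (7, n_points) OU rate, spike-count units
    gain_per_level: np.ndarray  # steepest slope of each curve
    gain_normalized: np.ndarray  # gain scaled to 1 at the lowest level


@dataclass
class ConjunctionReport:
    nrf_peak_time: int
    summed_reduced_peak_time: int
    peak_time_ratio: float  # nan when the full model never crosses threshold


def _percentile_axis(a: np.ndarray):
    lo, hi = np.percentile(a, [1.0, 99.0])
    if hi <= lo:
        raise ValueError("degenerate activation distribution")
    return lo, hi


def gain_analysis(params: NRFParams, X, n_levels: int = N_LEVELS,
                  n_points: int = N_SWEEP,
                  output_nonlinearity: str = "sigmoid",
                  exc_hu: int | None = None,
                  inh_hu: int | None = None) -> GainCurves:
    """OU rate versus excitatory drive at fixed inhibitory drive levels.

    Requires a bi-feature fit: exactly one effective excitatory and one
    effective inhibitory HU.  The inhibitory activation is clamped at
    ``n_levels`` values evenly spanning its observed range; the excitatory
    activation is swept over its full operating range, from HU threshold to
    saturation (i.e. beyond its 1st/99th activation centiles, which define
    the normalized axis).  The OU rate is

        rate = unrescale( g_out( w_E g(a_E) + w_I g(a_I) + b_o ) )

    and each curve's gain is its steepest slope with respect to the
    normalized excitatory axis (central differences).  With
    ``output_nonlinearity='linear'`` the OU applies the identity instead of
    g, in which case the inhibitory term is purely additive and the gain is
    level-independent.  ``exc_hu``/``inh_hu`` override the automatic
    effective-HU identification (useful for probing designed networks).
    """
    adj = adjust_network(params)
    p = adj.params
    if exc_hu is None or inh_hu is None:
        profiles = effective_hus(p, X)
        exc = [q for q in profiles if q.effective and q.kind == "excitatory"]
        inh = [q for q in profiles if q.effective and q.kind == "inhibitory"]
        if len(exc) != 1 or len(inh) != 1:
            raise ValueError(
                f"gain analysis needs a bi-feature fit (1 excitatory + 1 "
                f"inhibitory effective HU); got {len(exc)} + {len(inh)} — use "
                f"the conjunction analysis for multi-feature fits")
        je = exc[0].index if exc_hu is None else exc_hu
        ji = inh[0].index if inh_hu is None else inh_hu
    else:
        je, ji = exc_hu, inh_hu
    tr = forward(p, X)
    a_e, a_i = tr.a_hidden[:, je], tr.a_hidden[:, ji]
    e_lo, e_hi = _percentile_axis(a_e)
    i_lo, i_hi = _percentile_axis(a_i)
    # sweep from HU threshold to saturation: cover the observed range and
    # the near-full swing of the tanh (|tanh| > 0.999 at |zeta/rho2| > 3.8)
    sat = 3.8 * RHO2
    sweep = np.linspace(min(a_e.min(), -sat), max(a_e.max(), sat), n_points)
    levels = np.linspace(a_i.min(), a_i.max(), n_levels)
    axis = (sweep - e_lo) / (e_hi - e_lo)
    curves = np.empty((n_levels, n_points))
    for k, lev in enumerate(levels):
        a_o = (p.w_out[je] * activation_g(sweep)
               + p.w_out[ji] * activation_g(lev) + p.b_out)
        out = a_o if output_nonlinearity == "linear" else activation_g(a_o)
        curves[k] = unrescale_targets(out)
    slopes = np.gradient(curves, axis, axis=1)
    gains = slopes.max(axis=1)
    return GainCurves(exc_axis=axis,
                      inh_levels=(levels - i_lo) / (i_hi - i_lo),
                      curves=curves, gain_per_level=gains,
                      gain_normalized=gains / gains[0])


def reduced_forward(params: NRFParams, X, keep_exc_hu: int,
                    effective_exc=None, rho1: float = RHO1) -> np.ndarray:
    """Prediction (rescaled units) with all other effective excitatory HUs
    disabled: their outputs clamped below threshold at the minimum -rho1.

    ``params`` must be adjusted (excitatory = positive output weight);
    inhibitory and ineffective HUs are untouched.  When ``keep_exc_hu`` is
    the only effective excitatory HU the reduced model equals the full one.
    """
    if effective_exc is None:
        effective_exc = [q.index for q in effective_hus(params, X)
                         if q.effective and q.kind == "excitatory"]
    if keep_exc_hu not in effective_exc:
        raise ValueError("keep_exc_hu must be an effective excitatory HU")
    tr = forward(params, X)
    z = tr.z_hidden.copy()
    for j in effective_exc:
        if j != keep_exc_hu:
            z[:, j] = -rho1
    a_o = z @ params.w_out + params.b_out
    return activation_g(a_o)


def peak_time_ratio(params: NRFParams, X_clips, y_obs_clips,
                    window: PeakWindow | None = None) -> ConjunctionReport:
    """Conjunctive-selectivity index from single-excitatory-HU reduced models.

    For each effective excitatory HU a reduced model retains only that HU
    (others clamped at -rho1); the reduced predictions are summed over HUs
    and, like the full prediction, compared per clip against the observed
    PSTH's 2-sigma peak threshold (mu_n + 2 sigma_n, spike-count units).
    The ratio (summed-reduced peak time / NRF peak time) is < 1 when
    supra-threshold responses of the full model require the conjunction of
    several excitatory features.
    """
    X_clips = X_clips if isinstance(X_clips, (list, tuple)) else [X_clips]
    y_obs = y_obs_clips if isinstance(y_obs_clips, (list, tuple)) else [y_obs_clips]
    if window is None:
        window = peak_window(y_obs)
    p = adjust_network(params).params
    X_all = np.concatenate([x.windows if hasattr(x, "windows") else np.asarray(x)
                            for x in X_clips])
    exc = [q.index for q in effective_hus(p, X_all)
           if q.effective and q.kind == "excitatory"]
    if len(exc) < 2:
        raise ValueError("conjunction analysis needs >= 2 effective "
                         "excitatory HUs")
    full, summed = 0, 0
    offset = 0
    for x, y in zip(X_clips, y_obs):
        T = len(np.asarray(y).ravel())
        thr = window.mu[offset] + 2.0 * window.sigma[offset]
        rate_full = unrescale_targets(forward(p, x).y_hat)
        rate_sum = sum(unrescale_targets(reduced_forward(p, x, j, exc))
                       for j in exc)
        full += int(np.count_nonzero(rate_full >= thr))
        summed += int(np.count_nonzero(rate_sum >= thr))
        offset += 1
    ratio = summed / full if full > 0 else float("nan")
    return ConjunctionReport(nrf_peak_time=full,
                             summed_reduced_peak_time=summed,
                             peak_time_ratio=ratio)
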