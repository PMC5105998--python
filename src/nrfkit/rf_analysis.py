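"""Post-fit interpretation of a fitted network.

A fitted NRF is first sign-canonicalized ("adjusted"): the tanh units are
odd, so negating an HU's input weights, bias and output weight together
leaves the prediction unchanged.  After flipping every HU whose STRF
weight-sum is negative, the sign of the output weight alone classifies the
HU as excitatory or inhibitory, and an equivalent non-negative-output
description is obtained by shifting HU outputs up by rho1 and absorbing the
shift into the OU bias.

From the adjusted network we derive: the "effective" HUs (weighted-output
variance >= 5% of the summed variance over all HUs), the IE score (net
excitatory/inhibitory balance of a sub-field), the EC score (operating
point on the nonlinearity: -1 threshold/expansive, 0 linear, +1
saturation/compressive), display STRFs, half-max contours, and power-STRF
tuning widths on an 8x spline-interpolated grid (1/48-octave frequency
bins at the default 1/6-octave channel spacing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RectBivariateSpline
from skimage import measure

from .nrf_model import RHO1, NRFParams, forward

__all__ = [
    "AdjustedNRF",
    "HUProfile",
    "TuningWidths",
    "adjust_network",
    "effective_hus",
    "ie_score",
    "ec_score",
    "display_strf",
    "interpolate_strf",
    "power_strf",
    "tuning_widths",
    "contours",
]

#: weighted-output variance fraction above which an HU counts as effective
EFFECTIVE_FRACTION = 0.05

#: interpolation factor for display/width analyses (7 inserted points per gap)
INTERP_FACTOR = 8


@dataclass
class AdjustedNRF:
    """Sign-canonicalized network, prediction-equivalent to the original."""

    params: NRFParams
    nonneg_bias_shift: float  # OU bias in the non-negative-output description
    flipped: np.ndarray       # which HUs had their sign triplet negated


@dataclass
class HUProfile:
    index: int
    kind: str                        # "excitatory" | "inhibitory"
    weighted_output_variance: float
    variance_fraction: float
    effective: bool
    ie: float                        # nan for an all-zero STRF
    ec: float


@dataclass
class TuningWidths:
    freq_width_quarter: float  # octaves
    freq_width_half: float
    time_width_quarter: float  # ms
    time_width_half: float


def adjust_network(params: NRFParams, rho1: float = RHO1) -> AdjustedNRF:
    """Flip the sign triplet of every HU whose STRF weight-sum is negative.

    After adjustment each HU has ``sum_{f,tau} w_jft >= 0`` and predictions
    are unchanged; excitation/inhibition then reads off the sign of ``w_j``.
    The recorded bias shift ``b_o - rho1 * sum_j w_j`` is the OU bias of the
    equivalent description in which HU outputs are shifted to ``[0, 2*rho1]``.
    """
    sums = params.w_in.reshape(params.J, -1).sum(axis=1)
    flip = sums < 0
    sign = np.where(flip, -1.0, 1.0)
    adjusted = NRFParams(w_in=params.w_in * sign[:, None, None],
                         b_hidden=params.b_hidden * sign,
                         w_out=params.w_out * sign,
                         b_out=params.b_out)
    shift = adjusted.b_out - rho1 * adjusted.w_out.sum()
    return AdjustedNRF(params=adjusted, nonneg_bias_shift=float(shift),
                       flipped=flip)


def ie_score(w_jft: np.ndarray, w_j: float) -> float:
    """IE = sign(w_j) * sum(w_jft) / sum|w_jft|, bounded in [-1, 1]."""
    denom = np.abs(w_jft).sum()
    if denom == 0:
        raise ValueError("IE undefined for an all-zero STRF")
    return float(np.sign(w_j) * w_jft.sum() / denom)


def ec_score(outputs, rho1: float = RHO1, rho4: float = 0.0,
             rho5: float = 0.0, rho6: float = 1.0) -> float:
    """Operating point of a unit: EC = (rho6/rho1)(<output> - rho4) - rho5.

    Scaled so EC = -1 with the unit pinned at threshold and +1 at
    saturation.  NRF units (outputs in (-rho1, rho1)) use rho4 = 0,
    rho5 = 0, rho6 = 1; LN units (outputs in (rho4, rho4 + rho1)) use the
    fitted rho1, rho4 with rho5 = 1, rho6 = 2.
    """
    if rho1 == 0:
        raise ValueError("rho1 must be nonzero")
    mean_out = float(np.mean(outputs))
    return (rho6 / rho1) * (mean_out - rho4) - rho5


def effective_hus(params: NRFParams, X, rho1: float = RHO1) -> list:
    """Profile every HU of the (internally adjusted) network over stimuli X.

    The variance over the stimulus set of each HU's weighted output
    ``w_j * z_j(t)`` is expressed as a fraction of the summed variance over
    all J HUs; HUs at or above the 5% fraction are effective.  IE and EC
    are computed on the adjusted network so they respect the sign-flip
    symmetry.
    """
    adj = adjust_network(params, rho1).params
    tr = forward(adj, X)
    weighted = tr.z_hidden * adj.w_out[None, :]
    variances = weighted.var(axis=0)
    total = variances.sum()
    if total == 0:
        warnings.warn("all weighted-output variances are zero; no effective HUs")
        fractions = np.zeros(params.J)
    else:
        fractions = variances / total
    profiles = []
    for j in range(params.J):
        try:
            ie = ie_score(adj.w_in[j], adj.w_out[j])
        except ValueError:
            ie = float("nan")
        ec = ec_score(tr.z_hidden[:, j], rho1=rho1)
        kind = "excitatory" if adj.w_out[j] >= 0 else "inhibitory"
        profiles.append(HUProfile(
            index=j, kind=kind,
            weighted_output_variance=float(variances[j]),
            variance_fraction=float(fractions[j]),
            effective=bool(total > 0 and fractions[j] >= EFFECTIVE_FRACTION),
            ie=ie, ec=ec))
    return profiles


def display_strf(weights: np.ndarray, kind: str) -> np.ndarray:
    """STRF as displayed: inhibitory HUs are sign-reversed so the matrix
    shows the direction of effect on the model output."""
    w = np.asarray(weights, dtype=float)
    return -w if kind == "inhibitory" else w.copy()


def interpolate_strf(w: np.ndarray, factor: int = INTERP_FACTOR) -> np.ndarray:
    """Cubic-spline interpolation onto a grid ``factor`` times finer.

    Inserts ``factor - 1`` values between neighboring samples on both axes
    (output shape ``((F-1)*factor + 1, (H-1)*factor + 1)``); spline order
    degrades gracefully for very small matrices.
    """
    w = np.asarray(w, dtype=float)
    nf, nh = w.shape
    f = np.arange(nf)
    h = np.arange(nh)
    kx = min(3, nf - 1)
    ky = min(3, nh - 1)
    if kx < 1 or ky < 1:
        raise ValueError("STRF too small to interpolate")
    spl = RectBivariateSpline(f, h, w, kx=kx, ky=ky, s=0)
    ff = np.linspace(0, nf - 1, (nf - 1) * factor + 1)
    hh = np.linspace(0, nh - 1, (nh - 1) * factor + 1)
    return spl(ff, hh)


def power_strf(model, X=None, factor: int = INTERP_FACTOR) -> np.ndarray:
    """Interpolated power STRF: squared elements of the 8x-interpolated STRF.

    ``model`` may be a single weight matrix / linear-model STRF, or fitted
    :class:`NRFParams` (with stimuli ``X``), in which case the per-HU power
    STRFs of the effective HUs are summed, each weighted by the variance of
    that HU's weighted output (its signal strength at the OU).
    """
    if isinstance(model, NRFParams):
        if X is None:
            raise ValueError("NRF power STRF needs a stimulus set")
        adj = adjust_network(model).params
        profiles = effective_hus(model, X)
        total = np.zeros(((model.shape[0] - 1) * factor + 1,
                          (model.shape[1] - 1) * factor + 1))
        any_eff = False
        for p in profiles:
            if not p.effective:
                continue
            any_eff = True
            interp = interpolate_strf(adj.w_in[p.index], factor)
            total += p.weighted_output_variance * interp ** 2
        if not any_eff:
            raise ValueError("no effective HUs: power STRF undefined")
        return total
    w = model.w if hasattr(model, "w") else np.asarray(model, dtype=float)
    return interpolate_strf(w, factor) ** 2


def tuning_widths(power: np.ndarray, spacing_octaves: float = 1.0 / 6.0,
                  bin_ms: float = 5.0,
                  factor: int = INTERP_FACTOR) -> TuningWidths:
    """Marginal tuning widths of an interpolated power STRF.

    The power matrix (frequency x time, already on the ``factor``-times
    finer grid) is summed over each axis; the width at a height fraction is
    the number of interpolated bins at or above ``fraction * max`` times the
    interpolated bin size (``spacing/factor`` octaves; ``bin_ms/factor``
    ms).  Invariant to positive rescaling of the weights.
    """
    power = np.asarray(power, dtype=float)
    if power.max() <= 0:
        raise ValueError("all-zero power STRF: widths undefined")
    freq_profile = power.sum(axis=1)
    time_profile = power.sum(axis=0)

    def width(profile, frac, unit):
        return float(np.count_nonzero(profile >= frac * profile.max()) * unit)

    f_unit = spacing_octaves / factor
    t_unit = bin_ms / factor
    return TuningWidths(
        freq_width_quarter=width(freq_profile, 0.25, f_unit),
        freq_width_half=width(freq_profile, 0.5, f_unit),
        time_width_quarter=width(time_profile, 0.25, t_unit),
        time_width_half=width(time_profile, 0.5, t_unit))


def contours(display: np.ndarray, kind: str = "excitatory",
             factor: int = INTERP_FACTOR) -> list:
    """Half-maximum level-set polygons of an interpolated display STRF.

    Excitatory HUs are contoured at half the maximum of the interpolated
    matrix; inhibitory HUs at half the minimum.  Returns a list of (N, 2)
    arrays in interpolated-grid coordinates (row = frequency index, col =
    time index); a flat STRF yields an empty list.
    """
    interp = interpolate_strf(np.asarray(display, dtype=float), factor)
    if np.ptp(interp) == 0:
        return []
    level = 0.5 * (interp.max() if kind == "excitatory" else interp.min())
    return [np.asarray(c) for c in measure.find_contours(interp, level)]
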