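"""Noise-corrected prediction metrics: CC_raw, CC_half, CC_max, CC_norm, pMSE.

A model can only be as good as the neuron is reliable, so raw prediction
correlations are normalized by the ceiling achievable given trial-to-trial
noise: ``CC_norm = CC_raw / CC_max``, with ``CC_max`` estimated from the
split-half reliability ``CC_half`` of the trials via

    CC_max = sqrt( 2 / (1 + 1/CC_half) ).

The peak-activity MSE (pMSE) restricts the squared error to bins where the
observed PSTH exceeds its per-clip mean by two standard deviations.
All metrics operate on the un-rescaled spike-count scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .responses import smoothing_kernel

__all__ = [
    "MetricReport",
    "PeakWindow",
    "cc_raw",
    "cc_half",
    "cc_max",
    "cc_norm",
    "mse",
    "peak_window",
    "pmse",
    "evaluate_model",
]

#: number of random half-splits averaged for CC_half
N_SPLITS = 126


@dataclass
class MetricReport:
    cc_raw: float
    cc_half: float
    cc_max: float
    cc_norm: float
    mse: float
    pmse: float        # nan when no peak bins
    n_peak_bins: int


@dataclass
class PeakWindow:
    """Binary peak indicators p_n(t) = 1 iff y_n(t) >= mu_n + 2*sigma_n."""

    p: list            # per-clip boolean arrays
    mu: np.ndarray     # per-clip mean
    sigma: np.ndarray  # per-clip SD

    @property
    def n_peak_bins(self) -> int:
        return int(sum(w.sum() for w in self.p))


def _as_clips(y):
    if isinstance(y, (list, tuple)):
        return [np.asarray(v, dtype=float).ravel() for v in y]
    return [np.asarray(y, dtype=float).ravel()]


def _concat(y):
    return np.concatenate(_as_clips(y))


def cc_raw(y, y_hat) -> float:
    """Pearson correlation between observed and predicted responses."""
    a, b = _concat(y), _concat(y_hat)
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def cc_half(trials, n_splits: int = N_SPLITS, seed: int = 0,
            smooth_ms: float = 21.0, bin_ms: float = 5.0) -> float:
    """Mean split-half reliability of the trials.

    ``trials`` is a per-clip list of (R, T) binned counts (R even).  For
    each random disjoint half-partition, each half's trial-mean is smoothed
    with the same unit-sum Hanning kernel used for the full PSTH, halves are
    concatenated over clips, and their Pearson correlation taken; the mean
    over ``n_splits`` partitions is returned.
    """
    trials = [np.asarray(t, dtype=float) for t in
              (trials if isinstance(trials, (list, tuple)) else [trials])]
    R = trials[0].shape[0]
    if R < 2 or R % 2:
        raise ValueError("CC_half needs an even number of trials >= 2")
    kernel = smoothing_kernel(smooth_ms, bin_ms)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(R)
        ha, hb = perm[: R // 2], perm[R // 2:]
        ya = np.concatenate([np.convolve(t[ha].mean(axis=0), kernel, "same")
                             for t in trials])
        yb = np.concatenate([np.convolve(t[hb].mean(axis=0), kernel, "same")
                             for t in trials])
        vals[s] = np.corrcoef(ya, yb)[0, 1]
    return float(vals.mean())


def cc_max(cc_half_value: float) -> float:
    """Reliability ceiling: CC_max = sqrt(2 / (1 + 1/CC_half)).

    Monotone in CC_half with CC_max(1) = 1.  Non-positive CC_half (possible
    for pure-noise neurons) leaves the ceiling undefined.
    """
    if cc_half_value <= 0:
        raise ValueError("CC_max undefined for CC_half <= 0; flag the neuron")
    if cc_half_value > 1:
        cc_half_value = 1.0
    return float(np.sqrt(2.0 / (1.0 + 1.0 / cc_half_value)))


def cc_norm(y, y_hat, trials=None, cc_half_value: float | None = None,
            n_splits: int = N_SPLITS, seed: int = 0) -> float:
    """CC_raw / CC_max; falls back to CC_raw when no trials are available."""
    raw = cc_raw(y, y_hat)
    if cc_half_value is None:
        if trials is None:
            return raw
        cc_half_value = cc_half(trials, n_splits=n_splits, seed=seed)
    return raw / cc_max(cc_half_value)


def mse(y, y_hat) -> float:
    a, b = _concat(y), _concat(y_hat)
    return float(np.mean((a - b) ** 2))


def peak_window(y) -> PeakWindow:
    """Per-clip 2-sigma peak indicators from the observed response."""
    clips = _as_clips(y)
    mu = np.array([c.mean() for c in clips])
    sigma = np.array([c.std() for c in clips])
    # a flat clip (sigma = 0) has no peaks: every bin sits at the mean
    p = [(c >= m + 2 * s) if s > 0 else np.zeros(c.size, dtype=bool)
         for c, m, s in zip(clips, mu, sigma)]
    return PeakWindow(p=p, mu=mu, sigma=sigma)


def pmse(y, y_hat, window: PeakWindow | None = None) -> tuple[float, int]:
    """Mean squared error over peak bins only; returns (pmse, n_peak_bins).

    pmse is nan when no bin exceeds the per-clip 2-sigma threshold (e.g. a
    constant response).
    """
    clips, preds = _as_clips(y), _as_clips(y_hat)
    if window is None:
        window = peak_window(clips)
    n = window.n_peak_bins
    if n == 0:
        return float("nan"), 0
    err = 0.0
    for c, pr, p in zip(clips, preds, window.p):
        err += float(((pr[p] - c[p]) ** 2).sum())
    return err / n, n


def evaluate_model(y, y_hat, trials=None, n_splits: int = N_SPLITS,
                   seed: int = 0) -> MetricReport:
    """All performance measures for one model on one neuron."""
    raw = cc_raw(y, y_hat)
    if trials is not None:
        half = cc_half(trials, n_splits=n_splits, seed=seed)
        ceil = cc_max(half)
    else:
        half, ceil = float("nan"), 1.0
    p, n_peak = pmse(y, y_hat)
    return MetricReport(cc_raw=raw, cc_half=half, cc_max=ceil,
                        cc_norm=raw / ceil, mse=mse(y, y_hat),
                        pmse=p, n_peak_bins=n_peak)
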