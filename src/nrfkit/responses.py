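"""Neural response preprocessing: PSTHs, noise-ratio screening, target rescaling.

Per-trial spike counts (5 ms bins by default) are averaged over trials and
smoothed with a short unit-sum Hanning kernel to estimate the spike-count
PSTH ``y_n(t_n)`` for each clip; the stimulus-onset transient is discarded
and the retained bins are aligned 1:1 with the cochleagram frames.  A
noise-ratio statistic screens out neurons whose firing is not reliably
stimulus driven, and an affine rescaling maps spike counts onto the
symmetric range of the network activation function for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

__all__ = [
    "SIGMA1",
    "TrialResponses",
    "PSTH",
    "NoiseRatioReport",
    "smoothing_kernel",
    "compute_psth",
    "noise_ratio",
    "rescale_targets",
    "unrescale_targets",
    "bin_spike_times",
]

#: amplitude of the symmetric training range: counts 0/1 map to -/+ sigma1
SIGMA1 = 1.0 / np.tanh(2.0 / 3.0)  # ~1.7159

#: noise-ratio exclusion threshold
NR_EXCLUDE = 40.0


@dataclass
class TrialResponses:
    """Per-trial binned spike counts, one array of shape (R, n_bins) per clip."""

    counts: list  # list of (R, n_bins) arrays
    bin_ms: float = 5.0
    clip_ids: list | None = None

    def __post_init__(self) -> None:
        self.counts = [np.asarray(c, dtype=float) for c in self.counts]
        if not self.counts:
            raise ValueError("no clips")
        R = self.counts[0].shape[0]
        if any(c.shape[0] != R for c in self.counts):
            raise ValueError("all clips must share the same trial count")
        if np.any([np.any(c < 0) for c in self.counts]):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts[0].shape[0]


@dataclass
class PSTH:
    """Smoothed trial-mean spike counts per clip, onset transient removed."""

    y: list  # list of 1-D arrays, one per clip
    bin_ms: float
    onset_discard_ms: float
    clip_ids: list | None = None


@dataclass
class NoiseRatioReport:
    signal_power: float
    noise_power: float
    nr: float
    excluded: bool


def smoothing_kernel(smooth_ms: float = 21.0, bin_ms: float = 5.0) -> np.ndarray:
    """Unit-sum Hanning kernel; width rounded to the nearest odd bin count."""
    n = int(round(smooth_ms / bin_ms))
    if n % 2 == 0:
        n += 1
    if n <= 1:
        return np.ones(1)
    k = hann(n, sym=True)
    return k / k.sum()


def bin_spike_times(table: pd.DataFrame, clip_duration_s: float, n_trials: int,
                    bin_ms: float = 5.0, clip_ids=None) -> TrialResponses:
    """Bin a spike table (columns clip_id, trial, spike_time_s) into counts.

    ``trial`` is 0-based.  Spike times at or beyond the clip duration are an
    input error.
    """
    if clip_ids is None:
        clip_ids = sorted(table["clip_id"].unique())
    n_bins = int(round(clip_duration_s * 1000.0 / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms / 1000.0
    counts = []
    for cid in clip_ids:
        sub = table[table["clip_id"] == cid]
        if len(sub) and sub["spike_time_s"].max() >= clip_duration_s:
            raise ValueError(f"spike time beyond clip duration in clip {cid}")
        mat = np.zeros((n_trials, n_bins))
        for r in range(n_trials):
            t = sub.loc[sub["trial"] == r, "spike_time_s"].to_numpy()
            mat[r], _ = np.histogram(t, bins=edges)
        counts.append(mat)
    return TrialResponses(counts=counts, bin_ms=bin_ms, clip_ids=list(clip_ids))


def _smooth(mean_counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(mean_counts, kernel, mode="same")


def compute_psth(responses: TrialResponses, smooth_ms: float = 21.0,
                 onset_discard_ms: float = 250.0,
                 frame_ms: float = 10.0) -> PSTH:
    """Trial-average, smooth, and trim each clip's counts into the PSTH.

    The order follows the preprocessing pipeline: average over trials,
    convolve with the unit-sum Hanning kernel, then drop the onset-transient
    bins.  Trailing bins without a fully contained analysis frame are also
    dropped so PSTH bins align 1:1 with cochleagram frames (a 5 s clip at
    5 ms bins and 10 ms frames keeps 999 bins; a 250 ms discard leaves 949).
    """
    kernel = smoothing_kernel(smooth_ms, responses.bin_ms)
    d = int(round(onset_discard_ms / responses.bin_ms))
    tail = max(int(round(frame_ms / responses.bin_ms)) - 1, 0)
    y = []
    for c in responses.counts:
        sm = _smooth(c.mean(axis=0), kernel)
        stop = sm.size - tail
        if d >= stop:
            raise ValueError("onset discard leaves no bins")
        y.append(sm[d:stop])
    return PSTH(y=y, bin_ms=responses.bin_ms, onset_discard_ms=onset_discard_ms,
                clip_ids=responses.clip_ids)


def noise_ratio(responses: TrialResponses) -> NoiseRatioReport:
    """Signal/noise power decomposition of the per-trial responses.

    With ``R`` trials, writing ``V_mean`` for the variance over time of the
    trial-averaged response and ``V_trial`` for the mean over trials of the
    per-trial variance over time, the unbiased signal-power estimate is

        SP = (R * V_mean - V_trial) / (R - 1)

    the noise power is ``NP = V_trial - SP``, and the noise ratio is the
    residual noise power in the trial-averaged response relative to the
    signal power:

        NR = NP / (R * SP)

    Identical trials give NR = 0; stimulus-independent firing gives a large
    NR and the neuron is flagged (threshold ``NR_EXCLUDE`` = 40).  Non-
    positive signal power is reported as NR = +inf.
    """
    R = responses.n_trials
    if R < 2:
        raise ValueError("noise ratio requires at least 2 trials")
    all_counts = np.concatenate(responses.counts, axis=1)  # (R, total bins)
    v_mean = all_counts.mean(axis=0).var()
    v_trial = all_counts.var(axis=1).mean()
    sp = (R * v_mean - v_trial) / (R - 1)
    np_ = v_trial - sp
    if sp <= 0:
        return NoiseRatioReport(signal_power=sp, noise_power=np_,
                                nr=np.inf, excluded=True)
    nr = np_ / (R * sp)
    return NoiseRatioReport(signal_power=sp, noise_power=np_, nr=nr,
                            excluded=bool(nr > NR_EXCLUDE))


def rescale_targets(y, sigma1: float = SIGMA1):
    """Map spike counts onto the network output range: y' = sigma1*(2y - 1).

    Count 0 maps to -sigma1 and count 1 to +sigma1.  Accepts an array or a
    per-clip list of arrays.
    """
    if isinstance(y, (list, tuple)):
        return [rescale_targets(v, sigma1) for v in y]
    return sigma1 * (2.0 * np.asarray(y, dtype=float) - 1.0)


def unrescale_targets(y_rescaled, sigma1: float = SIGMA1):
    """Inverse of :func:`rescale_targets`: y = (y'/sigma1 + 1)/2."""
    if isinstance(y_rescaled, (list, tuple)):
        return [unrescale_targets(v, sigma1) for v in y_rescaled]
    return (np.asarray(y_rescaled, dtype=float) / sigma1 + 1.0) / 2.0
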