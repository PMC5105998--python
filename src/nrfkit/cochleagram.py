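"""Cochleagram front-end: audio -> log-power spectrogram on a log-spaced filterbank.

The models in this package predict neural firing from a "cochleagram", a
coarse approximation of the input delivered by the auditory periphery: a
Hamming-windowed power spectrogram whose Fourier bins are pooled by
overlapping triangular windows onto geometrically spaced frequency channels
(1/6-octave spacing by default), followed by a log transform and a
dynamic-range floor.  The model input at time ``t`` is a lagged snippet of
the cochleagram, an ``F x H`` matrix of the ``H`` most recent frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import hamming

__all__ = [
    "AudioClip",
    "FilterBank",
    "Cochleagram",
    "LaggedStimulus",
    "read_wav",
    "build_filterbank",
    "compute_cochleagram",
    "normalize_dataset",
    "lag_stimulus",
]

#: default channel count of the filterbank
N_CHANNELS = 34
#: lowest channel center frequency, Hz
F_LO = 500.0
#: geometric channel spacing, octaves
SPACING_OCTAVES = 1.0 / 6.0
#: analysis frame length / hop, ms
FRAME_MS = 10.0
HOP_MS = 5.0
#: dynamic range retained below the dataset maximum, dB
FLOOR_DB = 60.0
#: stimulus history length, bins
H_DEFAULT = 20


@dataclass
class AudioClip:
    """A mono audio waveform with its sampling rate."""

    samples: np.ndarray
    rate: float
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class FilterBank:
    """Triangular aggregation weights mapping FFT bins onto log-spaced channels.

    ``weights[k]`` holds the non-negative triangular weights of channel ``k``
    over the one-sided FFT frequency grid; each triangle spans from the
    previous to the next center frequency (edge channels truncated).
    """

    center_freqs: np.ndarray
    weights: np.ndarray  # (n_channels, n_fft_bins)
    fft_freqs: np.ndarray


@dataclass
class Cochleagram:
    """Time x frequency matrix of floored log power."""

    values: np.ndarray  # (T, F)
    frame_hop: float  # ms
    frame_len: float  # ms
    channel_freqs: np.ndarray
    floor: float
    clip_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class LaggedStimulus:
    """Per-bin stimulus history windows ``x_ft(t)``.

    ``windows[i]`` is the ``F x H`` matrix for valid bin ``valid_bins[i]``
    (0-based frame index into the source cochleagram): column ``tau`` (0-based)
    holds cochleagram frame ``t - tau``, i.e. ``tau = 0`` is the current frame
    and ``tau = H - 1`` reaches ``H - 1`` frames into the past.
    """

    windows: np.ndarray  # (n_valid, F, H)
    H: int
    valid_bins: np.ndarray  # frame indices with full in-clip history


def read_wav(path, clip_id: str = "") -> AudioClip:
    """Read a PCM or float WAV file as a mono :class:`AudioClip`."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:  # average channels
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioClip(samples=data.astype(float), rate=float(rate), clip_id=clip_id)


def n_frames(n_samples: int, rate: float, frame_ms: float = FRAME_MS,
             hop_ms: float = HOP_MS) -> int:
    """Number of fully contained analysis frames: floor((N - L)/h) + 1."""
    frame = int(round(frame_ms * rate / 1000.0))
    hop = int(round(hop_ms * rate / 1000.0))
    if n_samples < frame:
        raise ValueError("audio shorter than one analysis frame")
    return (n_samples - frame) // hop + 1


def build_filterbank(n_channels: int = N_CHANNELS, f_lo: float = F_LO,
                     spacing_octaves: float = SPACING_OCTAVES,
                     rate: float = 48828.125,
                     n_fft: int | None = None) -> FilterBank:
    """Build the triangular filterbank on the one-sided FFT grid.

    Center frequencies follow ``f_lo * 2**(k * spacing_octaves)`` for
    ``k = 0..n_channels-1``; with the defaults (34 channels, 500 Hz, 1/6
    octave) the top channel sits at 22,627 Hz.  Each channel's triangle
    spans from the previous to the next center frequency; the edge channels
    use a mirrored neighbor spacing and are truncated at the grid edges.

    Parameters
    ----------
    rate, n_fft
        Audio sampling rate and FFT length (defaults to the 10 ms frame
        length in samples, no zero padding), which fix the FFT bin grid.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if f_lo <= 0:
        raise ValueError("f_lo must be positive")
    k = np.arange(n_channels)
    centers = f_lo * 2.0 ** (k * spacing_octaves)
    nyquist = rate / 2.0
    if centers[-1] >= nyquist:
        raise ValueError(
            f"top center frequency {centers[-1]:.0f} Hz is at or above the "
            f"Nyquist frequency {nyquist:.0f} Hz")
    if n_fft is None:
        n_fft = int(round(FRAME_MS * rate / 1000.0))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    # triangle corner frequencies: previous and next center, mirrored at edges
    ratio = 2.0 ** spacing_octaves
    lower = np.concatenate(([centers[0] / ratio], centers[:-1]))
    upper = np.concatenate((centers[1:], [centers[-1] * ratio]))
    weights = np.zeros((n_channels, fft_freqs.size))
    for ch in range(n_channels):
        lo, c, hi = lower[ch], centers[ch], upper[ch]
        rising = (fft_freqs - lo) / (c - lo)
        falling = (hi - fft_freqs) / (hi - c)
        tri = np.minimum(rising, falling)
        weights[ch] = np.clip(tri, 0.0, None)
    return FilterBank(center_freqs=centers, weights=weights, fft_freqs=fft_freqs)


def compute_cochleagram(audio: AudioClip, bank: FilterBank | None = None,
                        frame_ms: float = FRAME_MS, hop_ms: float = HOP_MS,
                        floor_db: float = FLOOR_DB,
                        floor: float | None = None) -> Cochleagram:
    """Hamming power spectrogram -> triangular pooling -> log -> floor.

    Frames are fully contained in the clip (no padding): a clip of ``N``
    samples yields ``floor((N - L)/h) + 1`` frames for frame length ``L``
    and hop ``h`` in samples (4.75 s at 10 ms / 5 ms -> 949 frames).

    ``floor`` fixes the log-power floor explicitly (log units); otherwise it
    is set ``floor_db`` dB below the clip's maximum log power.  When
    processing a multi-clip dataset use :func:`normalize_dataset`, which also
    re-floors consistently across clips.
    """
    if audio.samples.size == 0:
        raise ValueError("empty audio")
    rate = audio.rate
    frame = int(round(frame_ms * rate / 1000.0))
    hop = int(round(hop_ms * rate / 1000.0))
    if frame < hop:
        raise ValueError("frame length must be >= hop")
    T = n_frames(audio.samples.size, rate, frame_ms, hop_ms)
    if bank is None:
        bank = build_filterbank(rate=rate, n_fft=frame)
    win = hamming(frame, sym=False)
    idx = np.arange(frame)[None, :] + hop * np.arange(T)[:, None]
    frames = audio.samples[idx] * win
    power = np.abs(np.fft.rfft(frames, n=frame, axis=1)) ** 2
    chan_power = power @ bank.weights.T  # (T, F)
    with np.errstate(divide="ignore"):
        logpow = np.log(chan_power)
    if floor is None:
        finite = logpow[np.isfinite(logpow)]
        top = finite.max() if finite.size else 0.0
        # floor_db dB below the maximum power (log base e scale)
        floor = top - floor_db * np.log(10.0) / 10.0
    values = np.maximum(logpow, floor)
    return Cochleagram(values=values, frame_hop=hop_ms, frame_len=frame_ms,
                       channel_freqs=bank.center_freqs, floor=float(floor),
                       clip_id=audio.clip_id)


def normalize_dataset(cochleagrams, mean: float | None = None,
                      sd: float | None = None):
    """Standardize a set of cochleagrams to pooled zero mean / unit variance.

    When ``mean``/``sd`` are given (statistics from a training set), they are
    applied unchanged so held-out data share the training normalization.

    Returns ``(normalized list, mean, sd)``.
    """
    cochleagrams = list(cochleagrams)
    if mean is None or sd is None:
        pooled = np.concatenate([c.values.ravel() for c in cochleagrams])
        if pooled.size < 2 or np.ptp(pooled) == 0:
            raise ValueError("degenerate dataset: zero pooled variance")
        mean = float(pooled.mean())
        sd = float(pooled.std())
        if sd == 0:
            raise ValueError("degenerate dataset: zero pooled variance")
    out = []
    for c in cochleagrams:
        out.append(Cochleagram(values=(c.values - mean) / sd,
                               frame_hop=c.frame_hop, frame_len=c.frame_len,
                               channel_freqs=c.channel_freqs,
                               floor=(c.floor - mean) / sd, clip_id=c.clip_id))
    return out, mean, sd


def lag_stimulus(cochleagram: Cochleagram, H: int = H_DEFAULT) -> LaggedStimulus:
    """Stack each frame with its ``H - 1`` predecessors into ``F x H`` windows.

    Only bins with a full in-clip history are valid: frames ``H-1 .. T-1``
    (0-based), i.e. ``T - H + 1`` windows.  ``windows[i][:, tau]`` is
    cochleagram frame ``valid_bins[i] - tau``.
    """
    values = cochleagram.values
    T, F = values.shape
    if T < H:
        raise ValueError(f"clip has {T} frames, fewer than H={H}")
    if H < 1:
        raise ValueError("H must be >= 1")
    valid = np.arange(H - 1, T)
    windows = np.empty((valid.size, F, H))
    for tau in range(H):
        windows[:, :, tau] = values[valid - tau]
    return LaggedStimulus(windows=windows, H=H, valid_bins=valid)
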