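"""Train/validation/test protocol and hyperparameter search.

The dataset is split once: the last ``test_fraction`` (20%) of every clip
is the held-out test set, and the remaining cross-validation (CV) portion
is divided into k folds (k = 10 at the full scale of 20 clips) whose
validation sets are the CV portion of whole clips (2 per fold).  For each
penalty strength on a log-spaced grid, the model is fitted on each fold's
training bins and scored by validation CC_norm; the lambda maximizing the
fold-mean wins (ties toward stronger regularization).  The final model is
refitted on the full CV set and evaluated once on the untouched test set.

A fit-consistency check compares the effective-HU STRFs recovered across
fold fits (greedy best / second-best matched correlations), with a
within-STRF permutation control that destroys spectrotemporal structure
while preserving the weight distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import ln_model, nrf_model
from .metrics import MetricReport, cc_half, cc_max, cc_raw, evaluate_model
from .nrf_model import NRFHyper, NRFParams
from .responses import PSTH, TrialResponses, rescale_targets, unrescale_targets
from .rf_analysis import adjust_network, display_strf, effective_hus

__all__ = [
    "EncodingDataset",
    "SplitSpec",
    "CVResult",
    "ConsistencyReport",
    "build_encoding_dataset",
    "make_splits",
    "default_lambda_grid",
    "select_lambda",
    "refit_full",
    "fit_consistency",
]


@dataclass
class EncodingDataset:
    """Aligned model inputs for one neuron.

    ``X[c]`` has shape (T_c, F, H): the lagged stimulus window for each
    retained response bin of clip ``c``.  ``y[c]`` is the spike-count PSTH
    over the same bins, and ``trials[c]`` (optional, shape (R, T_c)) holds
    the per-trial binned counts over those bins for reliability estimates.
    """

    X: list
    y: list
    trials: list | None = None
    clip_ids: list | None = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have one entry per clip")
        for x, yy in zip(self.X, self.y):
            if x.shape[0] != len(yy):
                raise ValueError("per-clip stimulus/response length mismatch")
        if self.clip_ids is None:
            self.clip_ids = list(range(len(self.X)))

    @property
    def n_clips(self) -> int:
        return len(self.X)

    @property
    def shape(self):
        return self.X[0].shape[1:]


def build_encoding_dataset(cochleagrams, psth: PSTH, H: int = 20,
                           trials: TrialResponses | None = None,
                           frame_ms: float = 10.0) -> EncodingDataset:
    """Align normalized cochleagrams with a PSTH into an EncodingDataset.

    PSTH bins (onset discard applied, tail trimmed to the frame grid)
    correspond to cochleagram frames ``d .. T-1`` with
    ``d = discard_ms / bin_ms``; the onset discard must cover the stimulus
    history (``d >= H - 1``) so every retained bin has a full in-clip
    history and no padding is ever needed.
    """
    from .cochleagram import lag_stimulus

    d = int(round(psth.onset_discard_ms / psth.bin_ms))
    if d < H - 1:
        raise ValueError(
            f"onset discard ({d} bins) shorter than stimulus history "
            f"H-1={H - 1}; discard at least {(H - 1) * psth.bin_ms:.0f} ms")
    X, tr = [], [] if trials is not None else None
    tail = max(int(round(frame_ms / psth.bin_ms)) - 1, 0)
    for c, (coch, y) in enumerate(zip(cochleagrams, psth.y)):
        lagged = lag_stimulus(coch, H)
        start = d - (H - 1)
        win = lagged.windows[start:start + len(y)]
        if win.shape[0] != len(y):
            raise ValueError("cochleagram shorter than the PSTH it should "
                             "explain")
        X.append(win)
        if trials is not None:
            stop = trials.counts[c].shape[1] - tail
            tr.append(trials.counts[c][:, d:stop])
    return EncodingDataset(X=X, y=[np.asarray(v, dtype=float) for v in psth.y],
                           trials=tr, clip_ids=psth.clip_ids)


@dataclass
class SplitSpec:
    """Per-clip test tails plus whole-clip validation folds of the CV set."""

    clip_lengths: np.ndarray
    cv_stop: np.ndarray          # per clip: CV portion is bins [0, cv_stop)
    folds: list                  # list of arrays of validation clip indices
    test_fraction: float

    @property
    def k(self) -> int:
        return len(self.folds)

    def test_slice(self, clip: int) -> slice:
        return slice(int(self.cv_stop[clip]), int(self.clip_lengths[clip]))

    def cv_slice(self, clip: int) -> slice:
        return slice(0, int(self.cv_stop[clip]))


@dataclass
class CVResult:
    lambda_grid: np.ndarray
    scores: np.ndarray        # (k, n_lambda) validation CC_norm
    best_lambda: float
    mean_scores: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mean_scores is None:
            self.mean_scores = np.nanmean(self.scores, axis=0)


@dataclass
class ConsistencyReport:
    best_corrs: np.ndarray    # per ordered fit pair
    second_corrs: np.ndarray  # nan where a fit has < 2 effective HUs
    mean_best: float
    mean_second: float


def make_splits(clip_ids, clip_lengths, k: int = 10,
                test_fraction: float = 0.2, seed: int = 0) -> SplitSpec:
    """Reserve per-clip test tails and form k whole-clip validation folds.

    The clip set must divide evenly into k folds (20 clips, k = 10 gives
    folds of 2 clips); clips are assigned to folds by a seeded permutation,
    so the folds are disjoint and jointly cover all clips.
    """
    clip_lengths = np.asarray(clip_lengths, dtype=int)
    n = len(clip_lengths)
    if n % k:
        raise ValueError(
            f"{n} clips cannot form {k} equal folds; choose k dividing {n} "
            f"(e.g. k={max(d for d in range(1, n + 1) if n % d == 0 and d <= k)})")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    cv_stop = clip_lengths - np.round(clip_lengths * test_fraction).astype(int)
    perm = np.random.default_rng(seed).permutation(n)
    per = n // k
    folds = [np.sort(perm[i * per:(i + 1) * per]) for i in range(k)]
    return SplitSpec(clip_lengths=clip_lengths, cv_stop=cv_stop, folds=folds,
                     test_fraction=test_fraction)


def _gather(data: EncodingDataset, clips, sl_fn):
    X = np.concatenate([np.asarray(data.X[c])[sl_fn(c)] for c in clips])
    y = np.concatenate([np.asarray(data.y[c])[sl_fn(c)] for c in clips])
    trials = None
    if data.trials is not None:
        trials = [np.asarray(data.trials[c])[:, sl_fn(c)] for c in clips]
    return X, y, trials


def _fit_model(kind: str, X, y, lam: float, hyper: NRFHyper | None):
    kind = kind.upper()
    if kind == "L":
        return ln_model.fit_linear_lasso(X, y, lam)
    if kind == "LN":
        strf = ln_model.fit_linear_lasso(X, y, lam)
        sig = ln_model.fit_output_sigmoid(ln_model.predict_linear(strf, X), y)
        return (strf, sig)
    if kind == "NRF":
        hyper = hyper or NRFHyper()
        hyper = NRFHyper(**{**hyper.__dict__, "lam": lam})
        return nrf_model.train(X, rescale_targets(y), hyper)
    raise ValueError(f"unknown model kind {kind!r}")


def _predict_model(kind: str, model, X) -> np.ndarray:
    kind = kind.upper()
    if kind == "L":
        return ln_model.predict_linear(model, X)
    if kind == "LN":
        return ln_model.predict_ln(model[0], model[1], X)
    if kind == "NRF":
        return unrescale_targets(nrf_model.forward(model, X).y_hat)
    raise ValueError(f"unknown model kind {kind!r}")


def default_lambda_grid(X, y, n: int = 20, span: float = 1e-4) -> np.ndarray:
    """Log-spaced penalties from the linear problem's full-shrinkage point.

    The largest value is the smallest lambda that zeroes every weight of
    the linear stage; the smallest is ``span`` times that.
    """
    top = ln_model.lambda_max_linear(X, y)
    return np.geomspace(span * top, top, n)


def default_nrf_lambda(X, y_rescaled, fraction: float = 1e-3) -> float:
    """Default network penalty when no cross-validated search is run.

    Set to a fixed fraction (1e-3) of the linear-stage full-shrinkage
    penalty: strong enough that hidden units redundant with the signal
    carry a real cost and shrink away, three decades below the point where
    the model collapses entirely.
    """
    return fraction * ln_model.lambda_max_linear(X, y_rescaled)


def select_lambda(model_kind: str, data: EncodingDataset, splits: SplitSpec,
                  grid, hyper: NRFHyper | None = None, seed: int = 0,
                  n_half_splits: int = 126) -> CVResult:
    """k-fold validation search over the penalty grid.

    For each fold, the model is fitted on the CV portion of the non-
    validation clips and scored by CC_norm on the CV portion of the
    validation clips (CC_max from the validation trials when available; the
    LN model is scored on its full prediction, with the sigmoid refitted
    inside every fold).  The best lambda maximizes the fold-mean score;
    exact ties break toward the larger lambda.  Grid ordering is
    irrelevant; a lambda where every fold fails scores -inf.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    all_clips = np.arange(data.n_clips)
    scores = np.full((splits.k, grid.size), np.nan)
    for f, val_clips in enumerate(splits.folds):
        train_clips = np.setdiff1d(all_clips, val_clips)
        Xtr, ytr, _ = _gather(data, train_clips, splits.cv_slice)
        Xva, yva, trva = _gather(data, val_clips, splits.cv_slice)
        half = None
        if trva is not None:
            half = cc_half(trva, n_splits=n_half_splits, seed=seed)
        for i, lam in enumerate(grid):
            try:
                model = _fit_model(model_kind, Xtr, ytr, lam, hyper)
                pred = _predict_model(model_kind, model, Xva)
                raw = cc_raw(yva, pred)
                scores[f, i] = raw / cc_max(half) if half is not None else raw
            except (ValueError, FloatingPointError) as exc:
                warnings.warn(f"fold {f}, lambda {lam:g}: fit failed ({exc})")
                scores[f, i] = -np.inf
    mean = np.nanmean(scores, axis=0)
    # argmax with ties toward larger lambda (grid is ascending)
    best = grid[grid.size - 1 - int(np.argmax(mean[::-1]))]
    return CVResult(lambda_grid=grid, scores=scores, best_lambda=float(best))


def refit_full(model_kind: str, data: EncodingDataset, splits: SplitSpec,
               best_lambda: float, hyper: NRFHyper | None = None,
               seed: int = 0, n_half_splits: int = 126):
    """Refit on the entire CV set; report metrics on the untouched test set.

    Returns ``(model, MetricReport)``.  Training data and test data are
    disjoint by construction (CV portion vs per-clip tails).
    """
    all_clips = np.arange(data.n_clips)
    Xcv, ycv, _ = _gather(data, all_clips, splits.cv_slice)
    model = _fit_model(model_kind, Xcv, ycv, best_lambda, hyper)
    Xte, yte, trte = _gather(data, all_clips, splits.test_slice)
    pred = _predict_model(model_kind, model, Xte)
    report = evaluate_model(yte, pred, trials=trte, seed=seed,
                            n_splits=n_half_splits)
    return model, report


def _effective_display_strfs(params: NRFParams, X):
    adj = adjust_network(params).params
    out = []
    for p in effective_hus(params, X):
        if p.effective:
            out.append(display_strf(adj.w_in[p.index], p.kind).ravel())
    return out


def _pair_corrs(strfs_a, strfs_b):
    """Greedy best and second-best matched correlations between two fits."""
    C = np.array([[np.corrcoef(a, b)[0, 1] for b in strfs_b]
                  for a in strfs_a])
    best = float(C.max())
    second = np.nan
    if min(C.shape) >= 2:
        i, j = np.unravel_index(np.argmax(C), C.shape)
        C2 = np.delete(np.delete(C, i, axis=0), j, axis=1)
        second = float(C2.max())
    return best, second


def fit_consistency(fold_params, X, seed: int = 0, n_shuffles: int = 0):
    """Cross-fit agreement of effective-HU STRFs.

    For every ordered pair of fits, the best-matched correlation is the
    highest Pearson correlation between any effective-HU display STRF of
    one fit and any of the other; the second-best is the maximum after
    removing that pair (greedy).  Fits without effective HUs are excluded
    with a warning.  With ``n_shuffles > 0`` a permutation control is also
    returned: weights are shuffled within every effective-HU STRF, which
    should drive the matched correlations to ~0 for structureless nulls.

    Returns ``report`` or ``(report, control_report)``.
    """
    strf_sets = []
    for i, p in enumerate(fold_params):
        s = _effective_display_strfs(p, X)
        if not s:
            warnings.warn(f"fit {i} has no effective HUs; excluded")
        else:
            strf_sets.append(s)
    if len(strf_sets) < 2:
        raise ValueError("need at least 2 fits with effective HUs")

    def report_for(sets):
        best, second = [], []
        for i in range(len(sets)):
            for j in range(len(sets)):
                if i == j:
                    continue
                b, s = _pair_corrs(sets[i], sets[j])
                best.append(b)
                second.append(s)
        best = np.asarray(best)
        second = np.asarray(second)
        return ConsistencyReport(
            best_corrs=best, second_corrs=second,
            mean_best=float(np.mean(best)),
            mean_second=float(np.nanmean(second)) if np.any(
                np.isfinite(second)) else float("nan"))

    report = report_for(strf_sets)
    if n_shuffles <= 0:
        return report
    rng = np.random.default_rng(seed)
    bests, seconds = [], []
    for _ in range(n_shuffles):
        shuffled = [[rng.permutation(s) for s in fit] for fit in strf_sets]
        r = report_for(shuffled)
        bests.append(r.mean_best)
        seconds.append(r.mean_second)
    control = ConsistencyReport(
        best_corrs=np.asarray(bests), second_corrs=np.asarray(seconds),
        mean_best=float(np.mean(bests)),
        mean_second=float(np.nanmean(seconds)))
    return report, control
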