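# Methods

This note records the modeling conventions, numerical choices and known
limitations of `nrfkit`, in the spirit of a methods appendix.

## Preprocessing

**Cochleagram.** Audio is framed with 10 ms Hamming windows hopped by 5 ms
(frames fully contained in the clip, so an *N*-sample clip yields
⌊(*N* − *L*)/*h*⌋ + 1 frames). One-sided FFT power (FFT length = frame
length, no zero padding) is pooled by triangular windows onto channels with
geometric center frequencies `f_lo · 2^(k·spacing)`; with the defaults (34
channels from 500 Hz at 1/6 octave) the top channel is 22,627 Hz. Each
triangle spans from the previous to the next center frequency; edge
channels mirror the neighbor spacing and are truncated at the FFT grid.
The log of the channel power is clipped at a floor 60 dB below the maximum
(configurable; the dynamic-range clamp is a convention, not a fitted
quantity). The whole stimulus ensemble is then standardized to zero mean
and unit variance, and the training-set statistics are reused verbatim on
held-out data.

**Alignment.** Model inputs are F × H lagged snippets (H = 20 bins =
100 ms of history). The response is binned at 5 ms, trial-averaged,
smoothed, and trimmed so that bins correspond 1:1 with spectrogram frames
(a 5 s clip has 999 frames, not 1000 bins). The onset discard (250 ms at
full scale) must cover the stimulus history (≥ (H−1)·5 ms), so every
modeled bin has a full in-clip history and no padding is ever used: a
4.75 s effective clip yields exactly 949 modeled bins.

**PSTH.** Smoothing uses a unit-sum Hanning kernel whose width is the
nearest odd bin count to 21 ms (5 bins at 5 ms), applied after trial
averaging and before the onset discard.

**Noise ratio.** The screening statistic uses the signal/noise power
decomposition: with R trials, V_mean the variance over time of the
trial-averaged response and V_trial the mean per-trial variance,

    SP = (R·V_mean − V_trial)/(R − 1),   NP = V_trial − SP,
    NR = NP / (R·SP).

NR is the residual noise power in the trial average relative to the signal
power: 0 for identical trials, +∞ (flagged) when SP ≤ 0, and neurons with
NR > 40 are excluded. This convention is pinned by simulation (signal
variance 1, per-trial noise variance 10, R = 20 gives NR ≈ 0.5) and by its
invariances (constant offsets leave NR unchanged; scaling the noise by k
scales NR by k²). The exact formula used in the original screening
literature is not restated there; this implementation is declared, not
claimed identical.

**Target rescaling.** Network training targets are y′ = σ₁(2y − 1) with
σ₁ = 1/tanh(2/3) ≈ 1.7159, mapping spike count 0 → −σ₁ and 1 → +σ₁ onto
the symmetric range of the tanh activation. All metrics are computed on
the un-rescaled count scale; the map is exactly invertible.

## Models

**LN.** The linear stage minimizes ‖y − Xw − b‖² + λ‖w‖₁ (bias
unpenalized), solved by coordinate descent (scikit-learn's LASSO with
α = λ/(2n), Gram precomputation, tolerance 1e−7); λ = 0 falls back to
least squares. The output stage fits
ŷ = ρ₁/(1 + e^{−(a−ρ₃)/ρ₂}) + ρ₄ by L-BFGS-B from multiple starts
(ρ₁ = range(y), ρ₄ = min(y), ρ₃ = median(a), ρ₂ ∈ {±sd(a), ±sd(a)/4});
the returned fit never has a higher error than the best start, and
increasing-slope starts are tried first so tied fits take the canonical
ρ₂ > 0 form. Constant targets are a degenerate-input error.

**NRF.** J = 20 hidden units by default (desk-scale fits in the tests use
J = 10; performance is insensitive to J well above the number of true
features). The activation constants ρ₁ = 1/tanh(2/3), ρ₂ = 3/2 are fixed
so g(±1) = ±1. Initialization draws every weight and bias uniformly from
±1/M, with M the number of incoming weights and biases of the receiving
unit (hidden: F·H + 1; output: J + 1), from a single seeded generator.

The penalized objective (biases unpenalized, per its definition) is
optimized by splitting every weight into positive and negative parts
(w = u − v, u, v ≥ 0, penalty λ·Σ(u+v)) and running bound-constrained
L-BFGS-B on the resulting smooth problem. The bound constraint drives
redundant weights exactly to zero — the same sparsity a proximal
soft-thresholding step would produce — while retaining quasi-Newton
convergence rates; sub-tolerance magnitudes (<1e−8) are snapped to zero
and reported as pruned. The solver runs up to 40 outer iterations of 25
L-BFGS-B steps, declaring convergence when the relative objective change
per outer iteration falls below 1e−6; the best iterate is returned, so the
objective trace is non-increasing and never exceeds its initial value.
Training is deterministic given the seed. A non-finite objective raises a
training error rather than returning garbage.

**Default penalty.** When no cross-validated search is run, λ defaults to
1e−3 × the linear-stage full-shrinkage penalty (the smallest λ that zeroes
every weight of the linear problem): strong enough that hidden units
redundant with the signal carry a real cost and shrink away, three decades
below total collapse. The cross-validated grid spans 1e−4 × to 1 × the
full-shrinkage penalty, 20 log-spaced values by default.

## Protocol

The last 20% of every clip is the test set; the remaining cross-validation
set is split into k folds whose validation sets are the CV portion of
whole clips (k = 10 folds of 2 clips at the 20-clip scale; the clip count
must divide evenly, otherwise an error suggests a feasible k). λ maximizes
the unweighted fold-mean validation CC_norm, with exact ties broken toward
the larger λ; grid ordering is irrelevant. The LN model is selected on its
full (sigmoid-composed) validation prediction, with the sigmoid refitted
inside every fold — selecting on the linear stage alone is possible but
not the default. The final model is refitted on the entire CV set and
evaluated once on the untouched test tails. Effective-HU variances and
activation centiles are computed on the CV stimulus set by default (the
full set including test is a configurable alternative; the conservative
choice avoids any test-conditioned statistic leaking into reported
structure).

Fit consistency across folds is summarized by greedy best and second-best
matched correlations between effective-HU display STRFs of fit pairs, with
a within-STRF permutation control (weights shuffled inside each STRF
matrix) that should drive the matched correlations toward zero.

## Metrics

CC_raw is the Pearson correlation of prediction and PSTH. CC_half averages
the correlation between smoothed half-mean PSTHs over 126 random disjoint
half-partitions of the trials (seeded; each half goes through the same
smoothing pipeline as the full PSTH). The ceiling is

    CC_max = √( 2 / (1 + 1/CC_half) ),

the Spearman–Brown-consistent form: it is the unique monotone form with
CC_max(1) = 1 and CC_max ≈ √(2·CC_half) as CC_half → 0, matching the
split-half semantics (each half contains R/2 of the trials, hence twice
the noise of the full average). Non-positive CC_half leaves the ceiling
undefined; the neuron is flagged rather than imputed. pMSE is the mean
squared error restricted to bins where the observed PSTH is at or above
its per-clip mean + 2 SD; a flat clip (SD = 0) contributes no peak bins,
and a neuron with no peak bins anywhere has pMSE undefined.

## Network interpretation

The adjusted network flips the (w_jfτ, b_j, w_j) triplet of every HU whose
STRF weight-sum is negative — a symmetry of the odd activation, so
predictions are preserved to machine precision — after which sign(w_j)
alone classifies HUs as excitatory or inhibitory. The equivalent
non-negative-output description shifts HU outputs by +ρ₁ and the OU bias
by −ρ₁·Σ_j w_j. Effective HUs are those whose weighted-output variance is
at least 5% of the summed variance over all J HUs. IE =
sign(w_j)·Σw_jfτ/Σ|w_jfτ| ∈ [−1, 1]; EC = (ρ₆/ρ₁)(⟨output⟩ − ρ₄) − ρ₅,
anchored at −1 (threshold) and +1 (saturation), with (ρ₄, ρ₅, ρ₆) =
(0, 0, 1) for network units and (fitted ρ₄, 1, 2) for the LN output. Both
scores are computed on the adjusted network and are therefore invariant to
the sign-flip symmetry.

Display STRFs negate inhibitory HUs so plots show the direction of effect
on the output. Tuning widths interpolate the display STRF onto an 8× grid
(cubic spline, no smoothing, 7 inserted values per gap; interpolated bins
are 1/48 octave × 5/8 ms), square it (the power STRF), take marginal sums,
and count bins at or above the height fraction (ties included, per the
"≥ 25% / ≥ 50%" rule) times the interpolated bin size. NRF power STRFs sum
the per-HU power STRFs of the effective HUs weighted by their
weighted-output variances. Contours are the half-maximum (excitatory) or
half-minimum (inhibitory) level sets of the interpolated display STRF.

**Gain analysis** (bi-feature fits: exactly one effective excitatory and
one effective inhibitory HU): the OU rate is swept against excitatory
activation at 7 inhibitory activation levels evenly spanning the observed
inhibitory range. The sweep covers the full operating range of the
excitatory HU — from threshold to saturation of the tanh, beyond the
1st/99th activation centiles that define the normalized axis. Gain is the
steepest slope of each 201-point curve (central differences), normalized
to 1 at the lowest inhibitory level. Substituting an identity output unit
makes the inhibitory term additive, so the gain becomes exactly
level-independent — the control that shows the effect requires the output
nonlinearity.

**Conjunction analysis** (≥ 2 effective excitatory HUs): reduced models
clamp every other effective excitatory HU's output at its minimum −ρ₁
("below threshold" in the non-negative description); inhibitory and
ineffective HUs are untouched. The summed reduced predictions and the full
prediction are compared, in count units, against the observed PSTH's
per-clip 2σ thresholds (thresholds are taken from the observed response
once, not recomputed per reduced model). The peak time ratio
(summed-reduced peak bins / full-model peak bins) is below 1 when
supra-threshold responses require feature conjunctions; it is undefined
(flagged) if the full model never crosses threshold.

## Synthetic ground truth

The generator emulates the structure of the target recordings: 20 clips of
4.75 s effective duration, 34-channel cochleagram at 5 ms, 20 trials, at
full scale. Routine tests use a desk-scale preset — 6 clips × 2 s, 18
channels, H = 20, 20 trials, 150 ms onset discard — chosen as the smallest
configuration that preserves every structural property (full history
coverage, whole-clip folds, split-half reliability estimation) while
keeping a complete fit under a few seconds.

Ground-truth networks place Gabor-shaped STRFs (unit L2 norm, scaled by a
hidden gain of 1.3–1.6 so activations reach the nonlinear range on
standardized stimuli) at non-overlapping spectrotemporal centers.
Excitation/inhibition is set through the output weights; the negative
output bias puts the OU near threshold, giving sparse, peaked rates —
presets cover bi-feature (1E+1I), conjunctive (2E with a strongly
expansive OU, so the rate rises appreciably only when both features
coincide), linear (one sub-field in the quasi-linear regime throughout)
and multi-feature (3E+1I) designs. Stimuli are either tone-cloud audio run
through the real cochleagram front-end or spectrotemporally correlated
Gaussian fields drawn directly in cochleagram space (correlation lengths 2
frames × 1.5 channels). Trials add truncated Gaussian noise to the rate
(sd 0.05–0.08 counts/bin, matching the squared-error fitting assumption
and giving split-half reliability > 0.95); a Poisson mode provides
count-like realism.

What the generator does *not* emulate: natural-sound higher-order
statistics, spike-sorting artifacts, non-stationarity across trials, or
any response property outside the NRF model class itself. Passing the
recovery tests therefore shows that the estimator is correct and
well-conditioned under its own assumptions — not that cortical neurons
satisfy them.

## Known limitations

- The optimizer is a batch quasi-Newton substitute for the
  sum-of-functions optimizer used in the original fitting work; it reaches
  equivalent desk-scale solutions but its iteration counts are not
  comparable.
- λ selection under very low noise favors under-regularized models (extra
  above-threshold HUs cost nothing in validation CC_norm); the default
  penalty exists for exactly this regime.
- The cochleagram is a log-power filterbank, not an auditory-nerve model:
  no adaptation, compression dynamics, or phase locking.
- CC_half requires an even trial count; odd counts are an input error
  rather than silently dropping a trial.
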