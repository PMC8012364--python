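# Methods

This note documents the models, parameter choices and numerical decisions
behind `fiberbehav`, and what the synthetic-data generator does and does
not emulate.

## Synthetic session events

Trials are generated sequentially and never overlap. Each trial draws its
delay uniformly from {5, 7.5, 12.5} s and its outcome from a (optionally
delay-conditional) categorical distribution over {correct, incorrect,
omission, premature}. Default outcome probabilities (0.60 / 0.10 / 0.12 /
0.18) give session-level rates typical of a trained rat on a variable-delay
challenge session. Correct/incorrect response latencies are a truncated
exponential (mean ≈ 0.65 s) inside the cue + 2 s limited-hold window;
premature responses use a Beta(2, 1.2) fraction of the delay, i.e. a hazard
that rises through the delay; magazine latencies are lognormal with a
median near 1.5 s (occasionally exceeding the 10 s exclusion cutoff, which
exercises the exclusion path). The inter-trial interval is 10 s plus
jitter so the −5…−1 s pre-trial baseline is free of trial-evoked signal by
construction. All times are seconds from session start; windows are
half-open `[start, end)`. Each generator op owns one `numpy` Generator
seeded from its config.

## Synthetic photometry

The two channels are built as

    F405(t) = B405 · bleach(t) · motion(t) + ε(t)
    F470(t) = B470 · bleach(t) · motion(t) · (1 + c(t)) + ε(t)

with `bleach(t) = exp(−t/τ_b)` (τ_b = 3000 s), `motion(t)` a bank of five
slow sinusoids (0.05–2 Hz, ±2 %) shared across channels up to a gain, and
white measurement noise (SD 0.003 a.u.). Motion is multiplicative and
shared because that is precisely the artifact class the isosbestic
regression-and-divide correction removes. The calcium component `c(t)` is,
per trial, a saturating exponential rise (τ_rise = 0.3 s, onset latency
0.2 s) toward a plateau of amplitude 5 % δF/F spanning the delay, decaying
with τ_decay = 0.8 s once the delay ends; premature responses truncate the
plateau at the response time and omissions attenuate the amplitude by 0.8.
On top of the trial-locked component an Ornstein–Uhlenbeck process
(SD 1 % δF/F, τ = 0.3 s) models spontaneous population fluctuations; this
is what sets a realistic baseline SD, so that injected plateaus come out
at peak z values of roughly 5–15 rather than the physically meaningless
hundreds a noise-free baseline would produce. The raw rate defaults to
1017.25 Hz so that decimation by 64 gives the ≈16 Hz analysis frame rate.

Not emulated: hemodynamic contamination, wavelength-dependent bleaching
(each channel shares one bleach curve), spike-to-fluorescence kinetics,
and sensor nonlinearity. Passing tests therefore demonstrate correctness
of the analysis given the shared-multiplicative-artifact model, not
robustness to channel-specific artifacts.

## Photometry preprocessing

δF/F is defined as `(F470 − fit)/fit` with `fit = a·F405 + b` from an
ordinary least-squares fit over the whole session (a Huber robust option
exists). The subtractive form (rather than plain division) maps a null
signal to 0, which matches the z-scored baselines used downstream. The
smoothing filter is a zero-phase (forward–backward) Butterworth lowpass at
1 Hz — zero-phase so that time-to-event metrics are not biased by filter
delay. Residual slow drift is removed spectrally: DFT bins at or below
0.005 Hz are zeroed. A low-order recursive highpass at 0.005 Hz would
attenuate the drift band by only ~6 dB at the corner; the spectral
brick-wall achieves the ≥20 dB rejection the pipeline promises while
leaving the 0.05–0.5 Hz signal band untouched (<1 dB). The cost is that a
high-duty-cycle transient train loses its near-DC component, shifting the
global offset; all downstream quantities are referenced to the per-trial
baseline, so this is immaterial (and the tests measure transient retention
baseline-referenced for the same reason). Decimation applies a zero-phase
Butterworth anti-alias filter at 0.8× the new Nyquist before stride
selection; factor 1 is the exact identity.

One frame corresponds to 1/fs ≈ 62.9 ms at the 15.89 Hz analysis rate.
(Equipment descriptions sometimes quote ≈125 ms per frame, i.e. ≈8 Hz;
this package treats frame duration strictly as 1/fs.)

## Epoching and z-scoring

The alignment frame is the first recorded frame at or after the event time
(no interpolation); windows are half-open in frame index. Trials whose
full window (including baseline) does not fit in the recording are dropped
and counted. Baseline SD uses ddof = 1, because the −5…−1 s baseline at
16 Hz holds only ~64 frames; trials with zero baseline SD are excluded
with a warning, never silently zeroed.

## Delay metrics

All metrics operate on z-scored, trial-start-aligned epochs restricted to
`[0, delay)` per trial, with an optional fixed horizon (e.g. 12.5 s, the
longest delay) for cross-delay comparisons. Crossings are reported at
frame resolution. "Time to peak" takes the first local maximum strictly
greater than both neighbors (plateaus resolve to their earliest frame)
whose value exceeds 20 % of the within-trial delay-window maximum; the
per-trial reading of "overall peak" is the default, with a per-animal
mean-trace mode available, since either reading is defensible. Undefined
metrics (no crossing, non-positive peak) propagate as NaN and are excluded
from per-animal means.

## Resampling statistics

The bootstrap resamples subjects (per-subject outcome-mean traces) with
replacement, 5000 iterations, and takes per-frame percentile bounds at
two-sided α = 0.001; frames are "elevated" when the lower bound exceeds
z = 0 (the one-directional readout is appropriate because traces are
z-scored to a zero baseline). An alternative construction — bootstrap each
subject's trials, then average the per-subject bounds — is provided as
`bootstrap_mean_ci_trialwise` for comparison; subject-level resampling is
the default. The percentile bootstrap is anti-conservative at n = 6
subjects: its effective multiplier is z₀.₉₇₅·√((n−1)/n) against a t₅
reference, giving ~87 % true coverage at nominal 95 %, and the test suite
asserts exactly that rather than nominal coverage.

Permutation tests compare per-frame group-mean differences under label
reshuffling (unpaired) or within-subject label swaps (paired; used for
outcome comparisons, where each subject contributes both traces). The
Monte-Carlo p uses the +1 correction so p is never zero, and tie
comparisons carry a 10⁻⁹ relative tolerance so the identity permutation
counts as an exceedance regardless of floating-point summation order
(this is what makes p-values exactly invariant to affine transforms of
the data). With 6-vs-6 subjects the permutation group has only
C(12,6) = 924 splits whose mirror pairs tie in |T|, so achievable
two-sided p-values are multiples of 1/462 and the exact size of the test
at α = 0.01 is 4/462 ≈ 0.0087 — slightly conservative, as permutation
tests at discrete levels must be. The calibration tests center on this
enumeration-derived level.

Singleton filtering removes runs of significant frames shorter than two
frames; surviving runs are reported as half-open `(start_s, end_s)`
windows. Benjamini–Hochberg FDR is exposed as `bh_fdr` (statsmodels
`fdr_bh` behind the package surface).

## Electrophysiology

Hyperpolarizing sweeps follow the RC closed form
`V(t) = V_rest + I·R·(1 − e^(−t/τ))`, with an alpha-shaped sag component
(peak resistance `sag_r_mohm`, τ_sag = 50 ms) when enabled. Depolarizing
and ramp sweeps spike through a leaky integrate-and-fire rule; the default
"instantaneous" mode fires when the steady-state voltage reaches
threshold, so the ramp rheobase equals the analytic (V_th − V_rest)/R,
while the "dynamic" mode integrates the membrane equation and documents
the ~ramp-rate·τ lag of ramp-based rheobase estimates.

Feature conventions: the I–V regression keeps a free intercept (baseline
offsets tolerated); the exponential-fit R² gate (>0.8) is computed on the
fitted 300 ms window only; capacitance is computed as C = τ/R — the only
unit-consistent reading of "input resistance over membrane time constant",
whose literal wording is dimensionally inverted (C_pF = 1000·τ_ms/R_MΩ);
sag uses the magnitude convention sag % = 100·(|ΔV_peak| − |ΔV_ss|)/|ΔV_peak|
so values fall in [0, 100) for physiological traces; PSC polarity is
auto-detected from the median trace (inward currents negative at −60 mV
holding) and the per-pulse peak-search window is `(onset, onset + 90 ms]`
(not fixed by convention; configurable). The PSC-train generator can drive
per-pulse amplitudes with a Tsodyks–Markram recursion
(uₖ₊₁ = U + uₖ(1−U)e^(−Δt/τ_f), Rₖ₊₁ = 1 − (1 − Rₖ(1−uₖ))e^(−Δt/τ_d),
amplitude ∝ uₖRₖ), which provides the analytic oracle for the
paired-pulse-ratio tests.

## Behavior

The magazine-latency exclusion (>10 s) removes the whole trial from every
denominator before any percentage is computed — matching "excluded from
further analysis" — with a latency-only mode behind a flag. Block
boundaries are half-open by trial start time (a trial at exactly 30:00
belongs to block 2). Variable-cue sessions reuse the same summarizer with
per-cue-duration grouping. For drug-vs-vehicle comparisons both a
percentage-point-difference helper and a ratio helper are provided; the
differencing convention is left to the caller.

## Problem sizes in tests and the acceptance script

The resampling checks use 200 replicates (bootstrap recovery: 6 subjects,
200 frames, 5000 iterations) and 500 replicates (permutation calibration:
6-vs-6, 200 frames, 5000 iterations); the enumeration-equivalence check
uses 5-vs-5 subjects (252 splits); noise-recovery checks use 100
replicates; null-threshold calibration uses 12 000 delay-window frames.
These sizes give Monte-Carlo standard errors comfortably below every
asserted tolerance while the whole suite runs in a couple of minutes.

## Known limitations

- The generator's artifact model is exactly the one the correction
  removes; real recordings contain channel-specific artifacts the
  isosbestic correction cannot cancel.
- Bootstrap and permutation inferences operate on subject-mean traces;
  trial-count imbalance across subjects is not propagated into the
  subject-level uncertainty.
- The spectral detrend assumes stationarity of the drift band over the
  session; abrupt baseline steps will ring.
- Ramp rheobase depends on ramp rate in dynamic mode; values are only
  comparable at a fixed ramp protocol.
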