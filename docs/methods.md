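# Methods

This note documents the models, numerical choices and limitations behind
`sniffalign`, in the order the pipeline runs.

## Sniff segmentation and flux

The intranasal pressure signal (arbitrary sensor units; inhalation negative)
is taken as proportional to the cross-section-averaged air velocity in the
nose.  Inhalation onsets are negative-going zero crossings of a
moving-average-smoothed copy of the trace (default 5 ms window; crossings
closer than 40 ms to the previous onset are treated as sensor noise).  The
inhalation offset is the later root of a parabola fitted to the raw pressure
around the first minimum after onset, in a window of ± 25% of the
onset-to-minimum interval (at least 5 samples) — a scale-free window, so the
fit behaves identically for 80 ms and 400 ms sniffs.  For a half-sine
inhalation lobe the parabola's root lies ~5% before the true zero return;
this small systematic bias cancels in all normalized quantities.  When the
parabola has no admissible root the first return of the smoothed pressure to
zero is used and the cycle flagged.

The inhalation flux is the trapezoidal cumulative integral of
`max(−P, 0)` on `[onset, t_inh]` on the native sampling grid (no
resampling; bit-stable and accurate to ~1e-6 relative at ≥ 10 kHz, ~1e-4 at
1 kHz).  Only inhalation-directed pressure enters, because odor cannot enter
the nose during exhalation.  The session constant `Q_norm` is the mean of
per-trial totals; because every use of flux is relative to `Q_norm`, the
unknown pressure-to-velocity proportionality cancels exactly (scaling all
traces by a common factor leaves every downstream quantity unchanged — a
tested invariant).

## Alignment models

All five transformations are strictly increasing piecewise-linear maps of
trial time and are represented by their knots, so forward maps, inverses and
Jacobians are exact.  The FD model's per-trial delay τ_f is the first time
the cumulative flux reaches λ·Q_norm, found by inverse interpolation of the
monotone cumulative integral; if a trial's total flux is below the target
the delay caps at t_inh and is flagged.  The whole spike train is shifted
rigidly by −(τ_f − ⟨τ_f⟩); spikes after the inhalation are shifted by the
same amount (the simplest reading of a rigid alignment), and transformed
times may be negative — PSTH supports extend to cover every training
trial's image, and spikes are never dropped.

Rates transform with the change-of-variables factor:
`f_i(t) = f̃(w(t))·w′(t)`.  Without the Jacobian, time-warping models would
systematically overpredict spike counts on long sniffs and the likelihood
comparison would penalize them for an accounting artifact rather than a
scientific one.  The factor is a config switch (`AlignmentSpec.jacobian`,
default on); expected-count conservation under all five maps is asserted to
1e-9 relative in the test suite.

Reference means (⟨dur⟩, ⟨t_inh⟩, ⟨τ_f⟩, Q_norm) are always computed on the
training fold only.

## Likelihood engine

PSTHs are histogram rates (total spikes / trials / bin width, in Hz) on
10 ms bins with optional Gaussian smoothing of σ = 5 ms (both configurable).
These defaults favor stable rate estimates at the 30–100 trials typical of
a cell-odor dataset; narrower bins sharpen temporal contrast at the cost of
variance (see Decoding below).  For scoring, the PSTH is interpolated
linearly between bin centers, floored at ε = 0.5 Hz (a nominal background
rate that prevents −∞ log-likelihoods in empty bins; configurable), and
pulled back onto each held-out sniff.  The Poisson log-likelihood uses rates
in Hz and times in ms with the integral converted to expected spikes;
results are reported in nats per sniff.  Both the spike-term and the
integral are computed exactly on the piecewise-linear representation (no
quadrature error), which is what makes the λ = 0 ≡ time-model identity hold
to 1e-12.

Cross-validation is seeded k-fold (default k = 5) over trials.  λ is
profiled over the grid 0…1 in steps of 0.05 (21 evaluations) with the same
fold assignment at every λ, and the optimum refined by a quadratic fit to
the profile within ± 0.25 of the grid argmax (a local window: the full
profile is typically asymmetric, and a global quadratic would bias the
vertex).  The fit is flagged unreliable when the quadratic opens upward or
when the best-vs-worst paired per-sniff difference is within twice its
standard error (a flat profile — e.g. data whose latency does not depend on
the waveform).  In the five-model comparison the FD model's λ is selected
per outer training fold by an inner 3-fold cross-validation, so its extra
parameter cannot inflate the held-out score.

## Response characterization

A cell-odor pair is classified by a two-sample KS test on pooled
within-sniff spike times, odor vs pre-odor background, at α = 0.05; the
excitatory/inhibitory label follows the sign of the first departure of the
stimulus mean cumulative spike-count curve from the background curve at 1 ms
resolution.  The pooled exact test is used rather than binning the times
first: quantization ties make the two-sample KS conservative and would break
the 5% type-I calibration.  Two caveats are documented as properties of this
design: (i) a pure rate scaling with an unchanged temporal profile is
invisible to the (normalized) KS statistic; (ii) the pooled distributions
inherit the sniff-duration mix of each sample, so comparing samples with
different duration *sets* inflates rejections slightly (6–8% at 100–200
trials in simulation) — calibration is exact when stimulus and background
share the duration distribution.

Fast/slow splits use a data-derived percentile boundary (lower tercile for
neural analyses, median for behavior); the boundary is always recomputed
from the data at hand, never hard-coded.  "Response latency" is the peak
latency of the background-subtracted group PSTH; the early-count window
defaults to the fast/slow boundary itself.  The latency shift (slow − fast)
is regressed on the fast-group latency by OLS with a 95% CI on the slope.

## Concentration decoding

The likelihood-ratio decoder holds one trial out per draw (leave-one-out:
including the drawn trial in its own class PSTH inflates success; a config
switch restores the no-holdout variant), rebuilds both concentration PSTHs
in the chosen alignment's coordinates, inverse-transforms each onto the held
sniff, and assigns the trial to the concentration with the higher Poisson
log-likelihood.  Draws alternate classes deterministically and rotate
through each class's trials in order — an equal-prior schedule that halves
the variance of the success estimate and makes the low/high label-swap
symmetry exact.  A consequence worth knowing: with N trials per class, 300
draws contain at most 2N distinct outcomes, so the success rate's sampling
variance is governed by the trial count, not the draw count; chance-level
calibration against the exact binomial band at n = 300 holds when each
trial is visited once (N = 150).

For the FD alignment, λ is fitted per concentration dataset by
cross-validation (concentration shifts the effective distance, so the two
classes earn separate values; a joint-λ mode exists).  Decoder PSTH
resolution is the package default (10 ms / σ 5 ms).  Sensitivity analysis on
synthetic data shows the FD-over-time success gap roughly doubles at
5 ms / σ 2.5 ms — fine temporal structure carries the concentration cue,
and coarse smoothing hides part of what alignment recovers — at the cost of
noisier per-pair success estimates; both knobs are exposed.

On data generated under the FD latency model with this package's default
effect sizes (below), the FD-aligned decoder beats the time-aligned one
consistently in direction, by ~2 percentage points on average over 30-pair
populations.  The magnitude depends directly on how strongly concentration
shifts latency versus amplitude in the generator; amplitude differences are
alignment-invariant, so generators (or recordings) whose concentration cue
is mostly amplitude show small alignment gains.

## Psychometrics

`ψ(c) = (1 − 2γ)·Φ((c − μ)/σ) + γ` with Φ the standard normal CDF (computed
via `scipy.special.ndtr`); the lapse γ is symmetric at both asymptotes and
box-constrained to [0, 0.25] for stability.  Fitting is Bernoulli maximum
likelihood (L-BFGS-B from three data-driven starts); σ at its lower bound
(step-like data) is flagged.  Deviance is twice the log-likelihood gap to
the saturated per-concentration model.  Bootstrap CIs resample trials with
replacement within concentration and refit (250 repetitions); more than 10%
failed refits flags the result.  The fast/slow comparison splits each
session at its median first-sniff duration, fits each half independently,
and tests the per-session parameter differences against zero across
sessions by Wilcoxon signed rank.

## Synthetic data

The generator defines the study conditions for every test:

* **Sniffs** — lognormal cycle durations, median 143 ms, log-sd 0.30
  (spanning roughly 75–440 ms over a long session, matching the observed
  range); inhalation fraction 0.45 ± 0.04 of the cycle; waveform = negative
  half-sine inhalation plus a volume-balancing positive exhalation lobe
  (chosen for closed-form flux integrals, which makes oracle tests exact);
  corr(log amplitude, log duration) = −0.5 (faster sniffs are deeper);
  additive Gaussian sensor noise, sd 2% of the median amplitude; 1 kHz
  sampling.
* **Spikes** — inhomogeneous Poisson by thinning: constant baseline 3 Hz
  plus a Gaussian kernel (σ = 15 ms, peak 60 Hz) centred at
  τ_f(λ_true) + τ_n with neural delay τ_n = 30 ms and a single λ_true per
  cell-odor pair.  τ_f is computed from the trial's noise-free waveform
  through the same flux machinery the analysis uses.  Concentration (log10
  units) moves λ by −0.10 per log (negative and modest, consistent with the
  observed small per-concentration shifts in effective distance) and the
  kernel peak by +20 Hz per log (anchored to the observed ~6 Hz amplitude
  difference per 2-fold concentration change).  A `latency_model='phase'`
  variant instead scales a fixed template with cycle duration
  (count-conserving) for phase-model recovery tests.
* **Behavior** — eight log-spaced concentrations across one order of
  magnitude, ~800 trials per session (~100 per concentration), choices
  Bernoulli from ψ, first-sniff durations from the sniff distribution, and
  no dependence of (μ, σ, γ) on sniff speed unless explicitly injected.

What the generator does *not* emulate: odor-front smearing by viscosity and
epithelial adsorption (represented only phenomenologically as the
concentration→λ and concentration→amplitude effects), receptor-level
transduction, spike-history dependence (the generator and the likelihood
are both Poisson — real spike trains have refractoriness the model ignores),
multi-unit correlations, and sequential behavioral strategies.  Passing
tests therefore demonstrate correctness of the estimators under the stated
generative assumptions, not performance on recorded data.

## Problem sizes

Tests and the acceptance script use 20 cell-odor pairs × 100 trials for λ
recovery, 20 pairs × 60 trials for model comparison, 30 concentration pairs
× 30 trials per concentration × 300 decoding draws, 500 replicates for
classifier calibration, and 20 replicates × 250 bootstrap refits for
psychometric coverage — population sizes at which the population-level
statistics (signed-rank, paired t) have meaningful resolution while single
runs stay cheap.

## Known limitations

* The parabolic inhalation offset underestimates the true zero return by a
  few percent for sine-like lobes; λ estimates absorb this through Q_norm.
* The rate floor ε couples weakly with the Jacobian for extreme warps
  (floor applied in transformed time).
* λ recovery degrades below ~30 trials per dataset; the λ-fit reliability
  flag should be honored.
* The KS classifier's duration-mix sensitivity (above) means background
  sniffs should be drawn from the same sniff-statistics regime as the
  odorized sniffs.
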