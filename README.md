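# sniffalign

Sniff-invariant analysis of olfactory-bulb odor responses.

In awake rodents, every odor sample rides on a sniff, and sniff waveforms
vary widely (cycle durations roughly 74–441 ms, median ~143 ms).  That
variability propagates into the responses of mitral/tufted (MT) cells:
response amplitude and latency change with sniff duration even though the
animal's percept of odor intensity does not.  `sniffalign` implements the
analysis pipeline for asking which *transformation of spike-train time*
removes this sampling-induced variability:

1. **Sniff processing** — segment intranasal pressure traces into sniff
   cycles (inhalation onsets at negative-going zero crossings; inhalation
   offset from a parabolic fit to the pressure minimum) and integrate the
   rectified inhalation pressure, `F_i(τ) = ∫₀^τ max(−P_i(t), 0) dt`.
2. **Alignment models** — five candidate spike-time transformations T:
   *time* (identity), *phase* (scale the whole cycle to the mean duration),
   *two-interval phase* (scale inhalation and the remainder independently),
   *inhalation-proportional* (scale everything by the inhalation ratio), and
   the *fluid-dynamics (FD) model*: each trial is rigidly shifted by
   `−(τ_f^i − ⟨τ_f⟩)`, where the front-arrival time τ_f^i is the moment the
   cumulative inhalation flux reaches a fraction λ of the session-mean total
   flux `Q_norm` — the time inhaled air needs to carry odor a fixed
   effective distance into the nose.  λ ∈ [0, 1] is the model's only free
   parameter; λ = 0 reduces to the time model.
3. **Likelihood engine** — each alignment is scored by how well the PSTH of
   transformed training spikes, pulled back onto every held-out sniff with
   the change-of-variables Jacobian, predicts that sniff's spikes under the
   inhomogeneous-Poisson log-likelihood
   `log P({t_j}|f_i) = Σ_j log f_i(t_j) − ∫₀^T f_i(t) dt`.
   λ is profiled over a 21-point grid (step 0.05) and refined by a quadratic
   fit; models are compared across cell-odor datasets with Wilcoxon
   signed-rank tests.
4. **Response characterization** — excitatory/inhibitory classification
   (two-sample KS against pre-odor background, sign of the first cumulative
   deviation) and fast/slow sniff comparisons of early spike count, peak
   rate and peak latency, with the latency-shift regression.
5. **Concentration decoding** — likelihood-ratio discrimination of two
   concentrations from single sniffs, with leave-one-out PSTHs, under any
   alignment (λ fitted per concentration for the FD model).
6. **Psychometrics** — two-alternative concentration classification:
   `ψ(c) = (1 − 2γ)·Φ((c − μ)/σ) + γ` fitted by maximum likelihood with
   deviance goodness-of-fit, 250-rep bootstrap CIs, and fast/slow-sniff
   split fits testing sniff invariance of (μ, σ, γ).
7. **Synthetic data** — generators for sniff waveforms, FD-consistent spike
   trains, and behavioral sessions with stored ground truth, so the whole
   pipeline is testable end to end without recordings.

The package is a library: import it from Python; the `examples/` scripts are
short narrative walk-throughs of each capability.

## Worked example

Recover the FD model's effective distance from synthetic data
(`examples/02_fit_lambda.py`):

```python
import sniffalign as sa

trials, gt = sa.generate_neural_session(
    sa.SniffGenParams(), sa.NeuralGenParams(lambda_true=0.35),
    n_trials=100, seed=11)
fit = sa.fit_lambda(trials, grid_step=0.05, k_folds=5, seed=0)
print(fit.lambda_opt, fit.reliable)
```

Running the example prints:

```
simulated 100 single-sniff trials, lambda* = 0.35, mean 2.7 spikes/sniff
grid evaluations: 21 (lambda 0..1, step 0.05)
grid argmax: lambda = 0.40 (mean held-out LL 6.652 nats/sniff; LL at lambda=0, i.e. the time model: 6.511)
parabola-refined lambda_opt = 0.382 (reliable=True) -- recovery error 0.032, ...
```

The λ profile peaks near the generating value: the cross-validated
log-likelihood at λ ≈ 0.35–0.40 exceeds the λ = 0 (time-model) score by
~0.14 nats per sniff, and the quadratic refinement lands within half a grid
step of the true effective distance.  `examples/03_model_comparison.py`
shows the five-model ranking on such data (FD first), and
`examples/04_decode_concentration.py` the likelihood-ratio concentration
decoder under time vs FD alignment.

## Layout

```
src/sniffalign/
  sniff.py          pressure traces, sniff cycles, flux integrals
  alignment.py      the five transformations, inverse rate transform
  likelihood.py     PSTHs, Poisson scoring, cross-validation, lambda fit
  responses.py      KS classification, fast/slow feature comparisons
  decoding.py       likelihood-ratio concentration decoder
  psychometrics.py  psychometric MLE, bootstrap, split fits
  synth.py          synthetic sniffs, spikes, behavior (ground truth)
  io.py             HDF5/CSV interfaces
examples/           one runnable narrative script per capability
docs/methods.md     model assumptions, parameter choices, limitations
```
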