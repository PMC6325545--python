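"""Fit the fluid-dynamics model's effective-distance parameter lambda.

Simulates one cell-odor pair whose response latency follows the odor-front
arrival time at lambda* = 0.35, then profiles the cross-validated Poisson
log-likelihood over the lambda grid (0 to 1, step 0.05) and refines the
optimum with a quadratic fit — recovering the generating value.
"""

import numpy as np

import sniffalign as sa

LAMBDA_TRUE = 0.35
trials, gt = sa.generate_neural_session(
    sa.SniffGenParams(), sa.NeuralGenParams(lambda_true=LAMBDA_TRUE),
    n_trials=100, seed=11)
print(f"simulated {len(trials)} single-sniff trials, lambda* = {LAMBDA_TRUE}, "
      f"mean {np.mean([t.spike_times.size for t in trials]):.1f} spikes/sniff")

fit = sa.fit_lambda(trials, grid_step=0.05, k_folds=5, seed=0)
print(f"grid evaluations: {fit.grid.size} (lambda 0..1, step 0.05)")
i = int(np.argmax(fit.grid_ll))
print(f"grid argmax: lambda = {fit.grid[i]:.2f} "
      f"(mean held-out LL {fit.grid_ll[i]:.3f} nats/sniff; "
      f"LL at lambda=0, i.e. the time model: {fit.grid_ll[0]:.3f})")
print(f"parabola-refined lambda_opt = {fit.lambda_opt:.3f} "
      f"(reliable={fit.reliable}) -- recovery error "
      f"{abs(fit.lambda_opt - LAMBDA_TRUE):.3f}, under half a grid step "
      "is typical at 100 trials")
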