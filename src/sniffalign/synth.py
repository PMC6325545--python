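"""Synthetic sniffing, spiking and behavioral data with known ground truth.

The generator emulates the statistics of awake-rodent respiration and
olfactory-bulb mitral/tufted (MT) cell responses so that every analysis stage
can be exercised against a stored ground truth:

* Sniff cycles: lognormal cycle durations (median 143 ms by default, matching
  the observed range of roughly 74-441 ms), a negative half-sine inhalation
  lobe followed by a volume-balancing positive exhalation lobe, and a
  configurable negative correlation between log amplitude and log duration
  (faster sniffs are deeper).
* Neural responses: each trial's response kernel is centred at
  ``tau_f(lambda_true) + tau_n`` — the fluid-dynamics odor-front arrival time
  for that trial's waveform plus a waveform-independent neural delay — on top
  of a constant baseline; spikes are drawn by thinning an inhomogeneous
  Poisson process.  Concentration shifts lambda down and the peak rate up.
  A ``latency_model='phase'`` variant instead time-scales a fixed rate
  template with the cycle duration (count-conserving), for model-recovery
  tests of the phase alignment.
* Behavior: two-alternative choices drawn from the three-parameter
  psychometric function over an eight-step log-spaced concentration grid,
  with first-sniff durations drawn from the sniff-duration distribution and,
  by default, no dependence of the psychometric parameters on sniff speed.

All outputs are exactly reproducible from ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import SpikeTrainTrial
from .psychometrics import BehaviorTrial, psychometric_value
from .sniff import InhalationFlux, PressureTrace, SniffCycle, inhalation_flux

__all__ = [
    "SniffGenParams",
    "NeuralGenParams",
    "BehaviorGenParams",
    "generate_sniff_train",
    "generate_neural_session",
    "generate_behavior_session",
    "reprocess_trial",
]


@dataclass
class SniffGenParams:
    """Sniff-waveform statistics.

    Defaults give a median cycle of 143 ms with a lognormal spread wide
    enough to cover roughly 74-441 ms over a session, an inhalation occupying
    ~45% of the cycle, and corr(log A, log T) = -coupling_rho (faster sniffs
    are deeper).
    """

    median_duration_ms: float = 143.0
    duration_log_sd: float = 0.30
    inhalation_fraction_mean: float = 0.45
    inhalation_fraction_sd: float = 0.04
    amplitude_median: float = 1.0
    amplitude_log_sd: float = 0.30
    coupling_rho: float = 0.5
    sample_rate_hz: float = 1000.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.median_duration_ms <= 0:
            raise ValueError("median duration must be positive")
        if not (0.0 < self.inhalation_fraction_mean < 1.0):
            raise ValueError("inhalation fraction must lie in (0, 1)")


@dataclass
class NeuralGenParams:
    """Odor-response model for one simulated cell-odor pair.

    ``lambda_true`` is the FD model's effective-distance fraction;
    ``tau_n_ms`` the waveform-independent neural delay.  Concentration (in
    log10 dilution units) moves lambda by ``d_lambda_per_log`` (negative:
    higher concentration activates receptors at a shorter effective
    distance) and the kernel peak by ``d_peak_hz_per_log``.
    """

    lambda_true: float = 0.4
    tau_n_ms: float = 30.0
    kernel: str = "gaussian"
    kernel_width_ms: float = 15.0
    peak_rate_hz: float = 60.0
    baseline_rate_hz: float = 3.0
    d_lambda_per_log: float = -0.10
    d_peak_hz_per_log: float = 20.0
    latency_model: str = "fd"  # 'fd' | 'phase'

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.kernel_width_ms <= 0:
            raise ValueError("kernel width must be positive")
        if self.peak_rate_hz < 0 or self.baseline_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.latency_model not in ("fd", "phase"):
            raise ValueError("latency_model must be 'fd' or 'phase'")


@dataclass
class BehaviorGenParams:
    """Ground truth of the behavioral forward model (concentrations in log10
    dilution units, eight equally spaced steps across one order of magnitude).

    ``mu_shift_fast``/``sigma_shift_fast``/``gamma_shift_fast`` inject a
    dependence of the psychometric parameters on sniff speed (added to the
    parameter on trials whose first sniff is faster than the median);
    defaults are zero — no dependence.
    """

    mu: float = 0.0
    sigma: float = 0.15
    gamma: float = 0.05
    n_trials: int = 800
    conc_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-0.5, 0.5, 8)
    )
    sniff_median_ms: float = 143.0
    sniff_log_sd: float = 0.30
    mu_shift_fast: float = 0.0
    sigma_shift_fast: float = 0.0
    gamma_shift_fast: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or not (0.0 <= self.gamma < 0.5):
            raise ValueError("require sigma > 0 and gamma in [0, 0.5)")
        if self.n_trials < 8:
            raise ValueError("need at least 8 trials")


def _draw_cycles(params: SniffGenParams, n: int, rng: np.random.Generator):
    """Correlated (duration, inhalation duration, amplitude) draws."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = params.coupling_rho
    dur = params.median_duration_ms * np.exp(params.duration_log_sd * z1)
    amp = params.amplitude_median * np.exp(
        params.amplitude_log_sd * (-rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * z2)
    )
    frac = np.clip(
        params.inhalation_fraction_mean
        + params.inhalation_fraction_sd * rng.standard_normal(n),
        0.2,
        0.75,
    )
    return dur, frac * dur, amp


def _cycle_waveform(dur: float, t_inh: float, amp: float, fs: float) -> np.ndarray:
    """Half-sine inhalation + volume-balancing exhalation lobe, sampled at fs."""
    n = max(int(round(dur * fs / 1000.0)), 4)
    t = np.arange(n) * 1000.0 / fs
    p = np.empty(n)
    inh = t < t_inh
    p[inh] = -amp * np.sin(np.pi * t[inh] / t_inh)
    t_exh = dur - t_inh
    amp_exh = amp * t_inh / t_exh  # equal inhaled/exhaled volume
    p[~inh] = amp_exh * np.sin(np.pi * (t[~inh] - t_inh) / t_exh)
    return p


def generate_sniff_train(
    params: SniffGenParams, n_cycles: int, seed: int = 0
) -> tuple[PressureTrace, list[SniffCycle]]:
    """A continuous pressure trace of ``n_cycles`` sniffs plus ground truth.

    A short positive exhalation tail is prepended before the first cycle and
    an inhalation stub appended after the last one, so every onset — first
    and last included — is a genuine negative-going zero crossing.  Ground-
    truth cycles store the exact onsets, half-sine inhalation ends and cycle
    ends.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    rng = np.random.default_rng(seed)
    dur, t_inh, amp = _draw_cycles(params, n_cycles, rng)
    fs = params.sample_rate_hz
    chunks, cycles = [], []
    # lead-in: decaying tail of a previous exhalation (30 ms)
    n_lead = max(int(round(30.0 * fs / 1000.0)), 4)
    t_lead = np.arange(n_lead) * 1000.0 / fs
    lead_dur = n_lead * 1000.0 / fs
    chunks.append(0.3 * params.amplitude_median
                  * np.sin(0.5 * np.pi * (1.0 - t_lead / lead_dur)))
    t_cursor = lead_dur
    for i in range(n_cycles):
        wav = _cycle_waveform(dur[i], t_inh[i], amp[i], fs)
        actual = wav.size * 1000.0 / fs  # grid-quantised cycle length
        cycles.append(
            SniffCycle(
                onset=t_cursor,
                inhalation_offset=t_cursor + t_inh[i],
                cycle_end=t_cursor + actual,
                trial_id=i,
            )
        )
        chunks.append(wav)
        t_cursor += actual
    # stub: first 30 ms of one more inhalation, so the last onset is a crossing
    stub_dur, stub_inh, stub_amp = _draw_cycles(params, 1, rng)
    stub = _cycle_waveform(stub_dur[0], stub_inh[0], stub_amp[0], fs)
    chunks.append(stub[: max(int(round(30.0 * fs / 1000.0)), 4)])
    samples = np.concatenate(chunks)
    if params.noise_sd > 0:
        samples = samples + rng.normal(
            0.0, params.noise_sd * params.amplitude_median, samples.size
        )
    return PressureTrace(samples=samples, sample_rate=fs, t0=0.0), cycles


def _thin_poisson(rate_fn, rate_max: float, dur: float, rng) -> np.ndarray:
    """Spike times on [0, dur) ms from an inhomogeneous Poisson by thinning."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * dur / 1000.0)
    cand = np.sort(rng.uniform(0.0, dur, n))
    keep = rng.uniform(0.0, rate_max, n) < rate_fn(cand)
    return cand[keep]


def generate_neural_session(
    sniff_params: SniffGenParams,
    neural_params: NeuralGenParams,
    n_trials: int,
    concentration_log: float = 0.0,
    seed: int = 0,
    odor_id: str = "odorA",
) -> tuple[list[SpikeTrainTrial], dict]:
    """Simulate one cell-odor(-concentration) dataset of single-sniff trials.

    Each trial is one odorized sniff in its own coordinate frame (onset at
    0).  The per-trial FD delay is computed from the trial's *noise-free*
    waveform via the same flux machinery the analysis uses, with Q_norm taken
    as the session mean of the trial totals; the response kernel is placed at
    ``tau_f + tau_n`` (kernels running past the cycle end are truncated by
    construction and flagged in the ground truth).

    Returns ``(trials, ground_truth)``; trials carry their flux and noisy
    pressure segment, ground truth stores every latent variable.
    """
    rng = np.random.default_rng(seed)
    p, q = sniff_params, neural_params
    dur, t_inh, amp = _draw_cycles(p, n_trials, rng)
    fs = p.sample_rate_hz

    traces, fluxes, cycles = [], [], []
    for i in range(n_trials):
        clean = _cycle_waveform(dur[i], t_inh[i], amp[i], fs)
        actual = clean.size * 1000.0 / fs
        cyc = SniffCycle(onset=0.0, inhalation_offset=min(t_inh[i], actual - 1.0 / fs),
                         cycle_end=actual, trial_id=i)
        trace_clean = PressureTrace(samples=clean, sample_rate=fs)
        fluxes.append(inhalation_flux(trace_clean, cyc))
        noisy = clean + (rng.normal(0.0, p.noise_sd * p.amplitude_median, clean.size)
                         if p.noise_sd > 0 else 0.0)
        traces.append(PressureTrace(samples=noisy, sample_rate=fs))
        cycles.append(cyc)

    qnorm = float(np.mean([f.total for f in fluxes]))
    lam_eff = float(np.clip(q.lambda_true + q.d_lambda_per_log * concentration_log,
                            0.0, 1.0))
    peak_eff = max(0.0, q.peak_rate_hz + q.d_peak_hz_per_log * concentration_log)

    tau_f = np.empty(n_trials)
    capped = np.zeros(n_trials, dtype=bool)
    for i, f in enumerate(fluxes):
        tau_f[i], capped[i] = f.delay_at(lam_eff * qnorm)

    mean_dur = p.median_duration_ms * np.exp(0.5 * p.duration_log_sd**2)
    centers = np.empty(n_trials)
    truncated = np.zeros(n_trials, dtype=bool)
    trials = []
    for i in range(n_trials):
        d = cycles[i].duration
        if q.latency_model == "fd":
            c0, w, pk = tau_f[i] + q.tau_n_ms, q.kernel_width_ms, peak_eff
        else:  # phase-consistent data: template scaled with cycle duration
            s = d / mean_dur
            c0 = (q.tau_n_ms + 0.5 * p.inhalation_fraction_mean * mean_dur) * s
            w = q.kernel_width_ms * s
            pk = peak_eff / s
        centers[i] = c0
        truncated[i] = c0 + 2.0 * w > d

        def rate(t, c0=c0, w=w, pk=pk):
            return q.baseline_rate_hz + pk * np.exp(-0.5 * ((t - c0) / w) ** 2)

        spikes = _thin_poisson(rate, q.baseline_rate_hz + max(pk, 0.0), d, rng)
        trials.append(
            SpikeTrainTrial(
                spike_times=spikes,
                cycle=cycles[i],
                stimulus=(odor_id, concentration_log),
                trial_id=i,
                flux=fluxes[i],
                trace=traces[i],
            )
        )
    ground_truth = {
        "lambda_true": q.lambda_true,
        "lambda_effective": lam_eff,
        "qnorm": qnorm,
        "tau_f": tau_f,
        "tau_f_capped": capped,
        "kernel_centers": centers,
        "kernel_truncated": truncated,
        "durations": dur,
        "t_inh": t_inh,
        "amplitudes": amp,
        "concentration_log": concentration_log,
        "peak_rate_effective": peak_eff,
    }
    return trials, ground_truth


def reprocess_trial(trial: SpikeTrainTrial, smoothing_ms: float = 5.0) -> SpikeTrainTrial:
    """Re-derive a trial's cycle and flux from its stored noisy pressure trace.

    Runs the parabolic inhalation-offset detector and the flux integral on
    the raw trace (onset fixed at 0, where the generator starts each cycle),
    replacing the generator's ground-truth values — the full measurement
    pipeline a real recording would go through.
    """
    from .sniff import inhalation_offset_parabolic  # local import, no cycle

    if trial.trace is None:
        raise ValueError("trial has no stored pressure trace")
    tr = trial.trace
    end = tr.times[-1]
    t_inh, flagged = inhalation_offset_parabolic(tr, onset=0.0, cycle_end=end,
                                                 smoothing_ms=smoothing_ms)
    cyc = SniffCycle(onset=0.0, inhalation_offset=t_inh,
                     cycle_end=trial.cycle.cycle_end,
                     trial_id=trial.trial_id, flagged=flagged)
    flux = inhalation_flux(tr, cyc)
    return SpikeTrainTrial(spike_times=trial.spike_times, cycle=cyc,
                           stimulus=trial.stimulus, trial_id=trial.trial_id,
                           flux=flux, trace=tr)


def generate_behavior_session(
    params: BehaviorGenParams, seed: int = 0, session_id: object = 0
) -> list[BehaviorTrial]:
    """Simulate a two-alternative concentration-classification session.

    Concentrations are drawn uniformly from the eight-step grid, choices are
    Bernoulli with probability given by the psychometric function, and
    first-sniff durations come from the lognormal sniff distribution,
    independent of choice unless a fast/slow parameter shift is configured.
    """
    rng = np.random.default_rng(seed)
    n = params.n_trials
    conc = rng.choice(params.conc_grid, size=n)
    sniff = params.sniff_median_ms * np.exp(
        params.sniff_log_sd * rng.standard_normal(n)
    )
    fast = sniff < np.median(sniff)
    mu = params.mu + params.mu_shift_fast * fast
    sigma = np.maximum(params.sigma + params.sigma_shift_fast * fast, 1e-6)
    gamma = np.clip(params.gamma + params.gamma_shift_fast * fast, 0.0, 0.499)
    p_high = psychometric_value(conc, mu, sigma, gamma)
    choice = rng.random(n) < p_high
    return [
        BehaviorTrial(
            concentration=float(conc[i]),
            choice="high_port" if choice[i] else "low_port",
            first_sniff_ms=float(sniff[i]),
            session_id=session_id,
            trial_id=i,
        )
        for i in range(n)
    ]
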