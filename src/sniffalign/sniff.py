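"""Sniff-cycle segmentation and inhalation-flux integrals.

The intranasal pressure signal is the analysis' proxy for airflow velocity in
the nose.  Sign convention throughout: inhalation is a *negative* pressure
deflection, exhalation positive.  A sniff cycle runs from one inhalation onset
(negative-going zero crossing of the smoothed pressure) to the next; the
inhalation offset ``t_inh`` is located by a parabolic fit around the first
pressure minimum, taking the parabola's later zero crossing.

Odor is carried into the nose only while air flows inward, so the quantity
that matters for latency modelling is the cumulative *inhalation* flux

    F(tau) = integral_0^tau max(-P(t), 0) dt,      tau in [0, t_inh],

in sensor-units * ms.  The unknown pressure-to-velocity proportionality is
never calibrated: all downstream quantities use flux normalised by the
session-mean total ``Q_norm``, which cancels the constant.

All times are in milliseconds relative to trial start; sniff-relative times
are measured from the inhalation onset.  Intervals are half-open
``[onset, cycle_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PressureTrace",
    "SniffCycle",
    "InhalationFlux",
    "segment_sniffs",
    "inhalation_offset_parabolic",
    "inhalation_flux",
    "compute_qnorm",
]


@dataclass
class PressureTrace:
    """Uniformly sampled intranasal pressure for one trial.

    Parameters
    ----------
    samples : ndarray
        Pressure sequence in arbitrary sensor units (inhalation negative).
    sample_rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample relative to trial start, in ms.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to trial start."""
        return self.t0 + np.arange(self.samples.size) * self.dt_ms


@dataclass
class SniffCycle:
    """One respiration period: inhalation onset to the next inhalation onset.

    ``flagged`` marks cycles whose inhalation offset came from the zero-return
    fallback rather than a well-conditioned parabolic fit.
    """

    onset: float
    inhalation_offset: float
    cycle_end: float
    trial_id: object = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.onset < self.inhalation_offset < self.cycle_end):
            raise ValueError(
                "require onset < inhalation_offset < cycle_end, got "
                f"{self.onset}, {self.inhalation_offset}, {self.cycle_end}"
            )

    @property
    def duration(self) -> float:
        return self.cycle_end - self.onset

    @property
    def t_inh(self) -> float:
        """Inhalation duration (ms from onset)."""
        return self.inhalation_offset - self.onset

    @property
    def t_exh(self) -> float:
        """Duration of the post-inhalation remainder of the cycle."""
        return self.cycle_end - self.inhalation_offset


@dataclass
class InhalationFlux:
    """Cumulative rectified inhalation-pressure integral for one sniff.

    ``tau`` is time from inhalation onset (ms), ``cum`` the running integral
    of ``max(-P, 0)`` in sensor-units*ms.  ``cum`` is non-decreasing with
    ``cum[0] == 0``; ``total`` is the value at ``t_inh``.
    """

    tau: np.ndarray
    cum: np.ndarray
    flagged: bool = False

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.cum = np.asarray(self.cum, dtype=float)
        if self.tau.shape != self.cum.shape or self.tau.size < 2:
            raise ValueError("tau and cum must be matching arrays of length >= 2")
        if self.cum[0] != 0.0 or np.any(np.diff(self.cum) < -1e-12):
            raise ValueError("cum must start at 0 and be non-decreasing")

    @property
    def t_inh(self) -> float:
        return float(self.tau[-1])

    @property
    def total(self) -> float:
        return float(self.cum[-1])

    def cum_at(self, tau: float | np.ndarray) -> np.ndarray:
        """Interpolated cumulative integral at ``tau`` ms after onset."""
        return np.interp(tau, self.tau, self.cum)

    def delay_at(self, target: float) -> tuple[float, bool]:
        """Smallest tau with ``cum(tau) >= target``.

        Returns ``(tau, capped)``; ``capped`` is True when the target exceeds
        the total integral, in which case tau is pinned to ``t_inh``.
        """
        if target <= 0.0:
            return 0.0, False
        if target > self.total:
            return self.t_inh, True
        i = int(np.searchsorted(self.cum, target, side="left"))
        if i == 0:
            return float(self.tau[0]), False
        c0, c1 = self.cum[i - 1], self.cum[i]
        # side="left" guarantees c0 < target <= c1, so c1 > c0
        frac = (target - c0) / (c1 - c0)
        return float(self.tau[i - 1] + frac * (self.tau[i] - self.tau[i - 1])), False


def _smooth(samples: np.ndarray, sample_rate: float, smoothing_ms: float) -> np.ndarray:
    if smoothing_ms < 0:
        raise ValueError("smoothing_ms must be >= 0")
    win = int(round(smoothing_ms * sample_rate / 1000.0))
    if win <= 1:
        return samples
    kernel = np.full(win, 1.0 / win)
    return np.convolve(samples, kernel, mode="same")


def segment_sniffs(
    trace: PressureTrace,
    smoothing_ms: float = 5.0,
    min_cycle_ms: float = 40.0,
) -> list[SniffCycle]:
    """Parse a pressure trace into contiguous, ordered sniff cycles.

    Inhalation onsets are negative-going zero crossings of the moving-average
    smoothed pressure (onset times linearly interpolated between samples);
    crossings closer than ``min_cycle_ms`` to the previous accepted onset are
    treated as noise and discarded.  The inhalation offset of each cycle is
    located with :func:`inhalation_offset_parabolic`.  The stretch after the
    final onset is not returned as a cycle (its end is unknown).

    Returns an empty list for traces with no zero crossings.  Raises
    ``ValueError`` on non-finite samples.
    """
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("pressure trace contains non-finite samples")
    s = _smooth(trace.samples, trace.sample_rate, smoothing_ms)
    t = trace.times

    neg = s < 0.0
    crossing_idx = np.flatnonzero(~neg[:-1] & neg[1:])
    onsets: list[float] = []
    for i in crossing_idx:
        # interpolate the zero time within [t[i], t[i+1]]
        if s[i] == s[i + 1]:
            onset = t[i]
        else:
            onset = t[i] + (0.0 - s[i]) / (s[i + 1] - s[i]) * (t[i + 1] - t[i])
        if onsets and onset - onsets[-1] < min_cycle_ms:
            continue
        onsets.append(float(onset))

    cycles: list[SniffCycle] = []
    for k in range(len(onsets) - 1):
        onset, cycle_end = onsets[k], onsets[k + 1]
        t_inh, flagged = inhalation_offset_parabolic(
            trace, onset, cycle_end=cycle_end, smoothing_ms=smoothing_ms
        )
        cycles.append(
            SniffCycle(
                onset=onset,
                inhalation_offset=t_inh,
                cycle_end=cycle_end,
                trial_id=k,
                flagged=flagged,
            )
        )
    return cycles


def inhalation_offset_parabolic(
    trace: PressureTrace,
    onset: float,
    cycle_end: float | None = None,
    smoothing_ms: float = 5.0,
    window_frac: float = 0.25,
    min_window_samples: int = 5,
) -> tuple[float, bool]:
    """Locate the inhalation offset t_inh after ``onset``.

    A parabola is fitted to the raw pressure in a window of half-width
    ``window_frac`` times the onset-to-minimum interval (at least
    ``min_window_samples`` samples) around the first pressure minimum after
    onset; t_inh is the parabola's later zero crossing.  When the fit is
    degenerate (no real root beyond the minimum) the first sample at which
    the smoothed pressure returns to >= 0 is used instead and the result is
    flagged.

    Returns ``(t_inh_ms, flagged)``.
    """
    s = _smooth(trace.samples, trace.sample_rate, smoothing_ms)
    t = trace.times
    hi = t[-1] if cycle_end is None else min(cycle_end, t[-1])
    sel = (t >= onset) & (t <= hi)
    idx = np.flatnonzero(sel)
    if idx.size < 3:
        raise ValueError("onset too close to the end of the trace")

    # rough inhalation extent: from the first negative sample after onset to
    # the first return of the smoothed pressure to >= 0
    seg = idx
    neg_start = None
    for j in seg:
        if s[j] < 0:
            neg_start = j
            break
    if neg_start is None:
        raise ValueError("no pressure minimum after onset (trace never negative)")
    ret = None
    for j in range(neg_start + 1, seg[-1] + 1):
        if s[j] >= 0:
            ret = j
            break
    zero_return_t = t[ret] if ret is not None else hi
    search_end = ret if ret is not None else seg[-1]

    lobe = np.arange(neg_start, search_end + 1)
    i_min = lobe[np.argmin(trace.samples[lobe])]
    t_min = t[i_min]

    half = max(window_frac * (t_min - onset), 0.5 * min_window_samples * trace.dt_ms)
    win = np.flatnonzero((t >= t_min - half) & (t <= t_min + half))
    if win.size < 3:
        win = np.arange(max(i_min - 2, 0), min(i_min + 3, t.size))

    a, b, c = np.polyfit(t[win], trace.samples[win], 2)
    disc = b * b - 4 * a * c
    flagged = False
    if a <= 0 or disc <= 0:
        t_inh = float(zero_return_t)
        flagged = True
    else:
        root = (-b + np.sqrt(disc)) / (2 * a)  # later root (a > 0)
        if root <= t_min or root <= onset:
            t_inh = float(zero_return_t)
            flagged = True
        else:
            t_inh = float(root)
    if cycle_end is not None and t_inh >= cycle_end:
        t_inh = float(min(zero_return_t, cycle_end - trace.dt_ms))
        flagged = True
    if t_inh <= onset:  # pathological fallback
        t_inh = float(onset + trace.dt_ms)
        flagged = True
    return t_inh, flagged


def inhalation_flux(trace: PressureTrace, cycle: SniffCycle) -> InhalationFlux:
    """Trapezoidal cumulative integral of rectified inhalation pressure.

    Integrates ``max(-P, 0)`` on ``[onset, t_inh]`` on the native sampling
    grid (exact endpoints added by linear interpolation; no resampling).
    A flux whose total is zero (no inward-directed pressure during the
    inhalation window) is flagged.
    """
    t = trace.times
    if cycle.onset < t[0] - 1e-9 or cycle.inhalation_offset > t[-1] + 1e-9:
        raise ValueError("cycle extends beyond the trace")
    inner = t[(t > cycle.onset) & (t < cycle.inhalation_offset)]
    grid = np.concatenate(([cycle.onset], inner, [cycle.inhalation_offset]))
    p = np.interp(grid, t, trace.samples)
    rect = np.maximum(-p, 0.0)
    cum = np.concatenate(([0.0], cumulative_trapezoid(rect, grid)))
    return InhalationFlux(tau=grid - cycle.onset, cum=cum, flagged=cum[-1] == 0.0)


def compute_qnorm(fluxes: list[InhalationFlux]) -> float:
    """Session normalisation constant: mean total inhalation flux over trials."""
    if len(fluxes) == 0:
        raise ValueError("compute_qnorm requires at least one flux")
    return float(np.mean([f.total for f in fluxes]))
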