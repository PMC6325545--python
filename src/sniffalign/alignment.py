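"""Spike-train alignment models and their action on rate functions.

Five per-trial remappings T of spike times (all measured from inhalation
onset) are implemented:

``time``
    identity — spikes stay in real time.
``phase``
    the whole cycle is scaled to the reference (training-set mean) cycle
    duration: ``t~ = t * <dur> / dur_i``.
``two_interval_phase``
    inhalation and the remainder of the cycle are scaled independently to
    their reference durations.
``inhalation_proportional``
    the whole cycle is scaled by the inhalation ratio ``<t_inh> / t_inh_i``.
``fd``
    fluid-dynamics model: a rigid shift ``t~ = t - (tau_f_i - <tau_f>)``,
    where ``tau_f_i`` is the trial's odor-front arrival time — the moment the
    cumulative inhalation flux reaches a fraction ``lambda`` of the
    session-mean total flux.  ``lambda`` in [0, 1] is the model's only free
    parameter; ``lambda = 0`` makes every shift zero, i.e. the time model.

Each map is strictly increasing and piecewise linear, so it is represented by
its knots and inverted exactly.  Rates transform with the change-of-variables
Jacobian: a PSTH ``f~`` estimated in transformed time pulls back to trial
time as ``f_i(t) = f~(w(t)) * w'(t)``, which conserves expected spike counts
(a config switch disables the Jacobian for diagnostic purposes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .sniff import InhalationFlux, SniffCycle

__all__ = [
    "MODELS",
    "SpikeTrainTrial",
    "AlignmentReference",
    "AlignmentSpec",
    "FDDelay",
    "fd_delay",
    "compute_reference",
    "map_knots",
    "transform_spike_train",
    "inverse_transform_rate",
    "TrialRate",
]

MODELS = ("time", "phase", "two_interval_phase", "inhalation_proportional", "fd")


@dataclass
class SpikeTrainTrial:
    """Spike times of one analyzed sniff, with its cycle and stimulus labels.

    Spike times are ms relative to the inhalation onset of the analyzed sniff
    and must lie in ``[0, cycle.duration)``, sorted ascending.  ``flux`` (the
    trial's inhalation-flux integral) is required by the FD model; ``trace``
    optionally keeps the raw pressure segment.
    """

    spike_times: np.ndarray
    cycle: SniffCycle
    stimulus: tuple = (None, None)
    trial_id: object = None
    flux: InhalationFlux | None = None
    trace: object = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and (
            np.any(np.diff(self.spike_times) < 0)
            or self.spike_times[0] < 0
            or self.spike_times[-1] >= self.cycle.duration
        ):
            raise ValueError("spike times must be sorted and within [0, cycle duration)")


@dataclass
class AlignmentReference:
    """Training-set means that anchor the transformed time axis (all ms)."""

    mean_dur: float
    mean_inh: float
    mean_exh: float
    mean_tau_f: float = 0.0
    qnorm: float | None = None

    def __post_init__(self) -> None:
        if self.mean_dur <= 0 or self.mean_inh <= 0 or self.mean_exh <= 0:
            raise ValueError("reference means must be strictly positive")


@dataclass
class AlignmentSpec:
    """An alignment rule: model name, FD lambda, and frozen reference means.

    ``lam`` is meaningful only for ``model='fd'``; leaving it ``None`` there
    asks downstream cross-validation to select lambda on training data.
    ``jacobian`` controls whether inverse-transformed rates carry the
    change-of-variables factor (default on; off does plain interpolation).
    """

    model: str
    lam: float | None = None
    reference: AlignmentReference | None = None
    jacobian: bool = True

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.model != "fd" and self.lam is not None:
            raise ValueError("lambda is only meaningful for the fd model")
        if self.lam is not None and not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = {"model": self.model, "lam": self.lam, "jacobian": self.jacobian}
        d["reference"] = asdict(self.reference) if self.reference else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentSpec":
        ref = d.get("reference")
        return cls(
            model=d["model"],
            lam=d.get("lam"),
            reference=AlignmentReference(**ref) if ref else None,
            jacobian=d.get("jacobian", True),
        )


@dataclass
class FDDelay:
    """Per-trial odor-front arrival time tau_f (ms from inhalation onset)."""

    tau_f: float
    capped: bool = False


def fd_delay(flux: InhalationFlux, lam: float, qnorm: float) -> FDDelay:
    """FD arrival time: smallest tau with ``cum_flux(tau) >= lam * qnorm``.

    If the target exceeds the trial's total flux the delay is capped at the
    inhalation offset and flagged.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if qnorm <= 0:
        raise ValueError("qnorm must be positive")
    tau, capped = flux.delay_at(lam * qnorm)
    return FDDelay(tau_f=tau, capped=capped)


def _trial_tau_f(trial: SpikeTrainTrial, spec: AlignmentSpec) -> float:
    if trial.flux is None:
        raise ValueError("FD alignment requires trials with an attached flux")
    if spec.lam is None or spec.reference is None or spec.reference.qnorm is None:
        raise ValueError("FD alignment requires lambda and a reference with qnorm")
    return fd_delay(trial.flux, spec.lam, spec.reference.qnorm).tau_f


def compute_reference(
    trials: list[SpikeTrainTrial],
    model: str,
    lam: float | None = None,
    jacobian: bool = True,
) -> AlignmentSpec:
    """Freeze an AlignmentSpec from a training set.

    Computes the mean cycle/inhalation durations and — for the FD model —
    the session-mean total flux ``Q_norm`` and mean FD delay ``<tau_f>`` at
    the given lambda.  Call this on the *training* fold only; held-out
    evaluation must not see its own trials here.
    """
    if not trials:
        raise ValueError("need at least one trial")
    durs = np.array([t.cycle.duration for t in trials])
    inhs = np.array([t.cycle.t_inh for t in trials])
    ref = AlignmentReference(
        mean_dur=float(durs.mean()),
        mean_inh=float(inhs.mean()),
        mean_exh=float((durs - inhs).mean()),
    )
    spec = AlignmentSpec(model=model, lam=lam if model == "fd" else None,
                         reference=ref, jacobian=jacobian)
    if model == "fd":
        if lam is None:
            raise ValueError("compute_reference for fd requires lambda")
        fluxes = [t.flux for t in trials]
        if any(f is None for f in fluxes):
            raise ValueError("FD alignment requires trials with an attached flux")
        ref.qnorm = float(np.mean([f.total for f in fluxes]))
        taus = [fd_delay(f, lam, ref.qnorm).tau_f for f in fluxes]
        ref.mean_tau_f = float(np.mean(taus))
    return spec


def map_knots(trial: SpikeTrainTrial, spec: AlignmentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Knots (x, y) of the trial's strictly increasing piecewise-linear map.

    x covers ``[0, dur_i]`` in trial time; y is its image in transformed
    time.  All five models are exact instances of this representation.
    """
    ref = spec.reference
    if ref is None:
        raise ValueError("spec.reference must be set (use compute_reference)")
    d = trial.cycle.duration
    ti = trial.cycle.t_inh
    if d <= 0 or ti <= 0 or d - ti <= 0:
        raise ValueError("degenerate cycle: zero-duration interval")
    m = spec.model
    if m == "time":
        x, y = [0.0, d], [0.0, d]
    elif m == "phase":
        x, y = [0.0, d], [0.0, ref.mean_dur]
    elif m == "two_interval_phase":
        x = [0.0, ti, d]
        y = [0.0, ref.mean_inh, ref.mean_inh + ref.mean_exh]
    elif m == "inhalation_proportional":
        x, y = [0.0, d], [0.0, d * ref.mean_inh / ti]
    elif m == "fd":
        shift = ref.mean_tau_f - _trial_tau_f(trial, spec)
        x, y = [0.0, d], [shift, d + shift]
    else:  # pragma: no cover - guarded by AlignmentSpec
        raise ValueError(m)
    return np.asarray(x), np.asarray(y)


def transform_spike_train(trial: SpikeTrainTrial, spec: AlignmentSpec) -> np.ndarray:
    """Forward-map the trial's spike times into the model's aligned axis.

    FD-transformed times may be negative (trials whose odor front arrives
    late are shifted earlier); spikes are never dropped.
    """
    x, y = map_knots(trial, spec)
    return np.interp(trial.spike_times, x, y)


def _integrate_pl(xs: np.ndarray, ys: np.ndarray, a: float, b: float) -> float:
    """Exact integral of the piecewise-linear interpolant of (xs, ys) on [a, b].

    Outside [xs[0], xs[-1]] the function is extended with its edge values.
    """
    if b < a:
        raise ValueError("require a <= b")
    inner = xs[(xs > a) & (xs < b)]
    grid = np.concatenate(([a], inner, [b]))
    vals = np.interp(grid, xs, ys)
    return float(np.trapezoid(vals, grid))


class TrialRate:
    """Per-sniff rate function ``f_i(t) = f~(w(t)) * w'(t)`` on [0, dur).

    ``f~`` is the linear interpolation of PSTH rates between bin centers
    (edge-extended beyond its support); ``w`` is the trial's forward time
    map.  Provides exact expected-count integrals, since both factors are
    piecewise linear.
    """

    def __init__(
        self,
        psth_x: np.ndarray,
        psth_y: np.ndarray,
        map_x: np.ndarray,
        map_y: np.ndarray,
        jacobian: bool = True,
        extrapolated: bool = False,
    ):
        self.psth_x = np.asarray(psth_x, dtype=float)
        self.psth_y = np.asarray(psth_y, dtype=float)
        self.map_x = np.asarray(map_x, dtype=float)
        self.map_y = np.asarray(map_y, dtype=float)
        self.jacobian = jacobian
        self.extrapolated = extrapolated
        self._slopes = np.diff(self.map_y) / np.diff(self.map_x)

    def _w(self, t):
        return np.interp(t, self.map_x, self.map_y)

    def _slope(self, t):
        seg = np.clip(np.searchsorted(self.map_x, t, side="right") - 1, 0,
                      self._slopes.size - 1)
        return self._slopes[seg]

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rate = np.interp(self._w(t), self.psth_x, self.psth_y)
        if self.jacobian:
            rate = rate * self._slope(t)
        return rate

    def expected_count(self, a: float = 0.0, b: float | None = None) -> float:
        """Expected spike count on [a, b] (spikes; rates Hz, times ms)."""
        if b is None:
            b = float(self.map_x[-1])
        total = 0.0
        # integrate segment by segment so the non-Jacobian variant is exact too
        bounds = np.clip(self.map_x, a, b)
        seg_lo = np.concatenate(([a], bounds[(bounds > a) & (bounds < b)]))
        seg_hi = np.concatenate((seg_lo[1:], [b]))
        for lo, hi in zip(seg_lo, seg_hi):
            if hi <= lo:
                continue
            mid = 0.5 * (lo + hi)
            slope = float(self._slope(mid))
            piece = _integrate_pl(self.psth_x, self.psth_y, float(self._w(lo)),
                                  float(self._w(hi)))
            total += piece if self.jacobian else piece / slope
        return total / 1000.0  # Hz * ms -> spikes


def inverse_transform_rate(
    psth,
    trial: SpikeTrainTrial,
    spec: AlignmentSpec,
    floor: float = 0.0,
) -> TrialRate:
    """Pull a transformed-time PSTH back onto one trial's real-time axis.

    ``psth`` is any object with ``bin_edges`` (ms, transformed time) and
    ``rates`` (Hz) attributes — see ``likelihood.RatePSTH``.  The rate is
    floored at ``floor`` Hz (applied to the PSTH values before interpolation,
    so integrals remain exact).  If the trial's image extends beyond the PSTH
    support the PSTH is edge-extended and the result marked
    ``extrapolated=True``.
    """
    edges = np.asarray(psth.bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.maximum(np.asarray(psth.rates, dtype=float), floor)
    xs = np.concatenate(([edges[0]], centers, [edges[-1]]))
    ys = np.concatenate(([rates[0]], rates, [rates[-1]]))
    mx, my = map_knots(trial, spec)
    extrap = my[0] < edges[0] - 1e-9 or my[-1] > edges[-1] + 1e-9
    return TrialRate(xs, ys, mx, my, jacobian=spec.jacobian, extrapolated=extrap)
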