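"""Psychometric-function fitting for two-alternative concentration judgments.

The probability of a "high concentration" choice at log-concentration c is
modelled as

    psi(c) = (1 - 2*gamma) * Phi((c - mu) / sigma) + gamma

with Phi the standard normal CDF: mu is the categorical boundary, sigma the
noise (inverse sensitivity), and gamma a symmetric lapse/guess rate pulling
both asymptotes off 0 and 1.  Parameters are estimated by Bernoulli maximum
likelihood with gamma box-constrained to [0, 0.25]; goodness of fit is the
deviance against the saturated per-concentration model, and confidence
intervals come from a nonparametric bootstrap (resampling trials within
concentration, 250 repetitions by default).

``compare_split_fits`` tests sniff-duration invariance: trials are split at
the median first-sniff duration, each half fitted independently, and the
per-session parameter differences tested against zero across sessions with
the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import wilcoxon

__all__ = [
    "BehaviorTrial",
    "PsychometricFit",
    "SplitComparison",
    "psychometric_value",
    "fit_psychometric",
    "bootstrap_ci",
    "compare_split_fits",
]

_GAMMA_MAX = 0.25
_SIGMA_MIN = 1e-4


@dataclass
class BehaviorTrial:
    """One two-alternative choice trial."""

    concentration: float  # log10 dilution units
    choice: str  # 'high_port' | 'low_port'
    first_sniff_ms: float
    session_id: object = 0
    trial_id: object = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration):
            raise ValueError("concentration must be finite")
        if self.first_sniff_ms <= 0:
            raise ValueError("first_sniff_ms must be positive")
        if self.choice not in ("high_port", "low_port"):
            raise ValueError("choice must be 'high_port' or 'low_port'")


@dataclass
class PsychometricFit:
    mu: float
    sigma: float
    gamma: float
    deviance: float
    nll: float
    n_trials: int
    ci: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


@dataclass
class SplitComparison:
    """Fast/slow split fits per session and population signed-rank tests."""

    per_session: pd.DataFrame
    p_values: dict
    boundary_rule: str
    flags: list = field(default_factory=list)


def psychometric_value(c, mu, sigma, gamma):
    """psi(c; mu, sigma, gamma); vectorized over any argument."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return (1.0 - 2.0 * np.asarray(gamma)) * ndtr(
        (np.asarray(c, dtype=float) - mu) / sigma
    ) + gamma


def _extract(trials) -> tuple[np.ndarray, np.ndarray]:
    c = np.array([t.concentration for t in trials], dtype=float)
    y = np.array([1.0 if t.choice == "high_port" else 0.0 for t in trials])
    return c, y


def _nll(theta, c, y):
    mu, sigma, gamma = theta
    p = np.clip(psychometric_value(c, mu, sigma, gamma), 1e-10, 1.0 - 1e-10)
    return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _deviance(c, y, mu, sigma, gamma) -> float:
    """2 * (LL_saturated - LL_fit) over concentration bins (0*log0 := 0)."""
    ll_fit, ll_sat = 0.0, 0.0
    for cc in np.unique(c):
        m = c == cc
        n, k = int(m.sum()), float(y[m].sum())
        p_hat = k / n
        p_fit = float(np.clip(psychometric_value(cc, mu, sigma, gamma),
                              1e-10, 1 - 1e-10))
        ll_fit += k * np.log(p_fit) + (n - k) * np.log(1 - p_fit)
        if 0 < p_hat < 1:
            ll_sat += k * np.log(p_hat) + (n - k) * np.log(1 - p_hat)
    return float(2.0 * (ll_sat - ll_fit))


def fit_psychometric(trials) -> PsychometricFit:
    """Maximum-likelihood fit of (mu, sigma, gamma) to choice data.

    Uses L-BFGS-B from a small set of data-driven starts; sigma hitting its
    lower bound (perfect separation / step-like data) is flagged
    ``sigma_at_bound``.  Requires at least two distinct concentrations.
    """
    c, y = _extract(trials)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    crange = float(c.max() - c.min())
    # boundary start: concentration where the empirical curve crosses 0.5
    levels = np.unique(c)
    p_emp = np.array([y[c == cc].mean() for cc in levels])
    above = np.flatnonzero(p_emp >= 0.5)
    mu0 = float(levels[above[0]]) if above.size else float(levels[-1])
    bounds = [(c.min() - crange, c.max() + crange),
              (_SIGMA_MIN, 10.0 * max(crange, _SIGMA_MIN)),
              (0.0, _GAMMA_MAX)]
    best = None
    for start in ((mu0, crange / 4.0, 0.02),
                  (float(np.median(c)), crange / 2.0, 0.05),
                  (mu0, crange / 10.0, 0.0)):
        res = minimize(_nll, np.asarray(start), args=(c, y),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma, gamma = (float(v) for v in best.x)
    flags = []
    if sigma <= _SIGMA_MIN * 1.01:
        flags.append("sigma_at_bound")
    if gamma >= _GAMMA_MAX * 0.999:
        flags.append("gamma_at_bound")
    if not best.success:
        flags.append("optimizer_not_converged")
    return PsychometricFit(mu=mu, sigma=sigma, gamma=gamma,
                           deviance=_deviance(c, y, mu, sigma, gamma),
                           nll=float(best.fun), n_trials=len(trials), flags=flags)


def bootstrap_ci(trials, n_boot: int = 250, seed: int = 0,
                 ci_level: float = 0.95) -> dict:
    """Percentile bootstrap intervals for (mu, sigma, gamma).

    Trials are resampled with replacement *within* each concentration and
    refitted ``n_boot`` times.  Returns ``{'mu': (lo, hi), 'sigma': ...,
    'gamma': ..., 'n_boot': n, 'n_failed': k, 'flagged': bool}``; flagged
    when more than 10% of refits fail.
    """
    c, _ = _extract(trials)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    rng = np.random.default_rng(seed)
    by_conc = {cc: [t for t in trials if t.concentration == cc] for cc in np.unique(c)}
    draws = {"mu": [], "sigma": [], "gamma": []}
    failed = 0
    for _ in range(n_boot):
        sample = []
        for cc, grp in by_conc.items():
            idx = rng.integers(0, len(grp), len(grp))
            sample.extend(grp[i] for i in idx)
        try:
            f = fit_psychometric(sample)
            if "optimizer_not_converged" in f.flags:
                failed += 1
                continue
            draws["mu"].append(f.mu)
            draws["sigma"].append(f.sigma)
            draws["gamma"].append(f.gamma)
        except (ValueError, RuntimeError):
            failed += 1
    lo, hi = 50.0 * (1 - ci_level), 50.0 * (1 + ci_level)
    out = {}
    for k, v in draws.items():
        arr = np.asarray(v)
        out[k] = (float(np.percentile(arr, lo)), float(np.percentile(arr, hi)))
    out["n_boot"] = n_boot
    out["n_failed"] = failed
    out["flagged"] = failed > 0.1 * n_boot
    return out


def compare_split_fits(trials, split_rule: str = "median") -> SplitComparison:
    """Fit fast- and slow-sniff trials separately and compare parameters.

    Trials are grouped by ``session_id``; within each session the split is at
    the median first-sniff duration (fast: strictly below).  Sessions whose
    halves cannot be fitted are dropped and flagged.  Population p-values are
    Wilcoxon signed-rank tests of each parameter difference against zero
    (identically-zero differences report p = 1).
    """
    if split_rule != "median":
        raise ValueError("only the median split rule is implemented")
    sessions: dict = {}
    for t in trials:
        sessions.setdefault(t.session_id, []).append(t)
    rows, flags = [], []
    for sid, strials in sessions.items():
        sniffs = np.array([t.first_sniff_ms for t in strials])
        boundary = float(np.median(sniffs))
        fast = [t for t in strials if t.first_sniff_ms < boundary]
        slow = [t for t in strials if t.first_sniff_ms >= boundary]
        try:
            ff, fs = fit_psychometric(fast), fit_psychometric(slow)
        except (ValueError, RuntimeError):
            flags.append(f"session {sid!r} dropped: unfittable half")
            continue
        rows.append({"session_id": sid, "boundary_ms": boundary,
                     "d_mu": ff.mu - fs.mu, "d_sigma": ff.sigma - fs.sigma,
                     "d_gamma": ff.gamma - fs.gamma,
                     "n_fast": len(fast), "n_slow": len(slow)})
    per_session = pd.DataFrame(rows)
    p_values = {}
    for name in ("d_mu", "d_sigma", "d_gamma"):
        if per_session.empty:
            p_values[name] = float("nan")
            continue
        d = per_session[name].to_numpy()
        if np.allclose(d, 0.0) or d.size < 2:
            p_values[name] = 1.0 if np.allclose(d, 0.0) else float("nan")
        else:
            p_values[name] = float(wilcoxon(d).pvalue)
    if len(rows) < 6:
        flags.append("low_power")
    return SplitComparison(per_session=per_session, p_values=p_values,
                           boundary_rule=split_rule, flags=flags)
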