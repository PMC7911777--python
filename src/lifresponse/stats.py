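"""Empirical spike statistics: ensemble averages, spontaneous correlations,
response traces and the d^2 comparison metric.

Averaging follows the trial-ensemble scheme: stimulus-evoked averages pool
over trials only (the perturbed process is non-stationary, so ergodic time
averaging is not available), while spontaneous averages additionally pool
over anchor times (stationarity after burn-in).  Every estimate carries a
central-limit standard error; tests use 3-sigma bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResponseTrace",
    "ensemble_average",
    "stationary_average",
    "spontaneous_correlation",
    "empirical_response",
    "d2_distance",
]


@dataclass
class ResponseTrace:
    """Time course ``delta f(n)`` of an observable's average shift."""

    times: np.ndarray
    values: np.ndarray
    stderr: np.ndarray | None = None
    method: str = "empirical"        # empirical | order1 | hc1 | exact
    observable: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)

    def restrict(self, lo: int, hi: int) -> "ResponseTrace":
        """Restriction to anchor times in ``[lo, hi]``."""
        mask = (self.times >= lo) & (self.times <= hi)
        return ResponseTrace(self.times[mask], self.values[mask],
                             None if self.stderr is None else self.stderr[mask],
                             self.method, self.observable, dict(self.meta))


def _same_params(a, b) -> bool:
    return a is b or (
        a.n_neurons == b.n_neurons
        and np.array_equal(a.weights, b.weights)
        and (a.gamma, a.theta, a.i0, a.sigma_b)
        == (b.gamma, b.theta, b.i0, b.sigma_b)
    )


def _check_nonempty(ensemble) -> None:
    if ensemble.n_trials < 1:
        raise ValueError("empty ensemble")


def ensemble_average(f, ensemble, n: int):
    """Trial average ``(1/M) sum_m f(n, omega^(m))`` and its standard error."""
    _check_nonempty(ensemble)
    vals = np.asarray(f.eval_ensemble(ensemble, [n]), dtype=float)[:, 0]
    m = vals.size
    se = vals.std(ddof=1) / np.sqrt(m) if m > 1 else 0.0
    return float(vals.mean()), float(se)


def _anchor_times(f, ensemble, window=None) -> np.ndarray:
    first, last = ensemble.analysis_window()
    if window is not None:
        first, last = window
    lo = max(first, ensemble.n_min + f.max_lag)
    if lo > last:
        raise ValueError("analysis window too short for the observable's range")
    return np.arange(lo, last + 1)


def stationary_average(f, ensemble, window=None):
    """Spontaneous mean of ``f``, pooled over trials and anchor times.

    The standard error treats trials (not time bins) as the independent
    unit, so autocorrelation within a trial does not bias it downward.
    """
    _check_nonempty(ensemble)
    times = _anchor_times(f, ensemble, window)
    vals = np.asarray(f.eval_ensemble(ensemble, times), dtype=float)
    per_trial = vals.mean(axis=1)
    m = per_trial.size
    se = per_trial.std(ddof=1) / np.sqrt(m) if m > 1 else 0.0
    return float(vals.mean()), float(se)


def spontaneous_correlation(f, g, lag: int, ensemble, window=None):
    """Centred stationary correlation ``C[f(t + lag), g(t)]``.

    Estimated as ``E[f(t+lag) g(t)] - E[f] E[g]`` with the expectation
    pooled over trials and all valid anchor times ``t`` (stationarity of
    the spontaneous measure).  Returns ``(value, stderr)`` with the error
    from the across-trial spread of per-trial estimates.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    _check_nonempty(ensemble)
    first, last = ensemble.analysis_window()
    if window is not None:
        first, last = window
    lo = max(first, ensemble.n_min + g.max_lag, ensemble.n_min + f.max_lag - lag)
    hi = last - lag
    if hi < lo:
        raise ValueError(f"window too short for lag {lag}")
    t = np.arange(lo, hi + 1)
    fv = np.asarray(f.eval_ensemble(ensemble, t + lag), dtype=float)
    gv = np.asarray(g.eval_ensemble(ensemble, t), dtype=float)
    fbar, gbar = fv.mean(), gv.mean()
    per_trial = ((fv - fbar) * (gv - gbar)).mean(axis=1)
    m = per_trial.size
    se = per_trial.std(ddof=1) / np.sqrt(m) if m > 1 else 0.0
    return float(per_trial.mean()), float(se)


def empirical_response(f, spont_ensemble, stim_ensemble, window=None) -> ResponseTrace:
    """Empirical shift ``delta mu_f(n)`` = stimulus-evoked minus spontaneous.

    The spontaneous term is the stationary time-and-trial pooled average;
    the evoked term is a per-time trial average.  The trace is compatible
    with zero before the stimulus onset (within CLT bands).
    """
    if not _same_params(spont_ensemble.params, stim_ensemble.params):
        raise ValueError("ensembles must share network parameters")
    if spont_ensemble.stimulus is not None:
        raise ValueError("the spontaneous ensemble must have no stimulus")
    base, base_se = stationary_average(f, spont_ensemble)
    times = _anchor_times(f, stim_ensemble, window)
    vals = np.asarray(f.eval_ensemble(stim_ensemble, times), dtype=float)
    m = vals.shape[0]
    means = vals.mean(axis=0)
    ses = vals.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros_like(means)
    label = getattr(f, "name", repr(f))
    return ResponseTrace(times, means - base, np.sqrt(ses**2 + base_se**2),
                         method="empirical", observable=label,
                         meta={"baseline": base})


def d2_distance(trace_a: ResponseTrace, trace_b: ResponseTrace) -> float:
    """Unnormalized squared distance ``sum_n (a(n) - b(n))^2``.

    As printed: no square root and no normalization, so the value scales
    with the response amplitude.  Symmetric, non-negative, zero iff the
    traces coincide on their (required common) window.
    """
    if trace_a.times.shape != trace_b.times.shape or \
            np.any(trace_a.times != trace_b.times):
        raise ValueError("traces must share the same time window")
    return float(np.sum((trace_a.values - trace_b.values) ** 2))
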