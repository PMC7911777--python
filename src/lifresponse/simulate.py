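"""Spike-raster generation: single trials and seeded trial ensembles.

Each step rebuilds the voltage from the spike history: the noise-free
mean ``Vbar_k`` follows the reset recursion ``Vbar(n+1) = gamma Vbar(n)
(1 - omega(n)) + sum_j W omega_j(n) + I0 + S(n)`` and, conditioned on the
history, the voltage is Gaussian with that mean and the integrated-noise
std ``sigma_k``; a spike occurs when ``Vbar + sigma * xi >= theta`` with
a fresh standard normal ``xi``.  Sampling the integrated noise in
distribution (rather than carrying a noisy voltage across steps, which
would condition the sub-threshold noise path on the spike history) makes
the one-step transition probabilities exactly the product of Gaussian
tails of the core model, for every leak rate.

Time runs on the post-burn-in clock: burn-in steps occupy times
``-burn_in .. -1`` (discarded from all averages), analysis steps ``0 ..
T-1``; the stimulus is defined on the analysis window and is identically
zero before its onset ``t0`` (hence throughout burn-in).

Ensembles are reproducible: trial ``m`` uses the ``m``-th child of
``numpy.random.SeedSequence(master_seed)``, so the same master seed yields
bit-identical rasters and an ensemble of size 1 equals a single trial run
with the corresponding child seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import NetworkParameters, SpikeRaster

__all__ = [
    "TrialEnsemble",
    "SimulationError",
    "simulate_trial",
    "simulate_ensemble",
    "estimate_firing_rates",
    "threshold_state",
]

_TRIAL_CHUNK = 20_000  # trials simulated per vectorized block (memory bound)


class SimulationError(RuntimeError):
    """Raised when the voltage becomes non-finite (parameter blow-up)."""


@dataclass
class TrialEnsemble:
    """``M`` seeded rasters sharing parameters; carrier of empirical averages.

    ``spikes[m, k, col]`` is ``omega_k(n)`` of trial ``m`` at time
    ``n = n_min + col``.
    """

    spikes: np.ndarray          # (M, N, L) uint8
    params: NetworkParameters
    stimulus: object            # StimulusField or None
    burn_in: int
    t_steps: int
    master_seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[2]

    @property
    def n_min(self) -> int:
        return -self.burn_in

    @property
    def n_max(self) -> int:
        return self.t_steps - 1

    def trial_seed(self, m: int) -> np.random.SeedSequence:
        """The child seed sequence that generated trial ``m``."""
        if self.master_seed is None:
            raise ValueError("ensemble was built without a master seed")
        return np.random.SeedSequence(self.master_seed).spawn(self.n_trials)[m]

    def raster(self, m: int) -> SpikeRaster:
        return SpikeRaster(self.spikes[m].copy(), n_min=self.n_min)

    def analysis_window(self):
        """(first, last) time of the post-burn-in window."""
        return 0, self.t_steps - 1


def _stim_column(stimulus, n: int, n_neurons: int) -> float | np.ndarray:
    if stimulus is None:
        return 0.0
    return stimulus.column(n)


def _run_dynamics(params: NetworkParameters, stimulus, t_steps: int, burn_in: int,
                  noise: np.ndarray, record_voltage: bool = False):
    """Vectorized threshold/reset recursion over a batch of trials.

    ``noise[m, col, k]`` are the standard Gaussian draws; returns spikes
    ``(M, N, L)`` and, optionally, the (noisy) voltage traces.
    """
    m_trials, length, n = noise.shape
    w_t = params.weights.T
    g = params.gamma
    vbar = np.zeros((m_trials, n))   # noise-free voltage mean
    s2 = np.zeros((m_trials, n))     # integrated-noise variance
    spikes = np.zeros((m_trials, n, length), dtype=np.uint8)
    volts = np.zeros((m_trials, n, length)) if record_voltage else None
    for col, t in enumerate(range(-burn_in, t_steps)):
        if not np.all(np.isfinite(vbar)):
            raise SimulationError(f"non-finite voltage at time step {t}")
        v = vbar + np.sqrt(s2) * noise[:, col, :]
        if record_voltage:
            volts[:, :, col] = v
        omega = v >= params.theta
        spikes[:, :, col] = omega
        keep = ~omega
        vbar = g * vbar * keep + omega @ w_t + params.i0 \
            + _stim_column(stimulus, t, n)
        s2 = g * g * s2 * keep + params.sigma_b**2
    return spikes, volts


def simulate_trial(params: NetworkParameters, stimulus, t_steps: int, burn_in: int,
                   seed, record_voltage: bool = False):
    """Simulate one trial; same seed gives a bit-identical raster.

    Returns a :class:`SpikeRaster` (with ``n_min = -burn_in``), or a
    ``(raster, voltage)`` pair when ``record_voltage`` is set.
    """
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((1, burn_in + t_steps, params.n_neurons))
    spikes, volts = _run_dynamics(params, stimulus, t_steps, burn_in, noise,
                                  record_voltage)
    raster = SpikeRaster(spikes[0], n_min=-burn_in)
    if record_voltage:
        return raster, volts[0]
    return raster


def simulate_ensemble(params: NetworkParameters, stimulus, t_steps: int,
                      burn_in: int, m_trials: int, master_seed: int) -> TrialEnsemble:
    """Simulate ``M`` independent trials with deterministically derived seeds."""
    if m_trials < 1:
        raise ValueError("m_trials must be >= 1")
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(m_trials)
    length = burn_in + t_steps
    n = params.n_neurons
    spikes = np.empty((m_trials, n, length), dtype=np.uint8)
    for lo in range(0, m_trials, _TRIAL_CHUNK):
        hi = min(lo + _TRIAL_CHUNK, m_trials)
        noise = np.empty((hi - lo, length, n))
        for i, ss in enumerate(children[lo:hi]):
            noise[i] = np.random.default_rng(ss).standard_normal((length, n))
        try:
            block, _ = _run_dynamics(params, stimulus, t_steps, burn_in, noise)
        except SimulationError as err:
            raise SimulationError(f"trials {lo}..{hi - 1}: {err}") from err
        spikes[lo:hi] = block
    return TrialEnsemble(spikes=spikes, params=params, stimulus=stimulus,
                         burn_in=burn_in, t_steps=t_steps, master_seed=master_seed)


def threshold_state(params: NetworkParameters, ensemble: TrialEnsemble,
                    stimulus=None):
    """Recompute ``X_k(n)`` and ``sigma_k(n)`` for every trial/neuron/time.

    Replays the deterministic (noise-free) part of the voltage recursion
    with the recorded reset times, giving the normalized threshold
    distance whose Gaussian tail is the spike probability at ``n + 1``.
    ``stimulus=None`` yields the spontaneous ``X^sp`` even on a
    stimulus-driven raster (used for the validity diagnostics).

    Returns ``(x, sigma)``, each of shape (M, N, L).
    """
    m_trials, n, length = ensemble.spikes.shape
    w_t = params.weights.T
    g = params.gamma
    vbar = np.zeros((m_trials, n))
    s2 = np.zeros((m_trials, n))
    x = np.empty((m_trials, n, length))
    sig = np.empty((m_trials, n, length))
    for col, t in enumerate(range(ensemble.n_min, ensemble.t_steps)):
        omega = ensemble.spikes[:, :, col]
        keep = 1.0 - omega
        vbar = g * vbar * keep + omega @ w_t + params.i0 \
            + _stim_column(stimulus, t, n)
        s2 = g * g * s2 * keep + params.sigma_b**2
        sig[:, :, col] = np.sqrt(s2)
        x[:, :, col] = (params.theta - vbar) / sig[:, :, col]
    return x, sig


def estimate_firing_rates(ensemble: TrialEnsemble, horizon_cap: int = 100):
    """Per-neuron spontaneous rates and mean-field horizons.

    ``nu_k`` is the fraction of post-burn-in (trial, time) bins with a
    spike; ``h_k = round(1 / nu_k)`` clipped to ``[1, horizon_cap]`` is
    the mean inter-spike interval used as the voltage-integration horizon
    in the linear-response predictors.

    Returns ``(nu, horizons)``.
    """
    first, last = ensemble.analysis_window()
    cols = slice(first - ensemble.n_min, last - ensemble.n_min + 1)
    nu = ensemble.spikes[:, :, cols].mean(axis=(0, 2))
    horizons = np.empty(ensemble.n_neurons, dtype=int)
    for k, r in enumerate(nu):
        if r <= 0.0:
            warnings.warn(
                f"neuron {k} never spiked; horizon set to cap {horizon_cap}",
                stacklevel=2,
            )
            horizons[k] = horizon_cap
        else:
            horizons[k] = int(np.clip(round(1.0 / r), 1, horizon_cap))
    return nu, horizons
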