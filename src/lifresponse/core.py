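"""Discrete-time stochastic leaky integrate-and-fire network: model core.

The sub-threshold voltage of neuron ``k`` follows the step recursion

    V_k(n+1) = gamma * V_k(n) * (1 - omega_k(n))
               + sum_j W_kj omega_j(n) + I0 + S_k(n) + sigma_B * xi_k(n),

with a spike ``omega_k(n) = 1`` whenever ``V_k(n) >= theta``, followed by an
instantaneous reset to zero.  Conditioned on the spike history, the
noise-free voltage integrates geometrically from the last reset time, and
the probability that neuron ``k`` fires at time ``n`` is the Gaussian
upper-tail probability ``Pi(X_k(n-1))`` of the normalized distance to
threshold ``X_k``.  The log of the one-step transition probability is the
normalized Gibbs potential ``phi(n, omega)`` of the spike process, a chain
with unbounded memory whose influence decays like ``gamma^m``.

This module holds the exact, scalar-level definitions (used by the tests
and the Markov oracle); vectorized counterparts for large ensembles live in
:mod:`lifresponse.simulate` and :mod:`lifresponse.response`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "NetworkParameters",
    "SpikeRaster",
    "VoltageComponents",
    "gaussian_tail",
    "log_gaussian_tail",
    "tail_log_derivatives",
    "last_reset_time",
    "integrated_voltage",
    "integrated_noise_std",
    "x_threshold_distance",
    "transition_probability",
    "potential_phi",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class NetworkParameters:
    """All constants of the network model.

    Parameters
    ----------
    n_neurons:
        Number of neurons ``N >= 1``.
    weights:
        ``N x N`` synaptic matrix; ``weights[k, j]`` is the weight from
        presynaptic neuron ``j`` onto postsynaptic neuron ``k``
        (dimensionless; positive = excitatory).
    gamma:
        Leak rate, ``0 <= gamma < 1``; per-step voltage retention factor.
    theta:
        Firing threshold (voltage units).
    i0:
        Constant input per step, fixing the baseline activity.
    sigma_b:
        Amplitude of the additive standard Gaussian noise, ``> 0``.
    """

    n_neurons: int
    weights: np.ndarray
    gamma: float
    theta: float
    i0: float
    sigma_b: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if w.shape != (self.n_neurons, self.n_neurons):
            raise ValueError(
                f"weights must be ({self.n_neurons}, {self.n_neurons}), got {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        if not (self.sigma_b > 0.0):
            raise ValueError("sigma_b must be > 0")
        object.__setattr__(self, "weights", w)

    @property
    def tau(self) -> float:
        """Integration time constant ``1 / (1 - gamma)`` (steps)."""
        return 1.0 / (1.0 - self.gamma)

    @property
    def tau_gamma(self) -> float:
        """Memory decay time ``-1 / log(gamma)`` (steps); 0 for gamma=0."""
        if self.gamma == 0.0:
            return 0.0
        return -1.0 / math.log(self.gamma)

    @property
    def sigma_infinity(self) -> float:
        """Stationary noise std ``sigma_B / sqrt(1 - gamma^2)``."""
        return self.sigma_b / math.sqrt(1.0 - self.gamma**2)


@dataclass
class SpikeRaster:
    """Binary spike array for one trial, neurons x time.

    ``spikes[k, n - n_min]`` is ``omega_k(n)`` for ``n`` in
    ``[n_min, n_min + L - 1]``.  ``n_min`` is the history start; in
    ensemble runs burn-in steps occupy negative times so that time 0 is the
    first post-burn-in step.
    """

    spikes: np.ndarray
    n_min: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.spikes)
        if s.ndim != 2:
            raise ValueError("spikes must be a 2-D (neurons x time) array")
        if not np.isin(s, (0, 1)).all():
            raise ValueError("spike entries must be exactly 0 or 1")
        self.spikes = s.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_max(self) -> int:
        return self.n_min + self.spikes.shape[1] - 1

    def _col(self, n: int) -> int:
        if not (self.n_min <= n <= self.n_max):
            raise IndexError(f"time {n} outside raster range [{self.n_min}, {self.n_max}]")
        return n - self.n_min

    def value(self, k: int, n: int) -> int:
        """``omega_k(n)``."""
        return int(self.spikes[k, self._col(n)])

    def pattern(self, n: int) -> np.ndarray:
        """The spiking pattern ``omega(n)`` as a length-N 0/1 array."""
        return self.spikes[:, self._col(n)].copy()


@dataclass
class VoltageComponents:
    """Decomposition of the conditional voltage mean and noise scale.

    ``v_syn + v_i + v_s`` is the noise-free conditional mean of
    ``V_k(n+1)`` given the spike history through ``n``; the integrated
    noise is Gaussian with mean 0 and standard deviation ``noise_std``.
    """

    v_syn: float
    v_i: float
    v_s: float
    noise_mean: float = 0.0
    noise_std: float = field(default=0.0)

    @property
    def mean(self) -> float:
        return self.v_syn + self.v_i + self.v_s


# ---------------------------------------------------------------------------
# The sigmoid Pi and its log-derivatives
# ---------------------------------------------------------------------------

def gaussian_tail(x):
    """Standard Gaussian upper-tail probability ``Pi(x) = P(Z > x)``.

    Strictly decreasing sigmoid from 1 (x -> -inf) to 0 (x -> +inf);
    ``Pi(0) = 1/2`` and ``Pi(x) + Pi(-x) = 1``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("gaussian_tail requires finite input")
    out = ndtr(-x)
    return float(out) if out.ndim == 0 else out


def log_gaussian_tail(x):
    """``log Pi(x)``, evaluated in log space (no underflow)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_gaussian_tail requires finite input")
    out = log_ndtr(-x)
    return float(out) if out.ndim == 0 else out


def tail_log_derivatives(order: int, x):
    """Derivatives ``a(u), b(u)`` of ``log Pi`` and ``log(1 - Pi)``.

    ``a(1)(x) = Pi'(x)/Pi(x) < 0`` and ``b(1)(x) = -Pi'(x)/(1-Pi(x)) > 0``.
    Second derivatives follow from the hazard-rate identities
    ``a(2) = -a(1) (x + a(1))`` and ``b(2) = -b(1) (x + b(1))``.

    Parameters
    ----------
    order:
        1 or 2.
    x:
        Scalar or array of finite reals.

    Returns
    -------
    (a, b):
        The pair of derivative values, same shape as ``x``.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = np.asarray(x, dtype=float)
    log_pdf = -0.5 * x**2 - _LOG_SQRT_2PI
    a1 = -np.exp(log_pdf - log_ndtr(-x))   # Pi' / Pi
    b1 = np.exp(log_pdf - log_ndtr(x))     # -Pi' / (1 - Pi)
    if order == 1:
        a, b = a1, b1
    else:
        a, b = -a1 * (x + a1), -b1 * (x + b1)
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


# ---------------------------------------------------------------------------
# Voltage integration from the last reset
# ---------------------------------------------------------------------------

def last_reset_time(raster: SpikeRaster, k: int, n: int) -> int:
    """Most recent time ``l <= n`` with ``omega_k(l) = 1``.

    Returns the sentinel ``n_min - 1`` when neuron ``k`` never spiked up to
    ``n`` (interpreted as "integrate from the history start").
    """
    col = raster._col(n)
    row = raster.spikes[k, : col + 1]
    nz = np.flatnonzero(row)
    if nz.size == 0:
        return raster.n_min - 1
    return raster.n_min + int(nz[-1])


def _integration_start(raster: SpikeRaster, k: int, n: int) -> int:
    return max(last_reset_time(raster, k, n), raster.n_min)


def _stimulus_value(stimulus, k: int, n: int) -> float:
    if stimulus is None:
        return 0.0
    return float(stimulus.value(k, n))


def integrated_voltage(params: NetworkParameters, raster: SpikeRaster,
                       stimulus, k: int, n: int) -> VoltageComponents:
    """Conditional law of ``V_k(n+1)`` given the spike history through ``n``.

    Integrates the step recursion from the last reset time ``tau_k(n)``
    (or the history start): synaptic term ``sum_j W_kj eta_kj`` with
    ``eta_kj = sum_l gamma^(n-l) omega_j(l)``, constant-input term
    ``I0 (1 - gamma^(n+1-tau)) / (1 - gamma)``, stimulus term, and the
    integrated-noise standard deviation.
    """
    l0 = _integration_start(raster, k, n)
    g = params.gamma
    steps = n - l0 + 1
    pw = g ** np.arange(steps - 1, -1, -1)          # gamma^(n-l), l = l0..n
    block = raster.spikes[:, l0 - raster.n_min: n - raster.n_min + 1].astype(float)
    v_syn = float(params.weights[k] @ (block @ pw))
    if g == 0.0:
        v_i = params.i0
    else:
        v_i = params.i0 * (1.0 - g**steps) / (1.0 - g)
    if stimulus is None:
        v_s = 0.0
    else:
        v_s = float(sum(pw[i] * _stimulus_value(stimulus, k, l0 + i) for i in range(steps)))
    std = params.sigma_b * math.sqrt((1.0 - g ** (2 * steps)) / (1.0 - g**2))
    return VoltageComponents(v_syn=v_syn, v_i=v_i, v_s=v_s, noise_std=std)


def integrated_noise_std(params: NetworkParameters, raster: SpikeRaster,
                         k: int, n: int) -> float:
    """Std of the noise integrated from the last reset through time ``n``.

    ``sigma_k(n) = sigma_B sqrt((1 - gamma^(2 s)) / (1 - gamma^2))`` with
    ``s`` the number of steps since the last reset; increases with ``s``
    and converges to ``sigma_B / sqrt(1 - gamma^2)``.  The printed model
    variance omits the ``sigma_B^2`` factor; it is included here because
    this is the variance of the integrated noise term of the voltage.
    """
    l0 = _integration_start(raster, k, n)
    steps = n - l0 + 1
    g = params.gamma
    return params.sigma_b * math.sqrt((1.0 - g ** (2 * steps)) / (1.0 - g**2))


def x_threshold_distance(params: NetworkParameters, raster: SpikeRaster,
                         stimulus, k: int, n: int) -> float:
    """Normalized distance to threshold ``X_k(n)`` (history through ``n``).

    ``X_k(n) = (theta - Vbar_k) / sigma_k(n)`` with ``Vbar_k`` the
    noise-free conditional mean of ``V_k(n+1)``; the spike probability at
    ``n+1`` is ``Pi(X_k(n))``.  Splits as ``X_k = X_k^sp + delta X_k``
    with ``delta X_k = -V_k^S / sigma_k`` linear in the stimulus.
    """
    comps = integrated_voltage(params, raster, stimulus, k, n)
    return (params.theta - comps.mean) / comps.noise_std


def transition_probability(params: NetworkParameters, raster: SpikeRaster,
                           stimulus, pattern, n: int) -> float:
    """``P[omega(n) = pattern | spike history through n-1]``.

    Conditional independence across neurons: the product over ``k`` of
    ``Pi(X_k(n-1))`` for spikers and ``1 - Pi(X_k(n-1))`` for the rest.
    Strictly inside (0, 1) for finite parameters; sums to 1 over the
    ``2^N`` patterns.
    """
    pattern = np.asarray(pattern)
    prob = 1.0
    for k in range(params.n_neurons):
        x = x_threshold_distance(params, raster, stimulus, k, n - 1)
        p = gaussian_tail(x)
        prob *= p if pattern[k] else (1.0 - p)
    return prob


def potential_phi(params: NetworkParameters, raster: SpikeRaster,
                  stimulus, n: int) -> float:
    """Normalized Gibbs potential ``phi(n, omega) = log P[omega(n) | past]``.

    Evaluated entirely in log space via ``log Pi`` and ``log(1 - Pi)``
    (= ``log Phi``), so no probability floor is needed; summed over a
    block, ``exp`` of the result is the block's conditional probability
    (chain rule).
    """
    total = 0.0
    for k in range(params.n_neurons):
        x = x_threshold_distance(params, raster, stimulus, k, n - 1)
        if raster.value(k, n):
            total += log_ndtr(-x)
        else:
            total += log_ndtr(x)
    return float(total)
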