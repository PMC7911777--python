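"""Linear response of spike observables to a weak stimulus.

The first-order change of an observable's average under a stimulus
switched on at ``t0`` is a sum of spontaneous correlation functions
between the observable and the first-order variation of the normalized
potential (a Kubo / fluctuation-dissipation relation).  For the discrete
LIF network this reduces to a convolution of the stimulus with a kernel
of spontaneous correlations:

* ``order1`` -- the full first-order kernel ``K[k, m] = C[f(m), zeta_k(0)]``
  where ``zeta_k`` is the per-neuron susceptibility built from the
  log-derivatives of the Gaussian tail;
* ``hc1`` -- the lowest-order Hammersley-Clifford truncation, which
  replaces ``zeta_k`` by ``gamma1 * omega_k / sigma_inf`` (a classical
  fluctuation-dissipation form using bare spike-variable correlations).

Both predictors are exactly linear in the stimulus amplitude and causal
(zero before ``t0 + 1``).  The memory of the kernel is truncated at depth
``D`` and the voltage-integration horizon is the mean-field value
``h_k = round(1 / nu_k)`` (the mean inter-spike interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (NetworkParameters, SpikeRaster, gaussian_tail,
                   integrated_noise_std, tail_log_derivatives,
                   x_threshold_distance)
from .simulate import TrialEnsemble, estimate_firing_rates, threshold_state
from .stats import ResponseTrace
from . import markov

__all__ = [
    "ResponseKernel",
    "derivative_a_b",
    "zeta",
    "zeta_series",
    "kernel_order1",
    "kernel_hc1",
    "kernel_order1_exact",
    "predict_order1",
    "predict_hc1",
    "general_response",
    "lif_delta_phi_order1",
    "validity_diagnostics",
]


@dataclass
class ResponseKernel:
    """``N x (D+1)`` correlation kernel with its convolution metadata."""

    kernel: np.ndarray           # (N, D+1); column m-1 holds lag m = 1..D+1
    nu: np.ndarray               # per-neuron spontaneous rates
    horizons: np.ndarray         # mean-field integration horizons h_k
    gamma: float
    depth: int
    method: str = "order1"       # order1 | hc1
    observable: str = ""
    scale: float = 1.0           # prefactor applied at prediction time
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth D must be >= 1")
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel entries must be finite")


def derivative_a_b(order: int, x):
    """Derivatives of ``log Pi`` and ``log(1 - Pi)`` (see core module).

    ``a(1) < 0 < b(1)`` everywhere and ``a(1)(0) = -b(1)(0) = -2/sqrt(2 pi)``.
    """
    return tail_log_derivatives(order, x)


# ---------------------------------------------------------------------------
# The susceptibility zeta
# ---------------------------------------------------------------------------

def zeta(params: NetworkParameters, raster: SpikeRaster, k: int, r: int) -> float:
    """Susceptibility ``zeta_k(r-1, omega)`` on a spontaneous raster.

    ``zeta_k = [omega_k(r) a1(X_k^sp(r-1)) + (1 - omega_k(r)) b1(X_k^sp(r-1))]
    / sigma_k(r-1)``: the derivative of the one-neuron potential with
    respect to a unit stimulus-induced shift of the threshold distance.
    """
    x_sp = x_threshold_distance(params, raster, None, k, r - 1)
    a1, b1 = tail_log_derivatives(1, x_sp)
    sig = integrated_noise_std(params, raster, k, r - 1)
    branch = a1 if raster.value(k, r) else b1
    return float(branch / sig)


def zeta_series(params: NetworkParameters, ensemble: TrialEnsemble) -> np.ndarray:
    """``zeta_k(t)`` for all trials/neurons/anchors, shape (M, N, L-1).

    Column ``c`` anchors at time ``t = n_min + c`` (the spike outcome is
    read at ``t + 1``, so the last raster column has no anchor).
    """
    x, sig = threshold_state(params, ensemble, stimulus=None)
    a1, b1 = tail_log_derivatives(1, x[:, :, :-1])
    omega_next = ensemble.spikes[:, :, 1:]
    return np.where(omega_next == 1, a1, b1) / sig[:, :, :-1]


# ---------------------------------------------------------------------------
# Kernel estimation
# ---------------------------------------------------------------------------

def _kernel_anchors(ensemble: TrialEnsemble, depth: int) -> np.ndarray:
    lo, hi = ensemble.analysis_window()
    t_hi = hi - (depth + 1)
    if t_hi < lo:
        raise ValueError("analysis window too short for the kernel depth")
    return np.arange(lo, t_hi + 1)


def _estimate_kernel(f, ensemble: TrialEnsemble, depth: int,
                     susceptibility: np.ndarray) -> np.ndarray:
    """Pool trials and anchor times for ``K[k, m] = C[f(t+m), s_k(t)]``."""
    t = _kernel_anchors(ensemble, depth)
    cols = t - ensemble.n_min
    s = susceptibility[:, :, cols]                      # (M, N, Tw)
    s_mean = s.mean(axis=(0, 2))
    kernel = np.empty((ensemble.n_neurons, depth + 1))
    for m in range(1, depth + 2):
        fv = np.asarray(f.eval_ensemble(ensemble, t + m), dtype=float)
        f_mean = fv.mean()
        kernel[:, m - 1] = np.einsum("mt,mkt->k", fv, s) / (fv.shape[0] * fv.shape[1]) \
            - f_mean * s_mean
    return kernel


def kernel_order1(f, spont_ensemble: TrialEnsemble, depth: int,
                  horizon_cap: int | None = None) -> ResponseKernel:
    """First-order response kernel from a spontaneous ensemble.

    Entry ``(k, m)`` is the stationary correlation between ``f`` anchored
    ``m`` steps ahead and ``zeta_k`` anchored at 0, for ``m = 1..D+1``;
    spontaneous rates and mean-field horizons are attached for the
    stimulus convolution.
    """
    if spont_ensemble.stimulus is not None:
        raise ValueError("kernel estimation requires a spontaneous ensemble")
    params = spont_ensemble.params
    cap = horizon_cap if horizon_cap is not None else 10 * depth
    zs = zeta_series(params, spont_ensemble)
    kernel = _estimate_kernel(f, spont_ensemble, depth, zs)
    nu, horizons = estimate_firing_rates(spont_ensemble, horizon_cap=cap)
    return ResponseKernel(kernel=kernel, nu=nu, horizons=horizons,
                          gamma=params.gamma, depth=depth, method="order1",
                          observable=getattr(f, "name", repr(f)))


def kernel_hc1(f, spont_ensemble: TrialEnsemble, depth: int,
               horizon_cap: int | None = None) -> ResponseKernel:
    """Lowest-order Hammersley-Clifford kernel: bare spike correlations.

    ``K[k, m] = C[f(m), omega_k]`` with the spike variable at the same
    anchor as ``zeta_k`` (degree-1 truncation of the susceptibility); the
    prefactor ``gamma1 / sigma_inf`` is stored as the kernel scale, where
    ``gamma1 = a1(thetaL) - b1(thetaL)`` at the effective threshold
    ``thetaL = (theta - I0/(1-gamma)) / sigma_inf``.
    """
    if spont_ensemble.stimulus is not None:
        raise ValueError("kernel estimation requires a spontaneous ensemble")
    params = spont_ensemble.params
    cap = horizon_cap if horizon_cap is not None else 10 * depth
    omega_next = spont_ensemble.spikes[:, :, 1:].astype(float)
    kernel = _estimate_kernel(f, spont_ensemble, depth, omega_next)
    nu, horizons = estimate_firing_rates(spont_ensemble, horizon_cap=cap)
    sigma_inf = params.sigma_infinity
    theta_l = (params.theta - params.i0 / (1.0 - params.gamma)) / sigma_inf
    a1, b1 = tail_log_derivatives(1, theta_l)
    return ResponseKernel(kernel=kernel, nu=nu, horizons=horizons,
                          gamma=params.gamma, depth=depth, method="hc1",
                          observable=getattr(f, "name", repr(f)),
                          scale=(a1 - b1) / sigma_inf,
                          meta={"theta_l": theta_l, "gamma1": a1 - b1})


def kernel_order1_exact(params: NetworkParameters, chain_depth: int, f,
                        depth: int, horizon_cap: int | None = None) -> ResponseKernel:
    """Oracle-supplied kernel: exact correlations on the depth-D block chain.

    Ground truth for the empirical estimator on small networks (and the
    noise-free kernel for the O(A^2) first-order-correctness check).
    """
    chain = markov.build_block_chain(params, chain_depth)
    p_inv = markov.invariant_distribution(chain)
    kernel = markov.exact_kernel_matrix(chain, p_inv, f, depth)
    nu = markov.exact_firing_rates(chain, p_inv)
    cap = horizon_cap if horizon_cap is not None else 10 * depth
    horizons = np.clip(np.round(1.0 / np.maximum(nu, 1e-12)), 1, cap).astype(int)
    return ResponseKernel(kernel=kernel, nu=nu, horizons=horizons,
                          gamma=params.gamma, depth=depth, method="order1",
                          observable=getattr(f, "name", repr(f)),
                          meta={"source": "markov_oracle"})


# ---------------------------------------------------------------------------
# Prediction (stimulus convolution)
# ---------------------------------------------------------------------------

def _predict(kernel: ResponseKernel, stimulus, t_steps: int) -> np.ndarray:
    """``-scale * sum_k sum_m sum_l gamma^l K[k,m] S_k(n - m - l)``."""
    g = kernel.gamma
    values = np.zeros(t_steps)
    for k in range(kernel.kernel.shape[0]):
        h_k = int(kernel.horizons[k])
        decay = np.power(g, np.arange(h_k + 1))
        kappa = np.zeros(kernel.depth + 1 + h_k + 1)
        for m in range(1, kernel.depth + 2):
            kappa[m: m + h_k + 1] += kernel.kernel[k, m - 1] * decay
        s_row = np.array([stimulus.value(k, n) for n in range(t_steps)])
        values -= kernel.scale * np.convolve(s_row, kappa)[:t_steps]
    return values


def predict_order1(kernel: ResponseKernel, stimulus, t_steps: int) -> ResponseTrace:
    """First-order predicted response trace on ``n = 0..t_steps-1``.

    Exactly linear in the stimulus amplitude and exactly zero before
    ``t0 + 1`` (the convolution only reaches stimulus values at
    ``n - m - l <= n - 1``).
    """
    values = _predict(kernel, stimulus, t_steps)
    return ResponseTrace(np.arange(t_steps), values, None, method=kernel.method,
                         observable=kernel.observable,
                         meta={"depth": kernel.depth})


def predict_hc1(f, spont_ensemble: TrialEnsemble, params: NetworkParameters,
                stimulus, depth: int) -> ResponseTrace:
    """Fluctuation-dissipation style prediction from bare spike correlations."""
    kern = kernel_hc1(f, spont_ensemble, depth)
    trace = predict_order1(kern, stimulus, stimulus.n_steps)
    trace.method = "hc1"
    return trace


# ---------------------------------------------------------------------------
# Model-agnostic first-order response (the general correlation series)
# ---------------------------------------------------------------------------

def general_response(f, delta_phi_fn, spont_ensemble: TrialEnsemble,
                     window, depth: int) -> ResponseTrace:
    """``delta f(n) = sum_{r=n-D}^{n} C_sp[f(n), delta phi(r)]``.

    ``delta_phi_fn(r, ensemble)`` must return the per-trial values of the
    potential variation ``delta phi(r, omega)`` on the spontaneous
    ensemble; correlations are trial averages (the explicit time
    dependence of ``delta phi`` forbids time pooling).
    """
    lo, hi = window
    first, last = spont_ensemble.analysis_window()
    if lo - depth - 1 < spont_ensemble.n_min or hi > last:
        raise ValueError("window (with depth margin) exceeds the ensemble range")
    times = np.arange(lo, hi + 1)
    values = np.zeros(times.size)
    cache: dict[int, np.ndarray] = {}
    for i, n in enumerate(times):
        fv = np.asarray(f.eval_ensemble(spont_ensemble, [n]), dtype=float)[:, 0]
        f_mean = fv.mean()
        total = 0.0
        for r in range(n - depth, n + 1):
            if r not in cache:
                cache[r] = np.asarray(delta_phi_fn(r, spont_ensemble), dtype=float)
            dp = cache[r]
            total += float((fv * dp).mean() - f_mean * dp.mean())
        values[i] = total
    return ResponseTrace(times, values, None, method="order1",
                         observable=getattr(f, "name", repr(f)),
                         meta={"path": "general_response", "depth": depth})


def lif_delta_phi_order1(params: NetworkParameters, spont_ensemble: TrialEnsemble,
                         stimulus, horizons: np.ndarray):
    """First-order potential variation of the LIF model, as a closure.

    ``delta phi(1)(r, omega) = -sum_k zeta_k(r-1, omega) *
    sum_{l=r-1-h_k}^{r-1} gamma^(r-1-l) S_k(l)`` (mean-field horizon).
    """
    zs = zeta_series(params, spont_ensemble)
    g = params.gamma

    def delta_phi(r: int, ensemble: TrialEnsemble) -> np.ndarray:
        col = (r - 1) - ensemble.n_min
        if not (0 <= col < zs.shape[2]):
            raise IndexError(f"anchor {r} outside the ensemble range")
        total = np.zeros(ensemble.n_trials)
        for k in range(params.n_neurons):
            drive = sum(g**j * stimulus.value(k, r - 1 - j)
                        for j in range(int(horizons[k]) + 1))
            if drive != 0.0:
                total -= zs[:, k, col] * drive
        return total

    return delta_phi


# ---------------------------------------------------------------------------
# Validity diagnostics
# ---------------------------------------------------------------------------

def validity_diagnostics(params: NetworkParameters, ensemble: TrialEnsemble,
                         stimulus, eps: float = 0.01, slack: float = 0.1) -> dict:
    """Where does the first-order expansion hold on this ensemble?

    Reports (i) the fraction of (trial, neuron, time) bins whose spike
    probability ``Pi(X)`` saturates outside ``[eps, 1-eps]`` and (ii) the
    fraction violating the second-order smallness condition
    ``|delta X| <= slack * 2 |X^sp + a1(X^sp)|`` after the onset.  Both
    fractions grow with the stimulus amplitude; a zero stimulus gives no
    smallness violations.
    """
    x_stim, _ = threshold_state(params, ensemble, stimulus)
    x_sp, _ = threshold_state(params, ensemble, None)
    lo_col = -ensemble.n_min  # post-burn-in columns
    x_win = x_stim[:, :, lo_col:]
    pi = gaussian_tail(x_win.ravel()).reshape(x_win.shape)
    saturation = float(np.mean((pi < eps) | (pi > 1.0 - eps)))
    t0 = stimulus.t0 if stimulus is not None else ensemble.t_steps
    c0 = t0 - ensemble.n_min
    delta_x = (x_stim - x_sp)[:, :, c0:]
    x_ref = x_sp[:, :, c0:]
    a1, b1 = tail_log_derivatives(1, x_ref)
    # the condition must hold for both log-expansion branches; the binding
    # bound is the smaller one, maximal near X = 0 (threshold-poised)
    bound = 2.0 * np.minimum(np.abs(x_ref + a1), np.abs(x_ref + b1))
    violation = float(np.mean(np.abs(delta_x) > slack * bound)) if delta_x.size else 0.0
    return {
        "eps": eps,
        "slack": slack,
        "saturation_fraction": saturation,
        "smallness_violation_fraction": violation,
        "max_abs_delta_x": float(np.abs(delta_x).max()) if delta_x.size else 0.0,
    }
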