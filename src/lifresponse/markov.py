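"""Exact small-network computations under a memory-D Markov truncation.

The spike process of the discrete LIF network has unbounded memory; on a
small network one obtains a finite Markov chain by truncating the memory
to depth ``D``: the state is the block of the last ``D`` spiking patterns,
and a neuron that has not spiked within the block integrates from the
block's first index (the truncation error is governed by ``gamma^D``; for
``gamma = 0`` and ``D >= 1`` the truncation is exact).  Transitions are
the model's product-of-Gaussian-tails probabilities evaluated on the
reconstructed history, nonzero exactly on the legal block overlaps.

Everything here is a ground-truth oracle for the stochastic estimators:
invariant measure by power iteration, exact expectations/correlations,
spectral gap, exact linear-response kernels, and exact non-stationary
propagation under a stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import NetworkParameters, gaussian_tail, tail_log_derivatives
from .stats import ResponseTrace

__all__ = [
    "BlockChain",
    "build_block_chain",
    "invariant_distribution",
    "state_blocks",
    "monomial_state_values",
    "exact_expectation",
    "exact_correlation",
    "exact_firing_rates",
    "zeta_state_values",
    "exact_kernel_matrix",
    "spectral_gap",
    "propagate_with_stimulus",
]

_CAPACITY_BITS = 16


@dataclass
class BlockChain:
    """Markov chain over depth-D spike blocks.

    States are integers encoding blocks of ``D`` patterns (bit
    ``i + N*d``, position ``d = 0`` oldest, ``d = D-1`` newest); the
    row-stochastic matrix is sparse with ``2^N`` legal successors per
    state.
    """

    params: NetworkParameters
    depth: int
    matrix: sp.csr_matrix

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


def _check_capacity(params: NetworkParameters, depth: int) -> None:
    n_bits = params.n_neurons * depth
    if n_bits > _CAPACITY_BITS:
        raise ValueError(
            f"N*D = {n_bits} bits exceeds the oracle capacity ({_CAPACITY_BITS})"
        )
    if params.n_neurons * (depth + 1) > 24:
        raise ValueError("transition table 2^(N(D+1)) too large for the oracle")


def state_blocks(n_neurons: int, depth: int) -> np.ndarray:
    """Decode all states: array (n_states, D, N), position 0 = oldest."""
    n_states = 1 << (n_neurons * depth)
    states = np.arange(n_states, dtype=np.int64)
    bits = (states[:, None] >> np.arange(n_neurons * depth)) & 1
    return bits.reshape(n_states, depth, n_neurons).astype(np.uint8)


def _conditional_stats(params: NetworkParameters, blocks: np.ndarray,
                       stim_block: np.ndarray | None, upto: int):
    """Noise-free mean voltage and noise std after integrating block rows
    ``0 .. upto-1`` from the (truncated) last reset.

    ``stim_block[k, d]`` holds the stimulus at the time of block position
    ``d``.  Returns ``(vbar, sigma)`` of shape (n_states, N).
    """
    g = params.gamma
    n = params.n_neurons
    n_states = blocks.shape[0]
    # last spike position of each neuron among rows < upto; 0 if none
    # (truncation: integrate from the block start).
    sub = blocks[:, :upto, :]
    rev = sub[:, ::-1, :]
    has = rev.any(axis=1)
    l0 = np.where(has, upto - 1 - rev.argmax(axis=1), 0)  # (n_states, N)
    # per-position drive u[s, d, k]
    u = sub.astype(float) @ params.weights.T + params.i0
    if stim_block is not None:
        u = u + stim_block.T[None, :upto, :]
    # suffix[s, j, k] = sum_{d=j}^{upto-1} g^(upto-1-d) u[s, d, k]: the
    # geometric integral of the drive from position j to the block end.
    suffix = np.zeros((n_states, upto + 1, n))
    for d in range(upto - 1, -1, -1):
        suffix[:, d, :] = suffix[:, d + 1, :] + g ** (upto - 1 - d) * u[:, d, :]
    vbar = np.take_along_axis(suffix, l0[:, None, :], axis=1)[:, 0, :]
    steps = upto - l0
    sigma = params.sigma_b * np.sqrt((1.0 - g ** (2 * steps)) / (1.0 - g**2))
    return vbar, sigma


def _spike_probs(params: NetworkParameters, blocks: np.ndarray,
                 stim_block: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron next-step spike probabilities for every state."""
    depth = blocks.shape[1]
    vbar, sigma = _conditional_stats(params, blocks, stim_block, depth)
    return gaussian_tail((params.theta - vbar) / sigma)


def _assemble(params: NetworkParameters, depth: int, probs: np.ndarray) -> sp.csr_matrix:
    n = params.n_neurons
    n_states = probs.shape[0]
    n_patterns = 1 << n
    patterns = ((np.arange(n_patterns)[:, None] >> np.arange(n)) & 1)  # (2^N, N)
    # P[s, a] = prod_k p^a (1-p)^(1-a)
    trans = np.ones((n_states, n_patterns))
    for k in range(n):
        pk = probs[:, k][:, None]
        trans *= np.where(patterns[:, k][None, :] == 1, pk, 1.0 - pk)
    rows = np.repeat(np.arange(n_states), n_patterns)
    shifted = np.arange(n_states, dtype=np.int64) >> n
    cols = (shifted[:, None] | (np.arange(n_patterns, dtype=np.int64)
                                << (n * (depth - 1)))).ravel()
    return sp.csr_matrix((trans.ravel(), (rows, cols)), shape=(n_states, n_states))


def build_block_chain(params: NetworkParameters, depth: int,
                      stim_block: np.ndarray | None = None) -> BlockChain:
    """Build the depth-D block transition matrix.

    ``stim_block`` (optional, shape ``(N, D)``) holds the stimulus values
    at the block's time positions, for a chain frozen at one time step of
    a perturbed run; rows sum to 1 exactly either way.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    _check_capacity(params, depth)
    blocks = state_blocks(params.n_neurons, depth)
    probs = _spike_probs(params, blocks, stim_block)
    return BlockChain(params=params, depth=depth,
                      matrix=_assemble(params, depth, probs))


def invariant_distribution(chain: BlockChain, tol: float = 1e-12,
                           max_iter: int = 10**6) -> np.ndarray:
    """Left fixed point of the transition matrix by power iteration.

    Strictly positive, sums to 1, with L1 residual ``||p M - p|| < tol``.
    """
    m = chain.matrix
    p = np.full(chain.n_states, 1.0 / chain.n_states)
    for _ in range(max_iter):
        nxt = p @ m
        nxt /= nxt.sum()
        if np.abs(nxt - p).sum() < tol:
            return nxt
        p = nxt
    residual = np.abs(p @ m - p).sum()
    raise RuntimeError(f"power iteration did not converge (residual {residual:.3e})")


def monomial_state_values(chain: BlockChain, monomial) -> np.ndarray:
    """Vector of a monomial's values over states (anchor = newest pattern)."""
    if monomial.max_lag > chain.depth - 1:
        raise ValueError("monomial range exceeds the block depth")
    blocks = state_blocks(chain.params.n_neurons, chain.depth)
    vals = np.ones(chain.n_states)
    for i, tau in monomial.events:
        vals *= blocks[:, chain.depth - 1 - tau, i]
    return vals


def _as_values(chain: BlockChain, f) -> np.ndarray:
    if isinstance(f, np.ndarray):
        return f
    if hasattr(f, "events"):
        return monomial_state_values(chain, f)
    blocks = state_blocks(chain.params.n_neurons, chain.depth)
    return np.asarray([f(b) for b in blocks], dtype=float)


def exact_expectation(chain: BlockChain, p_inv: np.ndarray, f) -> float:
    """Stationary expectation of a block observable (monomial, vector or
    callable on ``(D, N)`` blocks, oldest row first)."""
    return float(p_inv @ _as_values(chain, f))


def exact_correlation(chain: BlockChain, p_inv: np.ndarray, f, g, lag: int) -> float:
    """Centred stationary correlation ``C[f(t + lag), g(t)]``, exact.

    Decays like ``|lambda_2|^lag`` with the second eigenvalue of the
    transition matrix.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    fv = _as_values(chain, f)
    gv = _as_values(chain, g)
    q = p_inv * gv
    for _ in range(lag):
        q = q @ chain.matrix
    joint = float(q @ fv)
    return joint - float(p_inv @ fv) * float(p_inv @ gv)


def exact_firing_rates(chain: BlockChain, p_inv: np.ndarray) -> np.ndarray:
    """Exact per-neuron spike probabilities under the invariant measure."""
    blocks = state_blocks(chain.params.n_neurons, chain.depth)
    return p_inv @ blocks[:, -1, :]


def zeta_state_values(chain: BlockChain) -> np.ndarray:
    """Per-neuron susceptibility ``zeta_k`` over states, shape (n_states, N).

    ``zeta_k = [omega_k a1(X_k^sp) + (1 - omega_k) b1(X_k^sp)] / sigma_k``
    anchored so that the block's newest pattern is the spike outcome and
    ``X^sp``/``sigma`` integrate the remaining ``D - 1`` rows.  Requires
    ``D >= 2``.
    """
    if chain.depth < 2:
        raise ValueError("zeta needs depth >= 2 (one history step + outcome)")
    params = chain.params
    blocks = state_blocks(params.n_neurons, chain.depth)
    vbar, sigma = _conditional_stats(params, blocks, None, chain.depth - 1)
    x = (params.theta - vbar) / sigma
    a1, b1 = tail_log_derivatives(1, x)
    omega = blocks[:, -1, :]
    return np.where(omega == 1, a1, b1) / sigma


def exact_kernel_matrix(chain: BlockChain, p_inv: np.ndarray, f,
                        depth: int) -> np.ndarray:
    """Exact first-order kernel ``K[k, m] = C[f(m), zeta_k(0)]``, m = 1..depth+1.

    ``zeta`` anchored at ``t`` is a function of the block ending at
    ``t + 1``, so the chain lag between the two anchors is ``m - 1``.
    """
    fv = _as_values(chain, f)
    zeta = zeta_state_values(chain)
    n = chain.params.n_neurons
    f_mean = float(p_inv @ fv)
    z_mean = p_inv @ zeta
    kernel = np.empty((n, depth + 1))
    prop = fv.copy()
    for m in range(1, depth + 2):
        # prop = M^(m-1) f  (right action: prop[s] = E[f(t+m-1) | state s at t])
        if m > 1:
            prop = chain.matrix @ prop
        joint = (p_inv[:, None] * zeta) .T @ prop
        kernel[:, m - 1] = joint - f_mean * z_mean
    return kernel


def spectral_gap(chain: BlockChain) -> float:
    """``1 - |lambda_2|`` of the block transition matrix (in (0, 1])."""
    if chain.n_states <= 4096:
        eig = np.linalg.eigvals(chain.matrix.toarray())
    else:
        eig = spla.eigs(chain.matrix, k=2, which="LM", return_eigenvectors=False)
    mods = np.sort(np.abs(eig))[::-1]
    lam2 = mods[1] if mods.size > 1 else 0.0
    return float(1.0 - min(lam2, 1.0))


def propagate_with_stimulus(params: NetworkParameters, depth: int, stimulus,
                            f, t_steps: int) -> ResponseTrace:
    """Exact response trace ``delta f(n) = E[f(n)] - E_sp[f]``.

    Starts from the spontaneous invariant distribution (exact before the
    onset, since the stimulus vanishes there) and applies time-dependent
    transition matrices with the stimulus folded into the threshold
    distance at each step.  The trace is identically zero for
    ``n < t0 + 1`` (causality) and identically zero for zero amplitude.
    """
    chain = build_block_chain(params, depth)
    p_inv = invariant_distribution(chain)
    fv = _as_values(chain, f)
    base = float(p_inv @ fv)
    blocks = state_blocks(params.n_neurons, depth)
    t0 = stimulus.t0 if stimulus is not None else t_steps
    times = np.arange(t_steps)
    values = np.zeros(t_steps)
    pi = p_inv
    # transitions into n <= t0 see no stimulus: the distribution stays
    # invariant and the trace is exactly zero there (causality).
    for n in range(t0 + 1, t_steps):
        stim_block = np.stack(
            [stimulus.column(t) for t in range(n - depth, n)], axis=1
        ) if stimulus is not None else None
        probs = _spike_probs(params, blocks, stim_block)
        m_n = _assemble(params, depth, probs)
        pi = pi @ m_n
        values[n] = float(pi @ fv) - base
    label = getattr(f, "name", repr(f))
    return ResponseTrace(times, values, None, method="exact", observable=label,
                         meta={"baseline": base, "depth": depth})
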