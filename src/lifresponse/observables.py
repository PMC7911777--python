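"""Monomial spike observables and the Hammersley-Clifford decomposition.

A *monomial* is a product of spike variables ``omega_{i1}(t - tau_1) ...``:
the indicator of a joint spike event.  Our lag convention anchors events in
the past: the event ``(i, tau)`` reads ``omega_i(t - tau)`` when the
monomial is evaluated at anchor time ``t`` (causality: only times ``<= t``
are read).  The ``2^(N R)`` monomials of ``N`` neurons and range
``R = D + 1`` form a basis of the range-R observables; any such function
decomposes uniquely as ``f = sum_l f_l m_l`` with coefficients obtained by
Moebius inversion over the Boolean lattice of spike events.

Index encoding: event ``(i, tau)`` occupies bit ``i + N * tau`` (0-based),
and a monomial's index is the OR of its event bits; a spike block of range
R uses the same encoding, so ``m_l(block) = 1`` iff ``l``'s bits are a
subset of the block's bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Monomial",
    "LinearCombination",
    "TimedObservable",
    "monomial_index",
    "monomial_from_index",
    "hc_decompose",
    "hc_reconstruct",
]

_MAX_BITS = 24  # capacity guard for exhaustive 2^(N R) enumerations


@dataclass(frozen=True)
class Monomial:
    """A set of (neuron, lag) spike events; the empty set is the constant 1."""

    events: frozenset

    def __init__(self, events=()):
        ev = frozenset((int(i), int(t)) for i, t in events)
        for i, t in ev:
            if i < 0 or t < 0:
                raise ValueError("neuron and lag must be non-negative (causal lags)")
        object.__setattr__(self, "events", ev)

    @property
    def degree(self) -> int:
        return len(self.events)

    @property
    def max_lag(self) -> int:
        return max((t for _, t in self.events), default=0)

    def eval(self, raster, t: int) -> int:
        """Evaluate at anchor time ``t``: product of ``omega_i(t - tau)``."""
        for i, tau in self.events:
            if not raster.value(i, t - tau):
                return 0
        return 1

    def eval_ensemble(self, ensemble, times) -> np.ndarray:
        """Vectorized evaluation: (n_trials, len(times)) 0/1 array."""
        times = np.asarray(times, dtype=int)
        cols = times - ensemble.n_min
        if np.any(cols - self.max_lag < 0) or np.any(cols >= ensemble.n_steps):
            raise IndexError("anchor times reach outside the ensemble window")
        out = np.ones((ensemble.n_trials, times.size), dtype=np.uint8)
        for i, tau in self.events:
            out &= ensemble.spikes[:, i, cols - tau]
        return out

    def eval_block(self, block: np.ndarray) -> int:
        """Evaluate on a spike block ``block[lag, neuron]`` (lag 0 = anchor)."""
        for i, tau in self.events:
            if not block[tau, i]:
                return 0
        return 1

    def __repr__(self) -> str:
        ev = sorted(self.events, key=lambda e: (e[1], e[0]))
        return f"Monomial({ev})"


@dataclass(frozen=True)
class LinearCombination:
    """Finite-range observable ``sum_l f_l m_l`` as monomial/coefficient pairs."""

    terms: tuple  # of (Monomial, float)

    def __init__(self, terms):
        object.__setattr__(self, "terms", tuple((m, float(c)) for m, c in terms))

    @property
    def max_lag(self) -> int:
        return max((m.max_lag for m, _ in self.terms), default=0)

    def eval(self, raster, t: int) -> float:
        return sum(c * m.eval(raster, t) for m, c in self.terms)

    def eval_ensemble(self, ensemble, times) -> np.ndarray:
        out = np.zeros((ensemble.n_trials, np.asarray(times).size))
        for m, c in self.terms:
            out += c * m.eval_ensemble(ensemble, times)
        return out


@dataclass(frozen=True)
class TimedObservable:
    """A finite-range observable modulated by an explicit time profile.

    ``f(t, omega) = profile(t) * base(omega_{t-D}^{t})``; with the constant
    profile 1 this reduces to the static observable.
    """

    base: object
    profile: Callable[[int], float] = field(default=None)

    @property
    def max_lag(self) -> int:
        return self.base.max_lag

    def _scale(self, times):
        if self.profile is None:
            return 1.0
        return np.asarray([self.profile(int(t)) for t in np.atleast_1d(times)], dtype=float)

    def eval(self, raster, t: int) -> float:
        s = 1.0 if self.profile is None else float(self.profile(t))
        return s * self.base.eval(raster, t)

    def eval_ensemble(self, ensemble, times) -> np.ndarray:
        return self.base.eval_ensemble(ensemble, times) * self._scale(times)


# ---------------------------------------------------------------------------
# Index encoding
# ---------------------------------------------------------------------------

def monomial_index(m: Monomial, n_neurons: int, r: int) -> int:
    """Bijective index of ``m`` in ``0 .. 2^(N R) - 1`` (bit = i + N*tau)."""
    idx = 0
    for i, tau in m.events:
        if i >= n_neurons or tau >= r:
            raise ValueError(f"event ({i}, {tau}) outside N={n_neurons}, R={r}")
        idx |= 1 << (i + n_neurons * tau)
    return idx


def monomial_from_index(l: int, n_neurons: int, r: int) -> Monomial:
    """Inverse of :func:`monomial_index`."""
    if not (0 <= l < (1 << (n_neurons * r))):
        raise ValueError(f"index {l} outside 0..2^{n_neurons * r}-1")
    events = []
    for b in range(n_neurons * r):
        if l & (1 << b):
            events.append((b % n_neurons, b // n_neurons))
    return Monomial(events)


def _block_from_bits(bits: int, n_neurons: int, r: int) -> np.ndarray:
    block = np.zeros((r, n_neurons), dtype=np.uint8)
    for b in range(n_neurons * r):
        if bits & (1 << b):
            block[b // n_neurons, b % n_neurons] = 1
    return block


def hc_decompose(f, n_neurons: int, r: int) -> np.ndarray:
    """Coefficients of a range-R function on the monomial basis.

    ``f`` is a callable on spike blocks (``(R, N)`` 0/1 arrays, row = lag,
    lag 0 = anchor).  Coefficients follow from Moebius inversion over the
    Boolean lattice: ``f_S = sum_{T subset S} (-1)^(|S|-|T|) f(T)``; the
    reconstruction ``sum_l f_l m_l`` is exact on every block.  The
    transform is linear in ``f`` and maps a single monomial to the
    corresponding unit vector.
    """
    n_bits = n_neurons * r
    if n_bits > _MAX_BITS:
        raise ValueError(
            f"N*R = {n_bits} bits exceeds the exhaustive-enumeration capacity ({_MAX_BITS})"
        )
    size = 1 << n_bits
    coeffs = np.empty(size)
    for bits in range(size):
        coeffs[bits] = f(_block_from_bits(bits, n_neurons, r))
    # in-place subset Moebius transform
    for b in range(n_bits):
        step = 1 << b
        for bits in range(size):
            if bits & step:
                coeffs[bits] -= coeffs[bits ^ step]
    return coeffs


def hc_reconstruct(coeffs: np.ndarray, n_neurons: int, r: int):
    """Return the block function ``sum_l f_l m_l`` for given coefficients."""
    coeffs = np.asarray(coeffs, dtype=float)

    def f(block: np.ndarray) -> float:
        bits = 0
        for b in range(n_neurons * r):
            if block[b // n_neurons, b % n_neurons]:
                bits |= 1 << b
        # sum of coefficients over subsets of `bits`
        total = 0.0
        sub = bits
        while True:
            total += coeffs[sub]
            if sub == 0:
                break
            sub = (sub - 1) & bits
        return total

    return f
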