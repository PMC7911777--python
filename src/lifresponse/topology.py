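"""One-dimensional lattice connectivity and the moving Gaussian stimulus.

The network of the lattice experiments is a chain of ``N`` neurons at
positions ``x_k = k * dx`` (mm, 0-based) with null boundary conditions:
each neuron excites its nearest neighbours with weight ``w_plus`` and
inhibits its second neighbours with weight ``-w_minus``.  The stimulus is
a Gaussian pulse of spatial width ``Delta`` travelling left to right at
speed ``v``, sampled on the neuron/time grid with time bin ``b``; only the
ratio ``v*b/dx`` matters on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusField", "build_lattice_weights", "moving_gaussian_stimulus"]


@dataclass
class StimulusField:
    """Per-neuron, per-step stimulus values on the post-burn-in clock.

    ``values[k, n]`` is ``S_k(n)`` for steps ``0 <= n < T``; the field is
    identically zero before the onset step ``t0`` and outside the stored
    window (in particular during burn-in, which occupies negative times).
    """

    values: np.ndarray
    t0: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("stimulus values must be (neurons x steps)")
        if not np.all(np.isfinite(v)):
            raise ValueError("stimulus values must be finite")
        v = v.copy()
        v[:, : max(self.t0, 0)] = 0.0
        self.values = v

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def value(self, k: int, n: int) -> float:
        """``S_k(n)``; zero outside the stored window."""
        if 0 <= n < self.n_steps:
            return float(self.values[k, n])
        return 0.0

    def column(self, n: int) -> np.ndarray:
        """The pattern ``S(n)`` over neurons; zeros outside the window."""
        if 0 <= n < self.n_steps:
            return self.values[:, n]
        return np.zeros(self.n_neurons)

    def scaled(self, factor: float) -> "StimulusField":
        return StimulusField(self.values * factor, t0=self.t0, meta=dict(self.meta))


def build_lattice_weights(n_neurons: int, w_plus: float, w_minus: float) -> np.ndarray:
    """Banded lattice weight matrix: ``W[k+-1, k] = +w_plus``, ``W[k+-2, k] = -w_minus``.

    ``w_plus`` and ``w_minus`` are magnitudes (the inhibitory sign is
    applied here); entries pointing outside the chain are dropped (null
    boundaries).  The result is symmetric with bandwidth 2 and zero
    diagonal.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if w_plus < 0 or w_minus < 0:
        raise ValueError("w_plus and w_minus are magnitudes and must be >= 0")
    w = np.zeros((n_neurons, n_neurons))
    for k in range(n_neurons):
        for off, val in ((1, w_plus), (-1, w_plus), (2, -w_minus), (-2, -w_minus)):
            j = k + off
            if 0 <= j < n_neurons:
                w[j, k] = val
    return w


def moving_gaussian_stimulus(amplitude: float, delta: float, v: float, dx: float,
                             b: float, n_neurons: int, t0: int, n_steps: int,
                             x_start: float = 0.0) -> StimulusField:
    """Sample the travelling Gaussian pulse onto the neuron/time grid.

    ``S(x, t) = A / (sqrt(2 pi) Delta) * exp(-(x - x_start - v t)^2 / (2 Delta^2))``
    evaluated at ``x_k = k * dx`` and ``t = (n - t0) * b`` for ``n >= t0``
    (the pulse clock starts at onset); zero before ``t0``.  The spatial
    integral of ``S`` at fixed ``t`` is ``A``.

    Parameters
    ----------
    amplitude:
        Pulse amplitude ``A >= 0`` (voltage units * mm per step).
    delta:
        Spatial width (standard deviation) in mm, > 0.
    v:
        Propagation speed in mm/s.
    dx:
        Lattice spacing in mm, > 0.
    b:
        Time bin in seconds, > 0.
    x_start:
        Pulse centre position at onset (mm).
    """
    if delta <= 0 or b <= 0 or dx <= 0:
        raise ValueError("delta, b and dx must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    x = np.arange(n_neurons) * dx
    values = np.zeros((n_neurons, n_steps))
    norm = amplitude / (math.sqrt(2.0 * math.pi) * delta)
    for n in range(max(t0, 0), n_steps):
        centre = x_start + v * (n - t0) * b
        values[:, n] = norm * np.exp(-((x - centre) ** 2) / (2.0 * delta**2))
    return StimulusField(values, t0=t0, meta={
        "amplitude": amplitude, "delta_mm": delta, "v_mm_per_s": v,
        "dx_mm": dx, "b_s": b, "x_start_mm": x_start,
    })
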