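# lifresponse

Predicting how a weak, time-dependent stimulus shifts the average of *any*
finite-range spike observable of a stochastic spiking network — firing
rates, but also delayed pairwise (and higher-order) spike coincidences —
from the network's **spontaneous** correlations alone, and validating those
predictions against both direct simulation and an exactly solvable
small-network oracle.

The package is aimed at computational neuroscientists studying stimulus
coding and fluctuation–dissipation relations in spiking networks, and at
anyone who needs a carefully tested reference implementation of linear
response for Gibbs-type spike processes with memory.

## The model and the statistic

The network is a discrete-time stochastic leaky integrate-and-fire model:

    V_k(n+1) = γ V_k(n)(1 − ω_k(n)) + Σ_j W_kj ω_j(n) + I0 + S_k(n) + noise,

with threshold θ, reset to zero, leak rate γ ∈ [0, 1) and Gaussian noise of
amplitude σ_B. Conditioned on the spike history, the voltage is Gaussian,
so the spike process is a chain with unbounded memory whose transitions
factorize over neurons:

    P[ω_k(n) = 1 | past] = Π(X_k),   X_k = (θ − V̄_k) / σ_k,

where Π is the Gaussian upper-tail probability, V̄_k the noise-free voltage
integrated since the last reset and σ_k the integrated-noise std. The log
transition probability is the normalized Gibbs potential of the process.

For a stimulus S switched on at t0, the first-order (Kubo / fluctuation–
dissipation) response of an observable f is a convolution of S with a
kernel of spontaneous correlations. Two predictors are provided:

* `order1` — kernel `K[k,m] = C_sp[f(m), ζ_k(0)]` with the full
  susceptibility ζ_k built from the log-derivatives of Π;
* `hc1` — the lowest-order Hammersley–Clifford truncation, using bare spike
  correlations `C_sp[f(m), ω_k]` times a constant coefficient (the classical
  fluctuation–dissipation form).

An exact Markov oracle (block transition matrix over depth-D spike blocks,
invariant measure, spectral gap, exact correlations and exact non-stationary
propagation) supplies ground truth on small networks. Agreement between a
prediction and an empirical trace is measured by the unnormalized
`d² = Σ_n (pred(n) − emp(n))²`.

## Worked example

Exactly solvable two-neuron network (γ = 0): estimate the spontaneous rate,
predict the response of neuron 1 to a weak pulse on neuron 0, and compare
with exact propagation of the chain:

```python
import numpy as np
import lifresponse as lr
from lifresponse.experiments import tiny_network, tiny_pulse_stimulus
from lifresponse.observables import Monomial

params = tiny_network()
f = Monomial([(1, 0)])                 # spike variable of neuron 1

spont = lr.simulate_ensemble(params, None, t_steps=2000, burn_in=20,
                             m_trials=200, master_seed=11)
chain = lr.markov.build_block_chain(params, 2)
p_inv = lr.markov.invariant_distribution(chain)
rate, se = lr.stationary_average(f, spont)
print(f"spontaneous rate: {rate:.4f} +/- {se:.4f} "
      f"(exact {lr.markov.exact_firing_rates(chain, p_inv)[1]:.4f})")

stim = tiny_pulse_stimulus(0.2, t_steps=40)          # pulse on neuron 0
kernel = lr.kernel_order1(f, spont, depth=6)
pred = lr.predict_order1(kernel, stim, 40)
exact = lr.markov.propagate_with_stimulus(params, 2, stim, f, 40)
n = int(np.argmax(exact.values))
print(f"peak response at n={n}: predicted {pred.values[n]:+.4f}, "
      f"exact {exact.values[n]:+.4f}")
print(f"d2(predicted, exact) = {lr.d2_distance(pred, exact.restrict(0, 39)):.2e}")
```

Output:

```
spontaneous rate: 0.5314 +/- 0.0009 (exact 0.5319)
peak response at n=17: predicted +0.0451, exact +0.0424
d2(predicted, exact) = 2.94e-05
```

The empirical rate agrees with the invariant measure of the chain to within
its standard error; the kernel prediction tracks the exact evoked response
(the residual is the second-order, amplitude² effect — halve the pulse
amplitude and the peak discrepancy drops ~4×).

The lattice experiment (30 neurons, nearest-neighbour excitation,
second-neighbour inhibition, a travelling Gaussian pulse) runs from the
command line:

```bash
lifresponse experiment --out results/lattice
```

which writes `d2_table.csv` (d² per observable, amplitude and predictor),
`traces.csv` (empirical / order1 / hc1 response traces) and a run manifest.
Other subcommands: `simulate`, `kernel`, `predict`, `oracle`, `fixture`
(see `lifresponse --help`). Configuration is YAML; see
`lifresponse.experiments.default_lattice_config()` for the reference setup
and `docs/methods.md` for every parameter and the reasoning behind it.

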