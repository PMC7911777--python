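# Methods

## The model

`lifresponse` implements a discrete-time stochastic leaky integrate-and-fire
(LIF) network of `N` neurons. The noise-free voltage of neuron `k` obeys the
reset recursion

    Vbar_k(n+1) = gamma * Vbar_k(n) * (1 - omega_k(n))
                  + sum_j W_kj omega_j(n) + I0 + S_k(n),

where `omega_k(n) in {0,1}` is the spike variable, `gamma in [0,1)` the leak
rate, `W` the synaptic matrix (`W_kj`: presynaptic `j` onto postsynaptic `k`),
`I0` a constant drive and `S_k(n)` a time-dependent stimulus. An additive
Gaussian noise of amplitude `sigma_B` is integrated along the same window;
conditioned on the spike history the voltage is Gaussian with mean `Vbar` and
standard deviation

    sigma_k(n) = sigma_B * sqrt((1 - gamma^(2 s)) / (1 - gamma^2)),

`s` being the number of steps since the last reset. A neuron spikes when its
voltage reaches the threshold `theta` and is reset to zero. Consequently the
spike process is a chain with unbounded memory whose one-step transition
probabilities factorize over neurons,

    P[omega_k(n) = 1 | past] = Pi(X_k(n-1)),
    X_k(n-1) = (theta - Vbar_k(n-1, omega)) / sigma_k(n-1, omega),

with `Pi` the standard Gaussian upper-tail function. The log transition
probability is the normalized Gibbs potential `phi(n, omega)`; sums of `phi`
over a block give the block's conditional log-probability exactly (chain
rule), which the test suite checks to machine precision.

One numerical-design point deserves emphasis: the simulator samples the
integrated noise *in distribution* at every step (spike iff
`Vbar + sigma * xi >= theta`, fresh `xi ~ N(0,1)`), rather than carrying a
noisy voltage across steps. Carrying the noise would condition the
sub-threshold noise path on the spike history, making the true conditional
law a truncated Gaussian and the product-of-Gaussian-tails transition only a
small-`sigma_B` approximation. With the scheme used here the simulated
process *is* the analyzed chain, for every `gamma`; all deterministic limits
(sub-threshold silence, periodic spiking at vanishing noise, Bernoulli rates
at `gamma = 0`) are unaffected, and the test suite verifies empirical one-step
transition frequencies against the analytic probabilities directly.

## Observables

Finite-range observables are represented on the monomial basis: a monomial is
a set of (neuron, lag) events evaluated as the product of the corresponding
spike variables; lag `tau` reads `tau` steps before the anchor time
(causality). Any function of `N` neurons over `R` consecutive steps
decomposes uniquely over the `2^(N R)` monomials; coefficients are computed
by Moebius inversion over the Boolean lattice of spike events
(`observables.hc_decompose`), with exhaustive reconstruction checked exactly
for small `N*R`. The index encoding is `bit(i, tau) = i + N * tau`, 0-based;
it is a declared convention of this package (any bijection would do) and is
stable across releases.

## Linear response

For a weak stimulus switched on at `t0`, the first-order shift of an
observable's average is a sum of *spontaneous* correlation functions between
the observable and the first-order variation of the potential. Two
predictors are implemented:

* **order1** — the full first-order kernel. The per-neuron susceptibility is

      zeta_k(t) = [omega_k(t+1) a1(X_k^sp(t)) + (1 - omega_k(t+1)) b1(X_k^sp(t))]
                  / sigma_k(t),

  with `a1 = Pi'/Pi` and `b1 = -Pi'/(1 - Pi)` the log-derivatives of the
  Gaussian tail. The kernel entries `K[k, m] = C_sp[f(t+m), zeta_k(t)]`
  (`m = 1..D+1`) are stationary covariances pooled over trials and anchor
  times, and the prediction is the convolution

      delta mu_f(n) = - sum_k sum_{m=1}^{D+1} sum_{l=0}^{h_k}
                        gamma^l K[k, m] S_k(n - m - l),

  where the voltage-integration horizon uses the mean-field replacement of
  the last reset time by the mean inter-spike interval,
  `h_k = round(1 / nu_k)` clipped to `[1, 10 D]`.

* **hc1** — the lowest-order Hammersley–Clifford truncation of `zeta`,
  `zeta_k ~ gamma1 * omega_k / sigma_inf + const`, a classical
  fluctuation–dissipation form using bare spike correlations
  `C_sp[f(t+m), omega_k(t+1)]` with the constant coefficient
  `gamma1 = a1(thetaL) - b1(thetaL)` evaluated at the isolated-neuron
  effective threshold `thetaL = (theta - I0/(1-gamma)) / sigma_inf`,
  `sigma_inf = sigma_B / sqrt(1 - gamma^2)`. The additive constant drops
  because centred correlations annihilate constants. Anchoring note: since
  `zeta` anchored at `t` reads the spike at `t+1`, the truncation replaces it
  by `omega_k(t+1)` (not `omega_k(t)`); this makes `predict_hc1` exactly the
  degree-1 truncation of `predict_order1`, an identity the tests verify at
  `gamma = 0` where the truncation coefficient is available in closed form.

Both predictors are exactly linear in the stimulus amplitude and exactly
zero before `t0 + 1`. The kernel memory is truncated at depth `D`
(default 10, justified by the exponential decay of `gamma^m` times the
spontaneous correlations, itself governed by the spectral gap of the block
chain); increasing `D` changes predictions by at most a `gamma^D`-type tail.

`general_response` exposes the model-agnostic correlation-series entry point
for a user-supplied potential variation `delta phi(r, omega)`; for the LIF
model the first-order `delta phi` builder is provided and agrees with the
kernel path within estimation error.

### Validity diagnostics

The expansion is trustworthy when (i) spike probabilities stay away from
saturation, `Pi(X) in [eps, 1-eps]` (default `eps = 0.01`), and (ii) the
stimulus-induced shift is small against the second-order scale,
`|delta X| << 2 min(|X + a1(X)|, |X + b1(X)|)` (both expansion branches must
admit the truncation; the binding bound is maximal near `X = 0`, i.e. for a
threshold-poised network). `validity_diagnostics` reports the fraction of
bins violating each condition; both fractions grow monotonically with the
stimulus amplitude.

## Exact oracle

On small networks the chain is truncated to memory depth `D`: the state is
the block of the last `D` patterns and a neuron silent throughout the block
integrates from the block start (error `O(gamma^D)`; exact when
`gamma = 0`). The oracle builds the sparse `2^(ND) x 2^(ND)` row-stochastic
transition matrix (capacity `N*D <= 16` bits), obtains the invariant measure
by power iteration to an L1 residual of `1e-12` (cap `1e6` iterations), and
provides exact expectations, lagged correlations, spectral gap, exact
first-order kernels, and exact non-stationary propagation under a stimulus
(time-dependent matrices with the stimulus folded into the threshold
distance, starting from the invariant measure, which is exact before onset).

All stochastic estimators are validated against this oracle on a two-neuron
`gamma = 0` network, where the process is exactly Markov with one step of
memory: rates and lagged correlations at `10^6` pooled samples, response
traces at `10^5` trials, empirical kernels against exact kernels, and the
`O(A^2)` convergence of the first-order prediction (halving the amplitude
shrinks the maximal discrepancy against exact propagation by a factor ~4; at
`gamma = 0` the mean-field horizon is exact, so the quadratic scaling is not
polluted by a linear-in-A approximation error).

## Study conditions

The lattice experiment uses `N = 30` neurons at spacing `dx = 1 mm` with
nearest-neighbour excitation `w+ = 0.2` and second-neighbour inhibition
`w- = 2` (null boundaries), `theta = 1`, `gamma = 0.6` (decay time
`tau_gamma ~ 2` steps), kernel depth `D = 10`, and a Gaussian pulse of width
`Delta = 1 mm` travelling at `v = 2 mm/s` sampled at `b = 10 ms` (grid speed
`v b / dx = 0.02` sites/step).

Two constants are not fixed by that list and are this package's choices:

* `sigma_B = 0.4`, a moderate noise level giving `sigma_inf = 0.5`;
* `I0 = theta (1 - gamma) = 0.4`, the *threshold-poised* calibration: the
  isolated-neuron effective threshold distance `thetaL` is then 0, the centre
  of the sigmoid's linear region where the smallness condition above is least
  restrictive — the regime in which a linear-response demonstration is
  meaningful. With the strong lattice inhibition the resulting network
  baseline is ~0.12 spikes/bin. A markedly sub-threshold calibration instead
  places the network in the convex region of `Pi`, where the empirical
  response grows faster than linearly and *every* first-order predictor
  underestimates it; that regime is reported by the validity diagnostics
  rather than hidden.

The reduced-scale protocol (chosen as this package's default experiment
size) uses `M = 2000` trials of `T = 200` analysis steps after a burn-in of
`10 * max(tau_gamma, D) = 100` steps, onset `t0 = 20`, and pulse start
`x_start = 13 mm` so that the pulse transits the central neuron inside the
window; the amplitude sweep is `A in {0.25, 0.5, 1, 2}`, anchored so the
smallest amplitude keeps the peak `|delta X|` near 0.5. Observables: the
central-neuron rate `omega_15(n)` and the delayed pairwise coincidence
`omega_13(n-3) * omega_15(n)` (0-based labels). The agreement metric is the
unnormalized `d^2 = sum_n (pred(n) - emp(n))^2`; it contains an
amplitude-independent Monte-Carlo floor of roughly `T * var(f) / M` from the
empirical trace, so comparisons between predictors at the same amplitude are
the informative quantity at small `A`. Full-scale runs (`M = 10^4` or more)
are a flag away (`run.M` in the config).

Trial seeding: trial `m` of an ensemble uses child `m` of
`numpy.random.SeedSequence(master_seed)`; ensembles are bit-reproducible and
a size-1 ensemble coincides with `simulate_trial` run with the corresponding
child seed.

## What the synthetic data does and does not emulate

All data are generated by the model itself; the generator *is* the model
under study, so "passing" means the estimators and predictors are correct
for this model class — not that real recordings obey it. In particular the
model has no refractory period, no transmission delays, no electric
synapses, instantaneous reset to zero, and stationary Gaussian noise;
empirical spike trains violate all of these to varying degrees. The
fluctuation–dissipation machinery itself (predicting evoked responses from
spontaneous correlations) is model-agnostic through `general_response`, but
its kernels would then have to be estimated from data rather than derived.

## Known limitations

* The mean-field horizon (`tau -> mean inter-spike interval`) introduces an
  error linear in the stimulus amplitude whenever `gamma > 0`; it is the
  price of the convolutional kernel form. The `O(A^2)` claims are therefore
  certified on the `gamma = 0` oracle network.
* The depth-`D` oracle truncation limits exact cross-checks at `gamma > 0`
  to qualitative agreement; error `O(gamma^D)`.
* Second- and higher-order Volterra terms are out of scope; at large
  amplitudes the empirical response saturates (rates are bounded by 1) and
  both predictors deviate, which the amplitude sweep quantifies.
* `hc_decompose` enumerates all `2^(N R)` blocks and is guarded at
  `N R <= 24` bits; the block chain at `N D <= 16` bits.
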