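"""Linear-response machinery: log-derivatives of the sigmoid, the
susceptibility zeta, kernel estimation, the two predictors, the general
correlation-series path, and the validity diagnostics."""

import math

import numpy as np
import pytest

import lifresponse as lr
from lifresponse.core import (NetworkParameters, SpikeRaster,
                              log_gaussian_tail, potential_phi)
from lifresponse.experiments import tiny_pulse_stimulus
from lifresponse.observables import Monomial, hc_decompose, monomial_index
from lifresponse.response import (derivative_a_b, general_response,
                                  kernel_hc1, kernel_order1,
                                  kernel_order1_exact, lif_delta_phi_order1,
                                  predict_hc1, predict_order1,
                                  validity_diagnostics, zeta, zeta_series)
from lifresponse.topology import StimulusField


class TestLogDerivatives:
    def test_antisymmetry_at_zero(self):
        a1, b1 = derivative_a_b(1, 0.0)
        assert a1 == pytest.approx(-2.0 / math.sqrt(2 * math.pi), rel=1e-12)
        assert a1 == pytest.approx(-b1, rel=1e-12)

    def test_signs_everywhere(self):
        xs = np.linspace(-6, 6, 101)
        a1, b1 = derivative_a_b(1, xs)
        assert np.all(a1 < 0) and np.all(b1 > 0)

    @pytest.mark.parametrize("order", [1, 2])
    def test_finite_difference_oracle(self, order):
        h = 1e-5
        for x in (-1.3, 0.4, 1.0, 2.1):
            a, b = derivative_a_b(order, x)
            if order == 1:
                fd_a = (log_gaussian_tail(x + h) - log_gaussian_tail(x - h)) / (2 * h)
                fd_b = (math.log(1 - math.exp(log_gaussian_tail(x + h)))
                        - math.log(1 - math.exp(log_gaussian_tail(x - h)))) / (2 * h)
            else:
                fd_a = (derivative_a_b(1, x + h)[0]
                        - derivative_a_b(1, x - h)[0]) / (2 * h)
                fd_b = (derivative_a_b(1, x + h)[1]
                        - derivative_a_b(1, x - h)[1]) / (2 * h)
            assert a == pytest.approx(fd_a, abs=1e-6)
            assert b == pytest.approx(fd_b, abs=1e-6)

    def test_unsupported_order(self):
        with pytest.raises(ValueError):
            derivative_a_b(3, 0.0)


class TestZeta:
    def test_branch_selection(self, tiny_params):
        spikes = np.zeros((2, 6), dtype=np.uint8)
        spikes[0, 3] = 1
        r = SpikeRaster(spikes)
        from lifresponse.core import (integrated_noise_std,
                                      x_threshold_distance)
        x = x_threshold_distance(tiny_params, r, None, 0, 2)
        sig = integrated_noise_std(tiny_params, r, 0, 2)
        a1, b1 = derivative_a_b(1, x)
        assert zeta(tiny_params, r, 0, 3) == pytest.approx(a1 / sig)  # spiked
        assert zeta(tiny_params, r, 1, 3) == pytest.approx(b1 / sig)  # silent

    def test_finite_difference_of_potential(self, tiny_params):
        # zeta is (minus) the derivative of the potential with respect to a
        # unit one-step stimulus on that neuron
        rng = np.random.default_rng(8)
        spikes = (rng.random((2, 12)) < 0.4).astype(np.uint8)
        r = SpikeRaster(spikes)
        eps = 1e-5
        for k in (0, 1):
            for n in (5, 9):
                s = np.zeros((2, 12))
                s[k, n - 1] = eps
                stim = StimulusField(s, t0=0)
                # the potential perturbation comes only from neuron k's term
                d_phi = potential_phi(tiny_params, r, stim, n) \
                    - potential_phi(tiny_params, r, None, n)
                assert zeta(tiny_params, r, k, n) == pytest.approx(
                    -d_phi / eps, abs=1e-4)

    def test_series_matches_scalar(self, tiny_params):
        ens = lr.simulate_ensemble(tiny_params, None, 30, 5, 4, master_seed=14)
        zs = zeta_series(tiny_params, ens)
        for m in range(4):
            raster = ens.raster(m)
            for r in (0, 7, 20):
                col = (r - 1) - ens.n_min
                for k in (0, 1):
                    assert zs[m, k, col] == pytest.approx(
                        zeta(tiny_params, raster, k, r), rel=1e-12)


class TestKernels:
    def test_disconnected_neuron_has_null_kernel(self):
        params = NetworkParameters(2, np.zeros((2, 2)), 0.0, 1.0, 0.7, 0.5)
        ens = lr.simulate_ensemble(params, None, 3000, 5, 100, master_seed=19)
        f = Monomial([(0, 0)])
        kern = kernel_order1(f, ens, depth=4)
        # neuron 1 is independent of f: entries are pure noise around zero
        assert np.abs(kern.kernel[1]).max() < 0.01
        # neuron 0 at m=1 carries the self-susceptibility, far from zero
        assert abs(kern.kernel[0, 0]) > 0.1

    def test_empirical_kernel_matches_exact_oracle(self, tiny_params,
                                                   tiny_spont):
        f = Monomial([(1, 0)])
        k_emp = kernel_order1(f, tiny_spont, depth=5)
        k_ex = kernel_order1_exact(tiny_params, 2, f, depth=5)
        assert np.abs(k_emp.kernel - k_ex.kernel).max() < 0.015
        assert np.array_equal(k_emp.horizons, k_ex.horizons)

    def test_kernel_columns_decay(self, tiny_params):
        f = Monomial([(1, 0)])
        k_ex = kernel_order1_exact(tiny_params, 2, f, depth=8)
        mags = np.abs(k_ex.kernel).max(axis=0)
        assert mags[-1] < 1e-2 * mags.max()

    def test_stimulus_ensemble_rejected(self, tiny_params, tiny_stimulus):
        ens = lr.simulate_ensemble(tiny_params, tiny_stimulus, 40, 5, 10, 1)
        with pytest.raises(ValueError):
            kernel_order1(Monomial([(0, 0)]), ens, depth=3)


class TestPrediction:
    def test_zero_stimulus_zero_trace(self, tiny_params, tiny_spont):
        f = Monomial([(1, 0)])
        kern = kernel_order1(f, tiny_spont, depth=5)
        stim = tiny_pulse_stimulus(0.0, t_steps=40)
        assert np.all(predict_order1(kern, stim, 40).values == 0.0)

    def test_exact_linearity_in_amplitude(self, tiny_params, tiny_spont):
        f = Monomial([(1, 0)])
        kern = kernel_order1(f, tiny_spont, depth=5)
        t1 = predict_order1(kern, tiny_pulse_stimulus(0.1, t_steps=40), 40)
        t2 = predict_order1(kern, tiny_pulse_stimulus(0.2, t_steps=40), 40)
        assert np.allclose(t2.values, 2.0 * t1.values, rtol=1e-12, atol=1e-15)

    def test_exact_causality(self, tiny_params, tiny_spont):
        f = Monomial([(1, 0)])
        kern = kernel_order1(f, tiny_spont, depth=5)
        stim = tiny_pulse_stimulus(0.3, t_steps=40, t0=12)
        trace = predict_order1(kern, stim, 40)
        assert np.all(trace.values[:13] == 0.0)

    def test_first_order_matches_exact_response_at_small_amplitude(
            self, tiny_params):
        f = Monomial([(1, 0)])
        kern = kernel_order1_exact(tiny_params, 2, f, depth=12)
        stim = tiny_pulse_stimulus(0.05, t_steps=40)
        pred = predict_order1(kern, stim, 40)
        exact = lr.markov.propagate_with_stimulus(tiny_params, 2, stim, f, 40)
        peak = np.abs(exact.values).max()
        assert np.abs(pred.values - exact.values).max() < 0.03 * peak


class TestHC1:
    def test_scale_is_the_degree_one_hc_coefficient(self, tiny_params,
                                                    tiny_spont):
        # at gamma=0 the HC coefficient of omega_k in zeta (all other spikes
        # zero) is exactly gamma1(thetaL)/sigma_inf
        f = Monomial([(1, 0)])
        kern = kernel_hc1(f, tiny_spont, depth=5)
        p = tiny_params
        sig = p.sigma_b   # = sigma_inf at gamma 0

        def zeta_block(block):
            # range-2 block, lag row 0 = anchor (the spike outcome of k=0)
            from lifresponse.core import x_threshold_distance
            hist = np.array([block[1], [0, 0]], dtype=np.uint8).T
            raster = SpikeRaster(hist, n_min=0)
            x = x_threshold_distance(p, raster, None, 0, 0)
            a1, b1 = derivative_a_b(1, x)
            return (a1 if block[0, 0] else b1) / sig

        coeffs = hc_decompose(zeta_block, 2, 2)
        l = monomial_index(Monomial([(0, 0)]), 2, 2)
        assert kern.scale == pytest.approx(coeffs[l], rel=1e-12)

    def test_trace_within_dropped_coefficient_bound(self, tiny_params,
                                                    tiny_spont):
        # hc1 differs from order1 by the dropped (state-dependent) part of
        # zeta; Cauchy-Schwarz bounds every kernel-entry difference by
        # sd(f) * max|zeta_res|, which bounds the trace difference through
        # the same convolution
        f = Monomial([(1, 0)])
        depth = 5
        stim = tiny_pulse_stimulus(0.2, t_steps=40)
        t_o1 = predict_order1(kernel_order1(f, tiny_spont, depth), stim, 40)
        t_hc = predict_hc1(f, tiny_spont, tiny_params, stim, depth)
        p = tiny_params
        kern = kernel_hc1(f, tiny_spont, depth)
        # residual susceptibility over the 8 relevant (pattern, spike) combos
        from lifresponse.core import x_threshold_distance
        res = []
        for bits in range(8):
            pat = np.array([bits & 1, (bits >> 1) & 1], dtype=np.uint8)
            spike = (bits >> 2) & 1
            raster = SpikeRaster(np.stack([pat, [0, 0]], axis=1))
            x = x_threshold_distance(p, raster, None, 0, 0)
            a1, b1 = derivative_a_b(1, x)
            z = (a1 if spike else b1) / p.sigma_b
            res.append(z - kern.scale * spike)
        res = np.asarray(res)
        max_res = np.abs(res - res.mean()).max()
        h = int(kern.horizons.max())
        bound = 0.5 * max_res * (depth + 1) * (h + 1) * stim.values.max() * 2
        assert np.abs(t_hc.values - t_o1.values).max() <= bound

    def test_hc1_linearity_and_causality(self, tiny_params, tiny_spont):
        f = Monomial([(1, 0)])
        a = predict_hc1(f, tiny_spont, tiny_params,
                        tiny_pulse_stimulus(0.1, t_steps=40), 5)
        b = predict_hc1(f, tiny_spont, tiny_params,
                        tiny_pulse_stimulus(0.2, t_steps=40), 5)
        assert np.allclose(b.values, 2 * a.values, rtol=1e-12, atol=1e-15)
        assert np.all(a.values[:6] == 0.0)


class TestGeneralResponse:
    def test_null_perturbation(self, tiny_spont):
        f = Monomial([(0, 0)])
        trace = general_response(f, lambda r, e: np.zeros(e.n_trials),
                                 tiny_spont, (10, 30), depth=5)
        assert np.all(trace.values == 0.0)

    def test_constant_perturbation_is_centred_away(self, tiny_spont):
        f = Monomial([(0, 0)])
        trace = general_response(f, lambda r, e: np.full(e.n_trials, 3.7),
                                 tiny_spont, (10, 30), depth=5)
        assert np.allclose(trace.values, 0.0, atol=1e-12)

    def test_consistency_with_order1_predictor(self, tiny_params):
        f = Monomial([(1, 0)])
        depth = 5
        stim = tiny_pulse_stimulus(0.2, t_steps=40)
        ens = lr.simulate_ensemble(tiny_params, None, 40, 10, 40000,
                                   master_seed=71)
        kern = kernel_order1(f, ens, depth)
        pred = predict_order1(kern, stim, 40)
        dphi = lif_delta_phi_order1(tiny_params, ens, stim, kern.horizons)
        gen = general_response(f, dphi, ens, (8, 39), depth)
        diff = np.abs(gen.values - pred.values[gen.times]).max()
        peak = np.abs(pred.values).max()
        assert diff < 0.15 * peak


class TestValidityDiagnostics:
    def test_zero_stimulus_no_violations(self, tiny_params):
        stim = tiny_pulse_stimulus(0.0, t_steps=40)
        ens = lr.simulate_ensemble(tiny_params, stim, 40, 5, 200, 81)
        diag = validity_diagnostics(tiny_params, ens, stim)
        assert diag["smallness_violation_fraction"] == 0.0
        assert diag["max_abs_delta_x"] == 0.0

    def test_violations_increase_with_amplitude(self, tiny_params):
        fracs = []
        for amp in (0.2, 0.8, 2.0):
            stim = tiny_pulse_stimulus(amp, t_steps=40)
            ens = lr.simulate_ensemble(tiny_params, stim, 40, 5, 200, 82)
            diag = validity_diagnostics(tiny_params, ens, stim)
            fracs.append(diag["smallness_violation_fraction"])
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[0]

    def test_smallness_bound_maximal_near_threshold(self):
        xs = np.linspace(-4, 4, 401)
        a1, b1 = derivative_a_b(1, xs)
        bound = 2 * np.minimum(np.abs(xs + a1), np.abs(xs + b1))
        assert abs(xs[np.argmax(bound)]) < 0.3
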