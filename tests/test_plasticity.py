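"""The three learning rules against scalar reference implementations."""

import math

import numpy as np
import pytest

from bgexplore import plasticity
from bgexplore.plasticity import (
    DaStdpParameters,
    HomeostaticParameters,
    HomeostaticTraces,
    StdpTraces,
    update_da_stdp,
    update_sc_stdp,
    update_stn_gpe,
)

DT = 0.1


def scalar_da_stdp(pre_train, post_train, da_train, params, dt=DT):
    """Plain-Python single-synapse reference for the dopamine rule."""
    Apre = Apost = E = 0.0
    w = 0.0
    dpre = math.exp(-dt / params.tau_pre)
    dpost = math.exp(-dt / params.tau_post)
    dE = math.exp(-dt / params.tau_E)
    for xpre, xpost, da in zip(pre_train, post_train, da_train):
        Apre = Apre * dpre + params.delta_pre * xpre
        Apost = Apost * dpost + params.delta_post * xpost
        E = E * dE + xpost * Apre - xpre * Apost
        dw = params.alpha * params.da_sign * da * E * dt - params.delta_norm * xpre
        w = min(max(w + dw, -np.inf), np.inf)
    return w, E


class TestDaStdp:
    def test_no_dopamine_no_presynaptic_spike_no_change(self):
        params = DaStdpParameters()
        traces = StdpTraces.zeros(1, 1)
        traces.E[0, 0] = 5.0
        w = np.array([[0.3]])
        traces, w2 = update_da_stdp(
            traces, np.zeros(1), np.zeros(1), 0.0, w, params
        )
        assert w2[0, 0] == pytest.approx(0.3, abs=1e-12)

    @pytest.mark.parametrize("da_sign, direction", [(+1, 1), (-1, -1)])
    def test_pre_post_pair_with_dopamine_sign_structure(self, da_sign, direction):
        """A causal pre-then-post pairing plus a dopamine burst potentiates
        D1-type synapses and depresses D2-type synapses."""
        params = DaStdpParameters(da_sign=da_sign, alpha=1.0, w_min=-np.inf)
        traces = StdpTraces.zeros(1, 1)
        w = np.array([[0.5]])
        traces, w = update_da_stdp(traces, np.ones(1), np.zeros(1), 0.0, w, params)
        for _ in range(100):  # 10 ms gap
            traces, w = update_da_stdp(traces, np.zeros(1), np.zeros(1), 0.0, w, params)
        traces, w = update_da_stdp(traces, np.zeros(1), np.ones(1), 0.0, w, params)
        assert traces.E[0, 0] > 0
        w0 = w[0, 0]
        traces, w = update_da_stdp(traces, np.zeros(1), np.zeros(1), 0.5, w, params)
        assert direction * (w[0, 0] - w0) > 0

    def test_matches_scalar_reference_on_random_trains(self):
        rng = np.random.default_rng(42)
        n = 3000
        pre = (rng.random(n) < 0.02).astype(float)
        post = (rng.random(n) < 0.03).astype(float)
        da = np.where(np.arange(n) > 2000, 0.2 * np.exp(-(np.arange(n) - 2000) / 190.0), 0.0)
        params = DaStdpParameters(alpha=0.01, delta_norm=1e-4, da_sign=+1,
                                  w_min=-np.inf)
        w_ref, E_ref = scalar_da_stdp(pre, post, da, params)

        traces = StdpTraces.zeros(1, 1)
        w = np.zeros((1, 1))
        for k in range(n):
            traces, w = update_da_stdp(
                traces, pre[k : k + 1], post[k : k + 1], da[k], w, params
            )
        assert w[0, 0] == pytest.approx(w_ref, abs=1e-12)
        assert traces.E[0, 0] == pytest.approx(E_ref, abs=1e-12)


class TestScStdp:
    def test_no_spikes_no_change(self):
        params = DaStdpParameters()
        traces = StdpTraces.zeros(2, 2, eligibility=False)
        w = np.full((2, 2), 0.1)
        traces, w2 = update_sc_stdp(traces, np.zeros(2), np.zeros(2), w, params)
        assert np.allclose(w2, 0.1, atol=1e-12)

    def test_stdp_sign_convention(self):
        params = DaStdpParameters(alpha=1.0, w_min=-np.inf)
        # pre then post -> LTP
        traces = StdpTraces.zeros(1, 1, eligibility=False)
        w = np.zeros((1, 1))
        traces, w = update_sc_stdp(traces, np.ones(1), np.zeros(1), w, params)
        for _ in range(50):
            traces, w = update_sc_stdp(traces, np.zeros(1), np.zeros(1), w, params)
        traces, w = update_sc_stdp(traces, np.zeros(1), np.ones(1), w, params)
        assert w[0, 0] > 0
        # post then pre -> LTD
        traces = StdpTraces.zeros(1, 1, eligibility=False)
        w = np.zeros((1, 1))
        traces, w = update_sc_stdp(traces, np.zeros(1), np.ones(1), w, params)
        for _ in range(50):
            traces, w = update_sc_stdp(traces, np.zeros(1), np.zeros(1), w, params)
        traces, w = update_sc_stdp(traces, np.ones(1), np.zeros(1), w, params)
        assert w[0, 0] < 0

    def test_matches_scalar_reference(self):
        rng = np.random.default_rng(3)
        n = 2000
        pre = (rng.random(n) < 0.03).astype(float)
        post = (rng.random(n) < 0.03).astype(float)
        params = DaStdpParameters(alpha=0.5, delta_norm=1e-3, w_min=-np.inf)

        Apre = Apost = 0.0
        w_ref = 0.0
        dpre = math.exp(-DT / params.tau_pre)
        dpost = math.exp(-DT / params.tau_post)
        for xpre, xpost in zip(pre, post):
            Apre = Apre * dpre + params.delta_pre * xpre
            Apost = Apost * dpost + params.delta_post * xpost
            w_ref += params.alpha * (xpost * Apre - xpre * Apost) - params.delta_norm * xpre

        traces = StdpTraces.zeros(1, 1, eligibility=False)
        w = np.zeros((1, 1))
        for k in range(n):
            traces, w = update_sc_stdp(traces, pre[k:k+1], post[k:k+1], w, params)
        assert w[0, 0] == pytest.approx(w_ref, abs=1e-12)


class TestHomeostaticRule:
    def drive(self, traces, w, params, steps, p_pre, p_post, da, rng):
        for _ in range(steps):
            pre = (rng.random(1) < p_pre).astype(float)
            post = (rng.random(1) < p_post).astype(float)
            traces, w = update_stn_gpe(traces, pre, post, da, w, params)
        return traces, w

    def test_nonpositive_dopamine_freezes_weights(self):
        params = HomeostaticParameters()
        traces = HomeostaticTraces.zeros(1, 1)
        w = np.array([[params.w_init]])
        rng = np.random.default_rng(0)
        for da in (0.0, -0.3):
            _, w2 = self.drive(traces, w.copy(), params, 500, 0.05, 0.05, da, rng)
            assert np.array_equal(w2, w)

    def test_deadband_means_no_change(self):
        params = HomeostaticParameters()
        traces = HomeostaticTraces(
            A_pre=np.array([1.0]), A_post=np.array([1.0]),
            Abar_pre=np.array([1.0]), Abar_post=np.array([1.0]),
        )
        w = np.array([[params.w_init]])
        # ratios exactly 1 lie inside (0.9, 1.1): LTP = LTD = 0
        _, w2 = update_stn_gpe(
            traces, np.zeros(1), np.zeros(1), 0.25, w.copy(), params
        )
        assert w2[0, 0] == pytest.approx(params.w_init, abs=1e-15)

    def test_saturated_weight_cannot_grow(self):
        params = HomeostaticParameters()
        traces = HomeostaticTraces(
            A_pre=np.array([0.1]), A_post=np.array([0.1]),
            Abar_pre=np.array([1.0]), Abar_post=np.array([1.0]),
        )  # strong phasic decrease -> pure LTP drive
        w = np.array([[params.w_max]])
        _, w2 = update_stn_gpe(traces, np.zeros(1), np.zeros(1), 0.3, w, params)
        assert w2[0, 0] <= params.w_max

    def test_phasic_decrease_potentiates_increase_depresses(self):
        params = HomeostaticParameters(tau_w=1e4)  # fast for the test
        low = HomeostaticTraces(
            A_pre=np.array([0.5]), A_post=np.array([0.5]),
            Abar_pre=np.array([1.0]), Abar_post=np.array([1.0]),
        )
        w = np.array([[params.w_init]])
        _, w_up = update_stn_gpe(low, np.zeros(1), np.zeros(1), 0.3, w.copy(), params)
        assert w_up[0, 0] > params.w_init
        high = HomeostaticTraces(
            A_pre=np.array([2.0]), A_post=np.array([2.0]),
            Abar_pre=np.array([1.0]), Abar_post=np.array([1.0]),
        )
        _, w_down = update_stn_gpe(high, np.zeros(1), np.zeros(1), 0.3, w.copy(), params)
        assert w_down[0, 0] < params.w_init

    def test_weights_bounded_for_arbitrary_history(self):
        params = HomeostaticParameters(tau_w=1e3)  # aggressive updates
        traces = HomeostaticTraces.zeros(2, 2)
        w = np.full((2, 2), params.w_init)
        rng = np.random.default_rng(11)
        for _ in range(4000):
            pre = (rng.random(2) < 0.05).astype(float)
            post = (rng.random(2) < 0.05).astype(float)
            da = float(rng.normal(0.05, 0.2))
            traces, w = update_stn_gpe(traces, pre, post, da, w, params)
            assert np.all(w >= 0.0) and np.all(w <= params.w_max)

    def test_slow_trace_converges_to_fast_trace_mean(self):
        # 50 independent presynaptic neurons under the same constant-rate
        # drive: the population mean of Abar converges to the stationary
        # mean of A within 5% after ten slow time constants
        params = HomeostaticParameters(tau_Abar=200.0)
        n = 50
        traces = HomeostaticTraces.zeros(n, 1)
        w = np.full((n, 1), params.w_init)
        rng = np.random.default_rng(5)
        rate = 0.004  # per-step spike probability (40 Hz at dt=0.1)
        history = []
        for k in range(int(10 * params.tau_Abar / DT)):
            pre = (rng.random(n) < rate).astype(float)
            traces, w = update_stn_gpe(traces, pre, np.zeros(1), 0.0, w, params)
            if k > 5 * params.tau_Abar / DT:
                history.append(traces.A_pre.mean())
        stationary_mean = np.mean(history)
        abar = traces.Abar_pre.mean()
        assert abs(abar - stationary_mean) / stationary_mean < 0.05

    def test_zero_slow_trace_guard(self):
        # a synapse with no activity history sees no plasticity even under
        # a dopamine burst: undefined ratios count as inside the deadband
        params = HomeostaticParameters()
        traces = HomeostaticTraces.zeros(1, 1)
        w = np.array([[params.w_init]])
        for _ in range(100):
            traces, w = update_stn_gpe(
                traces, np.zeros(1), np.zeros(1), 0.3, w, params
            )
        assert w[0, 0] == pytest.approx(params.w_init, abs=1e-15)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HomeostaticParameters(deadband_lo=1.2)
        with pytest.raises(ValueError):
            HomeostaticParameters(w_init=0.002, w_max=0.001)
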