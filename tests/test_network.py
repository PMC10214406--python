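"""Circuit assembly, readout integrators, and channel-level analysis ops."""

import math

import numpy as np
import pytest

from bgexplore.config import default_config
from bgexplore.network import (
    ChannelLayout,
    SpikingAgent,
    activity_deviation,
    apply_selection_feedback,
    build_network,
    mean_channel_weight_matrix,
    run_stimulus_window,
)

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


@pytest.fixture(scope="module")
def desk_net():
    cfg = default_config("desk")
    return build_network(cfg, np.random.default_rng(7))


class TestBuild:
    def test_roster_contains_every_pathway(self, desk_net):
        expected = {
            "StrD1->SNr", "StrD2->GPe", "GPe->SNr", "GPe->STN", "STN->SNr",
            "SNr->SC", "SC->SCi", "SCi->SC", "StrD1->StrD1", "SC->StrD1",
            "SC->StrD2", "CTX->StrD1", "CTX->StrD2", "CTX->STN", "CTX->SC",
            "STN->GPe",
        }
        assert expected <= set(desk_net.roster)
        tags = {k: p.plasticity for k, p in desk_net.roster.items()}
        assert tags["CTX->StrD1"] == tags["CTX->StrD2"] == tags["CTX->STN"] == "da_stdp"
        assert tags["CTX->SC"] == "sc_stdp"
        assert tags["STN->GPe"] == "stn_gpe"

    def test_missing_projection_rejected(self):
        cfg = default_config("desk")
        del cfg["projections"]["SNr->SC"]
        with pytest.raises(ValueError, match="SNr->SC"):
            build_network(cfg, np.random.default_rng(0))

    def test_full_probability_gives_dense_mask(self):
        cfg = default_config("desk", overrides={
            "projections": {"StrD1->SNr": {"p": 1.0}},
            "layout": {"n_channels": 2},
        })
        net = build_network(cfg, np.random.default_rng(0))
        lay = net.layout
        block = net.Winh[lay.pop_slice("StrD1"), lay.pop_slice("SNr")]
        n = lay.n_per_channel
        for c in range(2):
            sub = block[c * n:(c + 1) * n, c * n:(c + 1) * n]
            assert np.all(sub > 0)
        assert np.all(block[:n, n:] == 0)  # within-channel pattern

    def test_same_seed_same_network(self):
        cfg = default_config("desk")
        a = build_network(cfg, np.random.default_rng(3))
        b = build_network(cfg, np.random.default_rng(3))
        assert np.array_equal(a.Wexc, b.Wexc)
        assert np.array_equal(a.Winh, b.Winh)
        assert np.array_equal(a.Wctx, b.Wctx)

    def test_inhibitory_and_excitatory_character_fixed_by_source(self, desk_net):
        lay = desk_net.layout
        # GPe is inhibitory: its rows in the excitatory matrix are empty
        assert np.all(desk_net.Wexc[lay.pop_slice("GPe"), :] == 0)
        # STN is excitatory: its rows in the inhibitory matrix are empty
        assert np.all(desk_net.Winh[lay.pop_slice("STN"), :] == 0)
        assert np.all(desk_net.Wexc >= 0) and np.all(desk_net.Winh >= 0)


class TestChannelMatrix:
    layout = ChannelLayout(n_channels=5, n_per_channel=4, n_cortex=4)

    def test_uniform_weights_give_constant_matrix(self):
        W = np.full((20, 20), 0.5)
        M = mean_channel_weight_matrix(W, self.layout)
        assert M.shape == (5, 5)
        assert np.allclose(M, 0.5, atol=1e-15)

    def test_single_synapse_locality(self):
        W = np.full((20, 20), 0.1)
        W[1 * 4 + 2, 3 * 4 + 1] += 1.0  # channel (1, 3) block
        M = mean_channel_weight_matrix(W, self.layout)
        assert M[1, 3] == pytest.approx(0.1 + 1.0 / 16)
        mask = np.ones((5, 5), bool)
        mask[1, 3] = False
        assert np.allclose(M[mask], 0.1, atol=1e-15)

    def test_matches_brute_force_block_means(self):
        rng = np.random.default_rng(5)
        W = rng.random((20, 20))
        M = mean_channel_weight_matrix(W, self.layout)
        for i in range(5):
            for j in range(5):
                block = W[i * 4:(i + 1) * 4, j * 4:(j + 1) * 4]
                assert M[i, j] == pytest.approx(block.mean(), rel=1e-12)


class TestActivityDeviation:
    def test_stationary_counts_deviate_little(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(20000, 3))
        dev = activity_deviation(counts, 500.0, dt_ms=0.1)
        assert np.all(np.abs(dev) < 0.05)

    def test_rate_doubling_inside_window(self):
        T, w0, wlen = 40000, 5000, 3000
        counts = np.full((T, 1), 2.0)
        counts[w0:w0 + wlen] = 4.0
        dev = activity_deviation(counts, w0 * 0.1, dt_ms=0.1, window_len_ms=wlen * 0.1)
        total_mean = (2 * (T - wlen) + 4 * wlen) / T
        assert dev[0] == pytest.approx((4 - total_mean) / total_mean, rel=1e-9)

    def test_silent_population_reported_missing(self):
        counts = np.zeros((1000, 2))
        counts[:, 0] = 1.0
        dev = activity_deviation(counts, 10.0, dt_ms=0.1)
        assert np.isnan(dev[1]) and not np.isnan(dev[0])


class TestReadout:
    def test_integrator_matches_hand_simulation_of_recorded_raster(self):
        """The engine's threshold crossing equals an independent integrator
        pass over the recorded SC spike raster."""
        cfg = default_config("desk")
        net = build_network(cfg, np.random.default_rng(11))
        net.run_window(250.0, np.random.default_rng(12))
        state = net.get_state()
        intg = net.integrator

        # run once with early stopping
        net.integrator.value[:] = 0.0
        res_stop = net.run_window(
            800.0, np.random.default_rng(99), ctx_on=True, stop_at_threshold=True
        )

        # replay the identical window (same state, identical rng stream) and
        # record the raster without stopping
        net.set_state(state)
        net.integrator.value[:] = 0.0
        res_full = net.run_window(
            800.0, np.random.default_rng(99), ctx_on=True, record_raster=True
        )

        lay = net.layout
        sc = res_full.raster[:, lay.pop_slice("SC")]
        per_channel = sc.reshape(sc.shape[0], 5, lay.n_per_channel).sum(axis=2)
        decay = math.exp(-net.dt / intg.tau_ms)
        value = np.zeros(5)
        crossed, step = -1, -1
        for t in range(per_channel.shape[0]):
            value = value * decay + intg.increment * per_channel[t]
            hit = np.nonzero(value >= intg.threshold)[0]
            if hit.size:
                crossed, step = int(hit[0]), t
                break
        assert crossed == res_stop.selection
        assert step == res_stop.step

    def test_silencing_one_snr_channel_selects_its_target(self):
        """Disinhibition: forcing one SNr sub-population silent makes its SC
        channel win the integrator race."""
        hits = 0
        for seed in range(4):
            cfg = default_config("desk")
            net = build_network(cfg, np.random.default_rng(100 + seed))
            lay = net.layout
            snr = lay.pop_slice("SNr")
            ch = 2
            sl = slice(snr.start + ch * lay.n_per_channel,
                       snr.start + (ch + 1) * lay.n_per_channel)
            net.Ibase[sl] = -100.0  # clamp this SNr sub-population silent
            rng = np.random.default_rng(200 + seed)
            net.run_window(250.0, rng)
            sel, _, _ = run_stimulus_window(net, rng)
            hits += sel == ch
        assert hits >= 3

    def test_selection_none_when_collicular_output_suppressed(self):
        cfg = default_config("desk")
        net = build_network(cfg, np.random.default_rng(5))
        lay = net.layout
        net.Ibase[lay.pop_slice("SC")] = -200.0  # SC cannot fire at all
        rng = np.random.default_rng(6)
        net.run_window(250.0, rng)
        sel, latency, _ = run_stimulus_window(net, rng)
        assert sel is None
        assert latency == float(net.config["timing"]["max_stimulus_ms"])

    def test_at_most_one_selection_per_window(self):
        cfg = default_config("desk")
        net = build_network(cfg, np.random.default_rng(21))
        rng = np.random.default_rng(22)
        net.run_window(250.0, rng)
        sel, _, res = run_stimulus_window(net, rng)
        if sel is not None and res.selection >= 0:
            # stopped at the crossing step: no later spikes were simulated
            assert res.counts.shape[0] == res.step + 1


class TestSelectionFeedback:
    def test_feedback_drives_selected_striatal_channel(self):
        # the feedback window follows an actual selection, as in the trial
        # loop: the selected channel's striatal sub-populations dominate
        cfg = default_config("desk")
        net = build_network(cfg, np.random.default_rng(31))
        rng = np.random.default_rng(32)
        net.run_window(250.0, rng)
        sel, _, _ = run_stimulus_window(net, rng)
        assert sel is not None
        apply_selection_feedback(net, sel)
        res = net.run_window(
            380.0, rng, feedback_channel=sel, feedback_until_ms=300.0
        )
        rates = net.mean_rates(res.counts)
        for pop in ("StrD1", "StrD2"):
            others = [c for c in range(5) if c != sel]
            assert rates[pop][sel] > max(rates[pop][others]) + 5.0

    def test_none_selection_is_noop(self):
        cfg = default_config("desk")
        net = build_network(cfg, np.random.default_rng(31))
        out = apply_selection_feedback(net, None)
        assert out.feedback_channel is None

    def test_zero_feedback_gain_leaves_rates_flat(self):
        cfg = default_config("desk", overrides={"feedback": {"rate_hz": 0.0}})
        net = build_network(cfg, np.random.default_rng(31))
        rng = np.random.default_rng(32)
        net.run_window(250.0, rng)
        res = net.run_window(380.0, rng, feedback_channel=2, feedback_until_ms=300.0)
        rates = net.mean_rates(res.counts)
        assert rates["StrD1"].max() < 2.0  # striatum silent without drive


class TestRestingState:
    def test_population_activity_profile(self, desk_net):
        """Without cortical input: striatum silent, SNr strongly tonic, GPe
        tonic, STN moderate, SC gated off by SNr inhibition."""
        rng = np.random.default_rng(42)
        res = desk_net.run_window(1200.0, rng)
        rates = {k: v.mean() for k, v in desk_net.mean_rates(res.counts).items()}
        assert rates["StrD1"] < 2.0 and rates["StrD2"] < 2.0
        assert rates["SNr"] > 40.0
        assert 15.0 < rates["GPe"] < 80.0
        assert 2.0 < rates["STN"] < 40.0
        assert rates["SC"] < 5.0
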