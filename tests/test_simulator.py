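"""Markov gating simulator: determinism, stationary statistics, ground truth."""

import numpy as np
import pytest

from tim23ephys import (
    ChannelModel,
    Protocol,
    RecordingMeta,
    default_model,
    ghk_reversal,
    reversal_potential,
    simulate_trace,
)
from tim23ephys.simulator import (
    expected_event_rate,
    simulate_states,
    stationary_distribution,
    stationary_open_probability,
)


class TestDefaultModel:
    def test_variant_contrasts(self):
        wt = default_model("wildtype")
        mut = default_model("N150A")
        # substrate activation factors 50 vs 6
        assert wt.flicker_amax == 50
        assert mut.flicker_amax == 6
        # mutant cation preference is 33% of wild type
        assert mut.pk_over_pcl == pytest.approx(0.33 * wt.pk_over_pcl)
        # conductance states and gating rates are shared
        assert mut.levels_pS == wt.levels_pS
        assert mut.rate_matrix == wt.rate_matrix
        assert (mut.v_half_mV, mut.v_slope_mV) == (wt.v_half_mV, wt.v_slope_mV)

    def test_transition_amplitudes_from_open(self):
        # partial and full closures from the 460 pS open level give the three
        # conductance-change classes 460 / 170 / 60 pS
        wt = default_model("wildtype")
        g = np.asarray(wt.levels_pS)
        amplitudes = sorted(g.max() - g[g < g.max()], reverse=True)
        assert amplitudes == [460.0, 170.0, 60.0]

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            default_model("G153L")


class TestReversalPotential:
    def test_symmetric_buffers_zero(self, wt_model, sym_meta):
        assert reversal_potential(wt_model, sym_meta) == pytest.approx(0.0)

    def test_pure_cation_limit(self, asym_meta):
        model = ChannelModel(pk_over_pcl=1e12)
        # (RT/F) ln 12.5 at 298.15 K
        assert reversal_potential(model, asym_meta) == pytest.approx(64.892, abs=0.01)

    def test_nonselective_zero(self, asym_meta):
        model = ChannelModel(pk_over_pcl=1.0)
        assert reversal_potential(model, asym_meta) == pytest.approx(0.0)


class TestSimulateTrace:
    def test_frozen_channel_constant_current(self):
        # open channel, no gating, no noise: I = 0.460 nS * 80 mV = 36.8 pA
        model = ChannelModel(
            rate_matrix=tuple(tuple(0.0 for _ in range(4)) for _ in range(4)),
            noise_sd_pA=0.0,
        )
        protocol = Protocol(voltage_mV=80.0, duration_s=1.0)
        trace, gt = simulate_trace(model, protocol, seed=3, initial_state=3)
        assert np.allclose(trace.samples, 36.8)
        # with zero rates the path never leaves its initial state
        assert gt.n_events == 0

    def test_seed_determinism(self, wt_model):
        protocol = Protocol(voltage_mV=80.0, duration_s=5.0, substrate_uM=0.3)
        t1, g1 = simulate_trace(wt_model, protocol, seed=42)
        t2, g2 = simulate_trace(wt_model, protocol, seed=42)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(g1.jump_times_s, g2.jump_times_s)
        t3, _ = simulate_trace(wt_model, protocol, seed=43)
        assert not np.array_equal(t1.samples, t3.samples)

    def test_two_state_occupancy_half(self):
        # k_open == k_close: long-run open fraction 0.5
        model = ChannelModel(
            levels_pS=(0.0, 460.0),
            rate_matrix=((0.0, 5.0), (5.0, 0.0)),
            v_half_mV=80.0,  # closure rate unscaled at the holding potential
            noise_sd_pA=0.0,
        )
        _, gt = simulate_trace(model, Protocol(voltage_mV=80.0, duration_s=400.0), seed=9)
        occ = gt.occupancy()
        assert occ[1] == pytest.approx(0.5, abs=0.03)

    def test_ground_truth_event_count_and_amplitudes(self, wt_model):
        _, gt = simulate_trace(wt_model, Protocol(voltage_mV=80.0, duration_s=30.0), seed=5)
        assert gt.n_events == len(gt.states) - 1
        assert gt.n_events == len(gt.event_amplitudes_pS)
        # star topology: every event touches the open level
        assert np.all(np.abs(gt.event_amplitudes_pS) >= 60)

    def test_mean_current_matches_stationary_mixture(self, wt_model, sym_meta):
        model = wt_model.model_copy(update={"noise_sd_pA": 0.0})
        protocol = Protocol(voltage_mV=80.0, duration_s=2000.0, sample_rate_Hz=1000.0)
        trace, _ = simulate_trace(model, protocol, seed=21)
        q = model.effective_rate_matrix(80.0)
        pi = stationary_distribution(q)
        expected = float(pi @ np.asarray(model.levels_pS)) * 80.0 * 1e-3
        assert np.mean(trace.samples) == pytest.approx(expected, rel=0.05)


class TestStationaryMachinery:
    def test_occupancy_converges_to_stationary(self, wt_model):
        # total-variation distance < 0.02 after 1e5 exact jumps
        q = wt_model.effective_rate_matrix(80.0)
        rng = np.random.default_rng(17)
        times, states = simulate_states(q, np.inf, rng, max_jumps=100_000)
        dwell = np.diff(times)  # completed dwells only
        occ = np.zeros(q.shape[0])
        np.add.at(occ, states[:-1], dwell)
        occ /= occ.sum()
        pi = stationary_distribution(q)
        assert 0.5 * np.abs(occ - pi).sum() < 0.02

    def test_substrate_scales_event_rate_not_occupancy(self, wt_model):
        # symmetric scaling of the flicker pairs: occupancies invariant,
        # event rate scaled by (almost exactly) the activation factor
        base = expected_event_rate(wt_model, 80.0)
        sat = expected_event_rate(wt_model, 80.0, substrate_uM=1e4)
        assert sat / base == pytest.approx(wt_model.flicker_amax, rel=0.05)
        q0 = wt_model.effective_rate_matrix(80.0)
        q1 = wt_model.effective_rate_matrix(80.0, substrate_uM=1e4)
        assert np.allclose(stationary_distribution(q0), stationary_distribution(q1))

    def test_voltage_closure_follows_boltzmann(self):
        # two-state open/closed model: stationary Po(V) is the Boltzmann curve
        model = ChannelModel(
            levels_pS=(0.0, 460.0),
            rate_matrix=((0.0, 1.0), (1.0, 0.0)),
            v_half_mV=120.0, v_slope_mV=15.0,
        )
        for v in (60.0, 100.0, 120.0, 150.0):
            po = stationary_open_probability(model, v)
            expected = 1.0 / (1.0 + np.exp((v - 120.0) / 15.0))
            assert po == pytest.approx(expected, abs=1e-9)

    def test_tim50_shifts_midpoint(self, wt_model):
        po_without = stationary_open_probability(wt_model, 100.0)
        po_with = stationary_open_probability(wt_model, 100.0, tim50_present=True)
        assert po_with < po_without  # receptor promotes closure


class TestSimulateIV:
    def test_unsorted_voltages_rejected(self, wt_model, asym_meta):
        from tim23ephys import simulate_iv

        with pytest.raises(ValueError):
            simulate_iv(wt_model, [0.0, -10.0, 10.0], asym_meta, seed=0)

    def test_noiseless_symmetric_is_ohmic(self, wt_model, sym_meta):
        from tim23ephys import simulate_iv

        model = wt_model.model_copy(update={"noise_sd_pA": 0.0})
        v = np.arange(-60.0, 61.0, 20.0)
        iv = simulate_iv(model, v, sym_meta, seed=0)
        i = iv.points["mean_current_pA"].to_numpy()
        assert np.allclose(i, 0.460 * v)  # through the origin, slope g_open
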