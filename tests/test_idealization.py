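"""Change-point idealization: exact recovery, oracle optimality, robustness."""

import numpy as np
import pytest

from tim23ephys import (
    ChannelModel,
    IdealizeParams,
    Protocol,
    idealize,
    residual_sd,
    simulate_trace,
)
from tim23ephys._pelt import pelt_changepoints
from tim23ephys.errors import MetadataError, Tim23EphysError

from conftest import make_step_trace


def exhaustive_changepoints(x, penalty):
    """O(n^2) dynamic program over *all* segmentations — the independent
    optimality oracle for the PELT search (no pruning, no recursion sharing
    beyond the textbook Bellman form)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    css = np.concatenate(([0.0], np.cumsum(x * x)))
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        s = np.arange(t)
        d = cs[t] - cs[s]
        cost = np.maximum(css[t] - css[s] - d * d / (t - s), 0.0)
        v = F[s] + cost + penalty
        best = int(np.argmin(v))
        F[t] = v[best]
        last[t] = best
    cps = []
    t = n
    while t > 0:
        t = last[t]
        if t > 0:
            cps.append(t)
    return np.array(sorted(cps), dtype=int)


class TestPeltCore:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        # random short traces with up to 4 true steps
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 2000))
        k = int(rng.integers(0, 5))
        bounds = np.sort(rng.choice(np.arange(20, n - 20), k, replace=False))
        levels = rng.uniform(-20, 20, k + 1)
        x = np.empty(n)
        for i, (a, b) in enumerate(zip(np.r_[0, bounds], np.r_[bounds, n])):
            x[a:b] = levels[i]
        x += rng.normal(0, 2.0, n)
        penalty = 3 * 4.0 * np.log(n)
        assert np.array_equal(
            pelt_changepoints(x, penalty, grid=1),
            exhaustive_changepoints(x, penalty),
        )

    def test_noiseless_step_exact(self):
        trace = make_step_trace([0.0, 36.8], [0.5, 0.5])
        ideal = idealize(trace)
        assert ideal.n_segments == 2
        assert ideal.segments["start_s"].iloc[1] == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(ideal.levels, [0.0, 36.8], atol=1e-9)

    def test_constant_noisy_trace_single_segment(self):
        trace = make_step_trace([5.0], [5.0], noise_sd=2.0, seed=1)
        ideal = idealize(trace)
        assert ideal.n_segments == 1
        assert ideal.levels[0] == pytest.approx(5.0, abs=0.1)


class TestIdealize:
    def test_transition_recovery_vs_ground_truth(self):
        # ~200 true transitions, step 14 pA in sd-2 noise (SNR ~ 7):
        # >= 95% recovered within +-2 ms, level error < 1 pA
        # v_half at the holding potential: closure rate unscaled
        model = ChannelModel(
            levels_pS=(0.0, 175.0),
            rate_matrix=((0.0, 10.0), (10.0, 0.0)),
            v_half_mV=80.0,
        )
        trace, gt = simulate_trace(model, Protocol(voltage_mV=80.0, duration_s=20.0), seed=8)
        # keep only transitions whose flanking dwells are resolvable
        dwell = np.diff(np.append(gt.jump_times_s, gt.duration_s))
        ok = (dwell[:-1] > 2e-3) & (dwell[1:] > 2e-3)
        true_times = gt.event_times_s[ok]
        assert len(true_times) > 150

        ideal = idealize(trace)
        found = ideal.segments["start_s"].to_numpy()[1:]
        hits = sum(np.min(np.abs(found - t)) <= 2e-3 for t in true_times)
        assert hits / len(true_times) >= 0.95
        for level in ideal.levels:
            assert min(abs(level - 0.0), abs(level - 14.0)) < 1.0

    def test_idempotent_on_piecewise_constant(self):
        trace = make_step_trace([0.0, 20.0, 5.0, 30.0], [0.3, 0.2, 0.25, 0.25])
        first = idealize(trace)
        again = idealize(
            make_step_trace(list(first.levels), list(first.durations))
        )
        assert again.n_segments == first.n_segments
        assert np.allclose(again.levels, first.levels)
        assert np.allclose(again.durations, first.durations)

    def test_penalty_monotonicity(self):
        trace = make_step_trace(
            [0.0, 15.0, 3.0, 25.0, 10.0], [0.2] * 5, noise_sd=2.0, seed=3
        )
        counts = []
        for penalty in (2.0, 20.0, 200.0, 2000.0, 20000.0):
            ideal = idealize(trace, IdealizeParams(penalty=penalty))
            counts.append(ideal.n_segments)
        assert counts == sorted(counts, reverse=True)

    def test_short_trace_rejected(self):
        with pytest.raises(Tim23EphysError):
            idealize(make_step_trace([1.0], [0.0005]))  # 5 samples

    def test_min_dwell_merges_short_blips(self):
        # a 0.3 ms blip is below the 0.5 ms dead time and must be absorbed
        trace = make_step_trace([0.0, 36.8, 0.0], [0.5, 0.0003, 0.5])
        ideal = idealize(trace)
        assert ideal.n_segments == 1

    def test_min_step_merges_close_levels(self):
        trace = make_step_trace([0.0, 1.0, 0.0], [0.3, 0.3, 0.3])
        ideal = idealize(trace, IdealizeParams(penalty=1e-4))
        assert ideal.n_segments == 1  # 1 pA < default 1.5 pA floor


class TestResidualSd:
    def test_noiseless_zero(self):
        trace = make_step_trace([0.0, 36.8], [0.5, 0.5])
        assert residual_sd(trace, idealize(trace)) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_injected_noise(self):
        trace = make_step_trace([0.0, 20.0, 40.0], [2.0, 2.0, 2.0],
                                noise_sd=2.0, seed=11)
        assert residual_sd(trace, idealize(trace)) == pytest.approx(2.0, rel=0.05)

    def test_estimate_independent_of_segment_count(self):
        # same noise level, different gating activity: sigma-hat agrees
        sds = []
        for levels, durs in [
            ([10.0], [4.0]),
            ([0.0, 20.0, 0.0, 20.0], [1.0] * 4),
            ([0.0, 15.0, 30.0, 15.0, 0.0, 30.0], [0.7] * 6),
        ]:
            trace = make_step_trace(levels, durs, noise_sd=2.0, seed=13)
            sds.append(residual_sd(trace, idealize(trace)))
        assert np.ptp(sds) < 0.1

    def test_mismatched_meta_rejected(self):
        t1 = make_step_trace([0.0, 36.8], [0.5, 0.5])
        t2 = make_step_trace([0.0, 36.8], [0.5, 0.5], sample_rate=5000.0)
        with pytest.raises(MetadataError):
            residual_sd(t1, idealize(t2))
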