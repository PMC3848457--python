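"""Tests for loss smoothing, thresholding, voting and post-processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindar import EventList
from spindar.detect import (
    LossTrace,
    default_threshold_grid,
    detect_events,
    optimize_threshold,
    postprocess_events,
    smooth_loss,
    threshold_events,
    vote_channels,
)


def trace(psi, fs=1.0, channel="ch0", window=5):
    psi = np.asarray(psi, dtype=float)
    return LossTrace(channel, fs, psi, smooth_loss(psi, window))


class TestSmoothLoss:
    def test_center_is_window_mean(self):
        out = smooth_loss(np.array([1.0, 2, 3, 4, 5]), 5)
        assert out[2] == pytest.approx(3.0)

    def test_constant_is_fixed_point(self):
        out = smooth_loss(np.full(20, 7.0), 5)
        np.testing.assert_allclose(out, 7.0)

    def test_isolated_spike_attenuated_five_fold(self):
        out = smooth_loss(np.array([0.0, 0, 10, 0, 0]), 5)
        assert out[2] == pytest.approx(2.0)

    def test_edges_use_shrunken_windows(self):
        out = smooth_loss(np.array([1.0, 2, 3, 4, 5]), 5)
        assert out[0] == pytest.approx(np.mean([1, 2, 3]))
        assert out[-1] == pytest.approx(np.mean([3, 4, 5]))

    @pytest.mark.parametrize("w", [0, 2, 4])
    def test_rejects_even_or_zero_window(self, w):
        with pytest.raises(ValueError):
            smooth_loss(np.zeros(10), w)

    def test_rejects_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            smooth_loss(np.zeros(3), 5)


class TestThresholdEvents:
    def test_all_below_threshold_gives_empty(self):
        assert len(threshold_events(trace(np.zeros(10)), 0.1)) == 0

    def test_run_length_extraction(self):
        t = LossTrace("c", 1.0, np.array([0.0, 0, 5, 5, 0]),
                      np.array([0.0, 0, 5, 5, 0]))
        ev = threshold_events(t, 1.0)
        assert list(ev) == [(2.0, 4.0)]

    def test_threshold_below_minimum_spans_everything(self):
        t = LossTrace("c", 2.0, np.full(8, 3.0), np.full(8, 3.0))
        ev = threshold_events(t, 1.0)
        assert list(ev) == [(0.0, 4.0)]


class TestVoteChannels:
    def test_third_of_six_channels_requires_two(self):
        masks = np.zeros((6, 4), dtype=bool)
        masks[0, 1] = masks[1, 1] = True  # two channels agree at sample 1
        masks[2, 2] = True  # one channel alone at sample 2
        out = vote_channels(masks, 1 / 3)
        assert out.tolist() == [False, True, False, False]

    def test_no_channel_flags_nothing_passes(self):
        assert not vote_channels(np.zeros((3, 5), dtype=bool)).any()

    def test_unanimity_is_logical_and(self):
        rng = np.random.default_rng(0)
        masks = rng.random((4, 50)) < 0.5
        np.testing.assert_array_equal(vote_channels(masks, 1.0), masks.all(axis=0))

    @settings(deadline=None)
    @given(st.integers(1, 8), st.integers(0, 2**32 - 1),
           st.floats(0.1, 1.0), st.floats(0.1, 1.0))
    def test_monotone_in_fraction(self, n_ch, seed, f1, f2):
        """Raising the voting fraction never adds flagged samples."""
        lo, hi = sorted((f1, f2))
        masks = np.random.default_rng(seed).random((n_ch, 30)) < 0.4
        v_lo, v_hi = vote_channels(masks, lo), vote_channels(masks, hi)
        assert not np.any(v_hi & ~v_lo)

    def test_rejects_empty_mask_set(self):
        with pytest.raises(ValueError):
            vote_channels(np.zeros((0, 5), dtype=bool))


class TestPostprocess:
    def test_small_gap_merged(self):
        ev = postprocess_events(EventList([(1.0, 1.4), (1.5, 1.9)]))
        assert list(ev) == [(1.0, 1.9)]

    def test_isolated_short_event_removed(self):
        assert len(postprocess_events(EventList([(3.0, 3.2)]))) == 0

    def test_long_event_unchanged(self):
        ev = postprocess_events(EventList([(5.0, 5.3)]))
        assert list(ev) == [(5.0, 5.3)]

    def test_short_fragment_survives_via_merge(self):
        # 200 ms fragment 100 ms from a large event: merge first, then prune
        ev = postprocess_events(EventList([(1.0, 2.0), (2.1, 2.3)]))
        assert list(ev) == [(1.0, 2.3)]

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0, 50), st.floats(0.01, 3)), max_size=15),
           st.integers(0, 2**16))
    def test_idempotent_and_disjoint(self, raw, seed):
        starts = sorted(a for a, _ in raw)
        ivs, t = [], 0.0
        for (a, d) in zip(starts, (d for _, d in raw)):
            onset = max(a, t + 1e-3)
            ivs.append((onset, onset + d))
            t = onset + d
        ev = postprocess_events(EventList(ivs))
        again = postprocess_events(ev)
        assert list(again) == list(ev)
        assert np.all(ev.intervals[1:, 0] >= ev.intervals[:-1, 1])


class TestOptimizeThreshold:
    def test_perfectly_separable_recovers_truth(self):
        fs = 10.0
        psi = np.full(200, 0.01)  # small positive background
        psi[50:60] = 5.0  # 1 s event
        psi[120:130] = 5.0
        tr = LossTrace("c", fs, psi, psi)  # pre-smoothed: use psi directly
        truth = EventList([(5.0, 6.0), (12.0, 13.0)])
        tau, curve = optimize_threshold([tr], truth, beta=2, fuzzy_s=0.0,
                                        grid=np.array([0.0, 1.0, 3.0, 6.0]))
        assert curve[curve[:, 0] == 3.0, 1][0] == pytest.approx(1.0)
        assert 0.0 < tau <= 3.0
        f_at_tau = curve[curve[:, 0] == tau, 1][0]
        assert f_at_tau == pytest.approx(1.0)

    def test_above_threshold_set_shrinks_with_tau(self):
        rng = np.random.default_rng(3)
        psi = rng.exponential(size=500)
        tr = trace(psi, fs=50.0)
        masks = [tr.psi_smooth > tau for tau in (0.1, 0.5, 1.0, 2.0)]
        for lo, hi in zip(masks, masks[1:]):
            assert not np.any(hi & ~lo)

    def test_rejects_empty_truth(self):
        tr = trace(np.ones(100))
        with pytest.raises(ValueError):
            optimize_threshold([tr], EventList(), grid=np.array([0.5]))

    def test_default_grid_is_quantile_spaced(self):
        tr = trace(np.linspace(0, 1, 1000), fs=10.0)
        grid = default_threshold_grid([tr], n=50)
        assert grid.size <= 50
        assert np.all(np.diff(grid) > 0)


class TestTrainTestProtocol:
    def test_threshold_from_first_half_transfers(self):
        """Tune tau on the first continuous half, apply unchanged to the
        second; on a stationary separable fixture both halves separate."""
        from spindar import SpindleDetector, EventList, compare_labels

        fs = 64.0
        rng = np.random.default_rng(11)
        n = int(120 * fs)
        x = rng.standard_normal(n)
        truth_iv = [(20.0 + 25 * k, 21.0 + 25 * k) for k in range(4)]
        for a, b in truth_iv:
            t = np.arange(int((b - a) * fs)) / fs
            x[int(a * fs): int(b * fs)] += 8 * np.sin(2 * np.pi * 10 * t)
        res = SpindleDetector(x[None, :], fs, ["Pz"], order=1).fit()
        first, second = res.train_test_split()
        mid_s = res.total_dur_s / 2
        truth_first = EventList([iv for iv in truth_iv if iv[1] <= mid_s])
        tau, _ = first.optimize_threshold(truth_first, beta=2.0)
        second.tau_ = tau  # protocol: apply unchanged
        ev2 = second.events()
        truth_second = EventList(
            [(a - mid_s, b - mid_s) for a, b in truth_iv if a >= mid_s]
        )
        s = compare_labels(truth_second, ev2, 0.1, second.total_dur_s, fs=fs)
        assert s.hit_rate == 1.0
        assert s.recall > 0.8


class TestPlotting:
    def test_diagnostics_plot_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        from spindar import SDAR
        from conftest import simulate_ar

        res = SDAR(simulate_ar([0.5], 500, seed=1), order=1, train_len=50).fit()
        ax = res.plot_diagnostics()
        assert len(ax) == 3


class TestEndToEnd:
    def test_separable_bursts_recovered_to_window_width(self):
        """Loss bursts far above background come back as the truth events,
        up to one smoothing-window width at each boundary."""
        fs = 100.0
        rng = np.random.default_rng(9)
        psi = 0.01 * rng.random(3000)
        truth = EventList([(5.0, 6.0), (15.0, 16.5), (25.0, 25.5)])
        for a, b in truth.intervals:
            psi[int(a * fs): int(b * fs)] = 10.0
        tr = trace(psi, fs=fs)
        ev = detect_events([tr], tau=1.0, vote_fraction=1.0)
        assert len(ev) == len(truth)
        w = 5 / fs
        for (a, b), (ta, tb) in zip(ev, truth):
            assert abs(a - ta) <= w and abs(b - tb) <= w
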