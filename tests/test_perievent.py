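"""Peri-event statistics: hand-window oracles, circular-null properties, the
two-tailed classification rule, synchrony and paired-session change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromcal as cc
from chromcal.datamodel import CalciumSession, ValidationError
from chromcal.perievent import (
    circular_null,
    classify_modulation,
    classify_session,
    merge_bouts,
    paired_session_change,
    pairwise_synchrony,
    perievent_statistic,
    rescale_traces,
    state_mean_activity,
)


def _session(traces, rate=10.0, events=None):
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    return CalciumSession(
        cell_ids=[f"c{i}" for i in range(traces.shape[0])],
        rate_hz=rate,
        traces=traces,
        events=events or [],
    )


class TestMergeBouts:
    def test_short_gap_merged(self):
        assert merge_bouts([(0.0, 1.0), (2.5, 4.0)]) == [(0.0, 4.0)]

    def test_long_gap_untouched(self):
        assert merge_bouts([(0.0, 1.0), (5.0, 6.0)]) == [(0.0, 1.0), (5.0, 6.0)]

    def test_transitive_merging(self):
        out = merge_bouts([(0.0, 1.0), (2.0, 3.0), (4.0, 5.0)])
        assert out == [(0.0, 5.0)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            merge_bouts([(5.0, 6.0), (0.0, 1.0)])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0.1, 5, allow_nan=False),
            ),
            min_size=1,
            max_size=15,
        )
    )
    def test_output_gaps_at_least_min_gap(self, raw):
        intervals = sorted((s, s + d) for s, d in raw)
        out = merge_bouts(intervals, min_gap_s=2.0)
        for (s0, e0), (s1, e1) in zip(out, out[1:]):
            assert s1 - e0 >= 2.0
            assert s1 > s0


class TestRescale:
    def test_hand_values(self):
        s = _session([[1.0, 2.0, 3.0]])
        out = rescale_traces(s)
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3 / 2)
        assert np.allclose(out.traces[0], expected, atol=1e-4)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        s = _session(rng.normal(size=(3, 100)))
        once = rescale_traces(s)
        twice = rescale_traces(once)
        assert np.allclose(once.traces, twice.traces, atol=1e-12)

    def test_constant_trace_names_cell(self):
        s = _session([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ValidationError, match="c0"):
            rescale_traces(s)


class TestPerieventStatistic:
    def test_zero_trace_gives_zero(self):
        trace = np.zeros(200)
        assert perievent_statistic(trace, [10.0], 10.0) == 0.0

    def test_unit_step_gives_one(self):
        # step to 1 at the event: post mean 1, pre mean 0 -> statistic 1
        trace = np.zeros(200)
        trace[100:] = 1.0
        assert perievent_statistic(trace, [10.0], 10.0) == pytest.approx(1.0)

    def test_hand_window_means(self):
        rate = 10.0
        trace = np.arange(200, dtype=float)
        t0 = 10.0
        post = trace[110:130].mean()
        pre = trace[70:90].mean()
        assert perievent_statistic(trace, [t0], rate) == pytest.approx(post - pre)

    def test_out_of_bounds_event_dropped_with_warning(self):
        trace = np.zeros(100)
        trace[60:] = 1.0
        with pytest.warns(UserWarning, match="dropped"):
            val = perievent_statistic(trace, [0.5, 5.0], 10.0)
        assert val == pytest.approx(1.0)

    def test_all_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            perievent_statistic(np.zeros(100), [0.5], 10.0)


class TestCircularNull:
    def test_white_noise_null_centered(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(size=6000)
        null = circular_null(trace, np.array([50.0, 200.0, 400.0]), 10.0, seed=2)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 3 * se

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(size=3000)
        a = circular_null(trace, np.array([100.0]), 10.0, n_shuffles=50, seed=7)
        b = circular_null(trace, np.array([100.0]), 10.0, n_shuffles=50, seed=7)
        assert np.array_equal(a, b)

    def test_trace_untouched_by_shuffling(self):
        rng = np.random.default_rng(4)
        trace = rng.normal(size=3000)
        before = trace.copy()
        circular_null(trace, np.array([100.0]), 10.0, n_shuffles=20, seed=0)
        assert np.array_equal(trace, before)

    def test_matches_scalar_statistic_on_same_offsets(self):
        # vectorized null equals per-shuffle recomputation via the public
        # statistic with circular indexing
        rng = np.random.default_rng(5)
        trace = rng.normal(size=2000)
        events = np.array([30.0, 90.0, 150.0])
        n = 25
        null = circular_null(trace, events, 10.0, n_shuffles=n, seed=9)
        offsets = np.random.default_rng(9).uniform(0, 200.0, size=n)
        for k in range(n):
            shifted = np.mod(events + offsets[k], 200.0)
            direct = perievent_statistic(trace, shifted, 10.0, circular=True)
            assert null[k] == pytest.approx(direct, abs=1e-12)


class TestClassification:
    def test_far_above_null_is_up(self):
        null = np.linspace(-1, 1, 1000)
        res = classify_modulation(5.0, null)
        assert res.label == "up"
        assert res.bootstrap_probability == pytest.approx(1 / 1001)

    def test_far_below_null_is_down(self):
        null = np.linspace(-1, 1, 1000)
        res = classify_modulation(-5.0, null)
        assert res.label == "down"
        assert res.bootstrap_probability == pytest.approx(1.0)

    def test_all_ties_is_non(self):
        null = np.zeros(1000)
        res = classify_modulation(0.0, null)
        assert res.label == "non"

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(-100, 100, allow_nan=False))
    def test_label_invariant_to_constant_shift(self, shift):
        rng = np.random.default_rng(6)
        null = rng.normal(size=500)
        obs = 1.2
        base = classify_modulation(obs, null)
        shifted = classify_modulation(obs + shift, null + shift)
        assert base.label == shifted.label
        assert base.bootstrap_probability == pytest.approx(
            shifted.bootstrap_probability
        )

    def test_planted_cells_recovered(self):
        spec = cc.CalciumSimSpec(
            n_cells=60, frac_up=0.2, frac_down=0.2, transient_amplitude=3.0, seed=15
        )
        session, truth = cc.simulate_calcium_session(spec)
        table = classify_session(session, n_shuffles=1000, seed=15)
        # a planted cell must never be labelled with the opposite sign
        for cell, lab in truth.modulated_cells.items():
            if lab in ("up", "down"):
                assert table.loc[cell, "label"] in (lab, "non")
        planted_up = [c for c, l in truth.modulated_cells.items() if l == "up"]
        planted_down = [c for c, l in truth.modulated_cells.items() if l == "down"]
        assert (table.loc[planted_up, "label"] == "up").mean() >= 0.75
        assert (table.loc[planted_down, "label"] == "down").mean() >= 0.75


class TestStateActivity:
    def test_constant_trace(self):
        s = _session([np.ones(100)], events=[(2.0, 4.0)])
        out = state_mean_activity(s)
        assert out.loc["c0", "in_zone"] == 1.0
        assert out.loc["c0", "out_zone"] == 1.0

    def test_step_trace_hand_means(self):
        trace = np.zeros(100)
        trace[20:40] = 2.0  # exactly the 2-4 s window at 10 Hz
        s = _session([trace], events=[(2.0, 4.0)])
        out = state_mean_activity(s)
        assert out.loc["c0", "in_zone"] == pytest.approx(2.0)
        assert out.loc["c0", "out_zone"] == pytest.approx(0.0)

    def test_empty_union_rejected(self):
        s = _session([np.ones(100)])
        with pytest.raises(ValidationError):
            state_mean_activity(s, [])


class TestSynchrony:
    def test_duplicated_and_negated_cells(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=100)
        s = _session([base, base.copy(), -base], events=[(0.0, 10.0)])
        mat, _ = pairwise_synchrony(s)
        assert mat.loc["c0", "c1"] == pytest.approx(1.0)
        assert mat.loc["c0", "c2"] == pytest.approx(-1.0)

    def test_three_cell_toy_matches_hand_pearson(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        z = np.array([5.0, 3.0, 1.0, 2.0, 4.0])
        s = _session([x, y, z], rate=1.0, events=[(0.0, 5.0)])
        mat, summary = pairwise_synchrony(s)

        def pearson(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return float((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))

        assert mat.loc["c0", "c1"] == pytest.approx(pearson(x, y), abs=1e-9)
        assert mat.loc["c0", "c2"] == pytest.approx(pearson(x, z), abs=1e-9)
        assert summary == pytest.approx(
            np.mean([pearson(x, y), pearson(x, z), pearson(y, z)]), abs=1e-9
        )

    def test_zero_variance_cell_marked_nan(self):
        s = _session(
            [np.ones(50), np.arange(50.0)], events=[(0.0, 5.0)]
        )
        mat, _ = pairwise_synchrony(s)
        assert np.isnan(mat.loc["c0", "c1"])
        assert mat.loc["c1", "c1"] == pytest.approx(1.0)


class TestPairedChange:
    def test_identical_sessions_zero(self):
        rng = np.random.default_rng(9)
        traces = rng.normal(size=(3, 200))
        pre = _session(traces, events=[(2.0, 6.0)])
        post = _session(traces.copy(), events=[(2.0, 6.0)])
        out = paired_session_change(pre, post, {"c0": "c0", "c1": "c1", "c2": "c2"})
        assert np.allclose(out["change"], 0.0, atol=1e-12)

    def test_shifted_cell_detected(self):
        rng = np.random.default_rng(10)
        traces = rng.normal(size=(2, 1000))
        pre = _session(traces, events=[(10.0, 30.0)])
        post_traces = traces.copy()
        # raise cell 0's in-zone activity by ~1 SD in the post session
        post_traces[0, 100:300] += 1.0
        post = _session(post_traces, events=[(10.0, 30.0)])
        out = paired_session_change(pre, post, {"c0": "c0", "c1": "c1"})
        assert out.loc["c0", "change"] > 0.5
        assert abs(out.loc["c1", "change"]) < 0.2

    def test_unregistered_cells_reported(self):
        rng = np.random.default_rng(11)
        traces = rng.normal(size=(2, 100))
        pre = _session(traces, events=[(1.0, 5.0)])
        post = _session(traces.copy(), events=[(1.0, 5.0)])
        out = paired_session_change(pre, post, {"c0": "c0"})
        assert out.attrs["excluded"] == ["c1"]

    def test_missing_registry_target_rejected(self):
        rng = np.random.default_rng(12)
        traces = rng.normal(size=(1, 100))
        pre = _session(traces, events=[(1.0, 5.0)])
        post = _session(traces.copy(), events=[(1.0, 5.0)])
        with pytest.raises(ValidationError):
            paired_session_change(pre, post, {"c0": "cX"})
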