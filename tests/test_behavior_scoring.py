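"""Dart/freezing/shock-response detection against hand-built traces and
an independent brute-force oracle."""

import numpy as np
import pytest

from fearframe.behavior_io import build_session_design, epoch_trace
from fearframe.behavior_scoring import (
    DartEvent,
    ScoringParams,
    block_average,
    classify_darter,
    detect_darts,
    detect_freezing,
    shock_response,
    summarize_session,
)
from fearframe.errors import DesignError

from _oracles import brute_force_darts, brute_force_freezing
from conftest import make_trace

RATE = 10.0  # compact traces for hand construction


def _base(design, rate=RATE, level=5.0):
    n = int(design.total_duration * rate)
    return np.full(n, level)


class TestDetectDarts:
    def test_constant_subthreshold_trace_has_no_darts(self, small_design):
        v = _base(small_design)
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        assert detect_darts(ep) == []

    def test_single_planted_excursion_in_cs3(self, small_design):
        v = _base(small_design)
        cs3_on = small_design.cs_onsets[2]
        i0 = int(cs3_on * RATE) + 5
        v[i0 : i0 + 5] = 25.0  # 0.5 s at 25 cm/s
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        events = detect_darts(ep)
        assert len(events) == 1
        e = events[0]
        assert e.trial_index == 3
        assert e.peak_velocity == 25.0
        assert e.onset == pytest.approx(i0 / RATE)

    def test_excursion_during_iti_is_ignored(self, small_design):
        v = _base(small_design)
        iti_start = small_design.cs_onsets[0] + small_design.cs_duration
        i0 = int(iti_start * RATE) + 10
        v[i0 : i0 + 5] = 25.0
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        assert detect_darts(ep) == []

    def test_nearby_runs_merge_into_one_event(self, small_design):
        v = _base(small_design)
        i0 = int(small_design.cs_onsets[0] * RATE) + 2
        v[i0 : i0 + 3] = 25.0
        v[i0 + 4 : i0 + 7] = 30.0  # 0.1 s gap < 0.3 s merge gap
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        events = detect_darts(ep)
        assert len(events) == 1
        assert events[0].peak_velocity == 30.0

    def test_separated_runs_stay_two_events(self, small_design):
        v = _base(small_design)
        i0 = int(small_design.cs_onsets[0] * RATE) + 2
        v[i0 : i0 + 3] = 25.0
        v[i0 + 9 : i0 + 12] = 30.0  # 0.6 s gap > 0.3 s
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        assert len(detect_darts(ep)) == 2

    def test_shock_evoked_burst_is_not_a_dart(self, small_design):
        # excursion begins at shock onset, inside the CS's final second
        v = _base(small_design)
        i0 = int(small_design.shock_onsets[0] * RATE)
        v[i0 : i0 + 5] = 60.0
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        assert detect_darts(ep) == []
        lenient = ScoringParams(exclude_shock_period_from_darts=False)
        assert len(detect_darts(ep, lenient)) == 1

    def test_straddling_excursion_counts_if_onset_inside_cs(self):
        design = build_session_design("extinction", cs_duration=5.0, iti=8.0,
                                      lead_in=6.0, n_cs=3)
        v = np.full(int(design.total_duration * RATE), 5.0)
        cs_off = design.cs_onsets[0] + design.cs_duration
        i0 = int(cs_off * RATE) - 3  # starts 0.3 s before CS offset
        v[i0 : i0 + 10] = 25.0
        ep = epoch_trace(make_trace(v, rate=RATE), design)
        events = detect_darts(ep)
        assert len(events) == 1
        assert events[0].offset == pytest.approx(cs_off)  # clipped

    def test_threshold_monotonicity_for_discrete_movements(self, small_design):
        # well-separated unimodal pulses: raising the threshold can only
        # remove events, never add them
        rng = np.random.default_rng(3)
        v = np.abs(rng.normal(3, 1, int(small_design.total_duration * RATE)))
        amps = [12.0, 18.0, 24.0, 32.0, 40.0, 15.0]
        slots = []
        for k, (cs0, _) in enumerate(small_design.cs_windows()):
            slots += [cs0 + 0.5, cs0 + 2.5]
        for amp, onset in zip(amps, slots):
            i0 = int(onset * RATE)
            m = 5
            v[i0 : i0 + m] = amp * np.sin(np.pi * (np.arange(1, m + 1)) / (m + 1))
        counts = [
            len(detect_darts(ep := epoch_trace(make_trace(v, rate=RATE),
                                               small_design),
                             ScoringParams(dart_threshold=thr)))
            for thr in (10.0, 15.0, 20.0, 25.0, 30.0)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # the ladder actually discriminates

    def test_agrees_with_brute_force_on_random_traces(self, small_design):
        rng = np.random.default_rng(7)
        ep0 = epoch_trace(
            make_trace(_base(small_design), rate=RATE), small_design
        )
        shock_by_trial = dict(
            zip(small_design.shock_trial_indices(), ep0.shock_onset_idx)
        )
        for _ in range(50):
            v = np.abs(rng.normal(10, 8, int(small_design.total_duration * RATE)))
            ep = epoch_trace(make_trace(v, rate=RATE), small_design)
            got = [
                (e.trial_index, int(round(e.onset * RATE)),
                 int(round(e.offset * RATE)), e.peak_velocity)
                for e in detect_darts(ep)
            ]
            expected = brute_force_darts(
                v, RATE, ep.cs, shock_by_trial
            )
            assert got == expected


class TestRunMachineryProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(min_value=0.0, max_value=40.0), min_size=60,
                 max_size=160)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_detector_agrees_with_brute_force_on_arbitrary_velocities(self, vals):
        design = build_session_design(
            "extinction", cs_duration=2.0, iti=3.0, lead_in=1.0, n_cs=2
        )
        rate = 10.0
        n = int(design.total_duration * rate)
        v = np.resize(np.asarray(vals), n)
        ep = epoch_trace(make_trace(v, rate=rate), design)
        got = [
            (e.trial_index, int(round(e.onset * rate)),
             int(round(e.offset * rate)), e.peak_velocity)
            for e in detect_darts(ep)
        ]
        assert got == brute_force_darts(v, rate, ep.cs, {})

    @given(
        st.lists(st.floats(min_value=0.0, max_value=2.0), min_size=60,
                 max_size=160)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_freezing_total_matches_brute_force(self, vals):
        design = build_session_design(
            "extinction", cs_duration=2.0, iti=3.0, lead_in=1.0, n_cs=2
        )
        rate = 10.0
        n = int(design.total_duration * rate)
        v = np.resize(np.asarray(vals), n)
        trace = make_trace(v, rate=rate)
        ep = epoch_trace(trace, design)
        got = sum(b.duration for b in detect_freezing(trace, ep))
        expected = sum(
            (b - a) / rate for a, b in brute_force_freezing(v, rate)
        )
        assert got == pytest.approx(expected, abs=1e-9)


class TestClassifyDarter:
    def test_darts_only_on_trials_1_and_2_is_non_darter(self):
        darts = [
            DartEvent(1, 0.0, 0.1, 25.0),
            DartEvent(2, 0.0, 0.1, 30.0),
        ]
        assert classify_darter(darts) == "Non-darter"

    def test_single_dart_on_trial_5_is_darter(self):
        assert classify_darter([DartEvent(5, 0.0, 0.1, 21.0)]) == "Darter"

    def test_no_darts_is_non_darter(self):
        assert classify_darter([]) == "Non-darter"

    def test_invariant_to_event_order(self):
        darts = [DartEvent(k, 0.0, 0.1, 25.0) for k in (1, 5, 2)]
        assert classify_darter(darts) == classify_darter(list(reversed(darts)))


class TestShockResponse:
    def test_peak_at_onset(self, small_design):
        v = _base(small_design)
        i0 = int(small_design.shock_onsets[1] * RATE)
        v[i0] = 60.0
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        assert shock_response(ep)[1] == 60.0

    def test_peak_2_s_after_onset_is_captured(self, small_design):
        v = _base(small_design)
        i0 = int(small_design.shock_onsets[0] * RATE) + int(2 * RATE)
        v[i0] = 80.0
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        assert shock_response(ep)[0] == 80.0

    def test_peak_beyond_window_is_excluded(self, small_design):
        params = ScoringParams(shock_response_window=5.0)
        v = _base(small_design)
        s0 = int(small_design.shock_onsets[0] * RATE)
        v[s0] = 30.0
        v[s0 + int(6 * RATE)] = 90.0  # outside the 5-s window
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        got = shock_response(ep, params)[0]
        # oracle: brute-force max over the window samples
        expected = max(v[s0 : s0 + int(5 * RATE)])
        assert got == expected == 30.0

    def test_instantaneous_variant(self, small_design):
        v = _base(small_design)
        s0 = int(small_design.shock_onsets[0] * RATE)
        v[s0] = 12.0
        v[s0 + 3] = 70.0
        ep = epoch_trace(make_trace(v, rate=RATE), small_design)
        assert shock_response(ep, ScoringParams(shock_instantaneous=True))[0] == 12.0

    def test_shock_free_design_errors(self):
        design = build_session_design("extinction", cs_duration=5.0, iti=8.0,
                                      lead_in=6.0, n_cs=2)
        v = np.full(int(design.total_duration * RATE), 5.0)
        ep = epoch_trace(make_trace(v, rate=RATE), design)
        with pytest.raises(DesignError):
            shock_response(ep)


class TestDetectFreezing:
    def test_short_immobility_is_not_a_bout(self, small_design):
        v = _base(small_design)
        v[10:18] = 0.0  # 0.8 s < 1 s minimum
        trace = make_trace(v, rate=RATE)
        ep = epoch_trace(trace, small_design)
        assert detect_freezing(trace, ep) == []

    def test_fully_frozen_cs_scores_100_percent(self, small_design):
        v = _base(small_design)
        cs0, cs1 = int(small_design.cs_onsets[0] * RATE), int(
            (small_design.cs_onsets[0] + small_design.cs_duration) * RATE
        )
        v[cs0:cs1] = 0.0
        trace = make_trace(v, rate=RATE)
        ep = epoch_trace(trace, small_design)
        bouts = detect_freezing(trace, ep)
        summ = summarize_session(trace, ep, [], bouts)
        assert summ[1].percent_freezing_cs == pytest.approx(100.0)

    def test_planted_bout_durations_recovered(self, small_design):
        v = _base(small_design)
        plan = [(30, 2.0), (80, 3.0), (140, 1.5)]
        for i0, dur in plan:
            v[i0 : i0 + int(dur * RATE)] = 0.1
        trace = make_trace(v, rate=RATE)
        ep = epoch_trace(trace, small_design)
        bouts = detect_freezing(trace, ep)
        # bouts may be split across epoch boundaries; group pieces by start
        onsets = sorted({i0 / RATE for i0, _ in plan})
        total_by_plant = []
        for i0, dur in plan:
            lo, hi = i0 / RATE, i0 / RATE + dur
            total_by_plant.append(
                sum(b.duration for b in bouts if lo - 1e-9 <= b.onset < hi)
            )
        for planted_dur, got in zip([d for _, d in plan], total_by_plant):
            assert got == pytest.approx(planted_dur, abs=1.0 / RATE)

    def test_agrees_with_brute_force(self, small_design):
        rng = np.random.default_rng(11)
        for _ in range(30):
            v = np.abs(rng.normal(0.6, 0.6, int(small_design.total_duration * RATE)))
            trace = make_trace(v, rate=RATE)
            ep = epoch_trace(trace, small_design)
            got_total = sum(b.duration for b in detect_freezing(trace, ep))
            oracle = brute_force_freezing(v, RATE)
            # oracle bouts are unsplit; total frozen time must match exactly
            expected = sum((b - a) / RATE for a, b in oracle)
            assert got_total == pytest.approx(expected, abs=1e-9)

    def test_freeze_threshold_monotonicity(self, small_design):
        rng = np.random.default_rng(13)
        v = np.abs(rng.normal(0.6, 0.6, int(small_design.total_duration * RATE)))
        trace = make_trace(v, rate=RATE)
        ep = epoch_trace(trace, small_design)
        totals = [
            sum(
                b.duration
                for b in detect_freezing(
                    trace, ep, ScoringParams(freeze_velocity_threshold=thr)
                )
            )
            for thr in (0.2, 0.5, 1.0, 2.0)
        ]
        assert totals == sorted(totals)


class TestSummarize:
    def test_zero_bouts_give_zero_percents(self, small_design):
        v = _base(small_design)
        trace = make_trace(v, rate=RATE)
        ep = epoch_trace(trace, small_design)
        summ = summarize_session(trace, ep, [], [])
        assert all(s.percent_freezing_cs == 0.0 for s in summ[1:])
        assert summ[0].baseline_percent_freezing == 0.0

    def test_bout_split_at_cs_offset(self):
        design = build_session_design("extinction", cs_duration=5.0, iti=8.0,
                                      lead_in=6.0, n_cs=2)
        v = np.full(int(design.total_duration * RATE), 5.0)
        cs0 = int(design.cs_onsets[0] * RATE)
        cs1 = cs0 + int(design.cs_duration * RATE)
        v[cs1 - 20 : cs1 + 30] = 0.0  # 2 s in CS, 3 s into ITI
        trace = make_trace(v, rate=RATE)
        ep = epoch_trace(trace, design)
        summ = summarize_session(trace, ep, [], detect_freezing(trace, ep))
        assert summ[1].percent_freezing_cs == pytest.approx(100 * 2.0 / 5.0)

    def test_block_average_counts(self):
        from fearframe.behavior_scoring import TrialSummary

        # trial-0 baseline row must be ignored by block averaging
        summaries = [TrialSummary(trial_index=0, baseline_percent_freezing=0.0)]
        summaries += [
            TrialSummary(trial_index=k, percent_freezing_cs=float(k))
            for k in range(1, 21)
        ]
        blocks = block_average(summaries, 2)
        assert len(blocks) == 10
        assert blocks[0] == (1, 1.5)
        assert blocks[9] == (10, 19.5)

    def test_rescaling_invariance(self, small_design):
        # same planted events at 10 and 20 Hz: boundaries within one period
        for rate in (10.0, 20.0):
            v = np.full(int(small_design.total_duration * rate), 5.0)
            cs0 = small_design.cs_onsets[0]
            i0 = int((cs0 + 1.0) * rate)
            v[i0 : i0 + int(0.5 * rate)] = 25.0
            ep = epoch_trace(make_trace(v, rate=rate), small_design)
            events = detect_darts(ep)
            assert len(events) == 1
            assert events[0].onset == pytest.approx(cs0 + 1.0, abs=1.0 / rate)
            assert events[0].offset == pytest.approx(cs0 + 1.5, abs=1.0 / rate)
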