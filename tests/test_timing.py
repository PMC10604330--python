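import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posturekit import Label
from posturekit.nn.training import ProbabilitySequence
from posturekit.timing import (
    MatchResult,
    TransitionEvent,
    classification_report,
    debounce,
    decode_labels,
    default_max_gap,
    delta_t_group_stats,
    extract_transitions,
    match_transitions,
    run_length_encode,
    score_predictions,
    transition_time_accuracy,
)

# --- independent oracles -------------------------------------------------


def _rle(track):
    runs = []
    for lab in track:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return runs


def _debounce_oracle(track, min_run):
    """Repeated-pass rewrite: relabel the first too-short run with its
    predecessor's label (or successor's, if it is the first run), until
    no run is shorter than min_run or only one run remains."""
    track = list(track)
    while True:
        runs = _rle(track)
        if len(runs) <= 1:
            return track
        for idx, (lab, ln) in enumerate(runs):
            if ln < min_run:
                new_lab = runs[idx - 1][0] if idx > 0 else runs[1][0]
                runs[idx][0] = new_lab
                track = [l for l, n in runs for _ in range(n)]
                break
        else:
            return track


# --- decode --------------------------------------------------------------


class TestDecode:
    def test_argmax_row(self):
        row = np.array([[0.1, 0.6, 0.05, 0.1, 0.05, 0.05, 0.05]])
        assert decode_labels(ProbabilitySequence(probs=row, rate=100.0))[0] == Label.WALKING

    def test_uniform_row_ties_to_lowest_index(self):
        row = np.full((1, 7), 1.0 / 7.0)
        assert decode_labels(ProbabilitySequence(probs=row, rate=100.0))[0] == Label.STANDING

    def test_length_preserved(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(7), size=50)
        assert decode_labels(ProbabilitySequence(probs=probs, rate=100.0)).shape == (50,)


# --- debounce ------------------------------------------------------------


class TestDebounce:
    def test_min_run_one_is_identity(self):
        track = np.array([0, 1, 1, 2, 0, 0])
        assert np.array_equal(debounce(track, 1), track)

    def test_single_sample_flicker_absorbed(self):
        track = np.array([0] * 10 + [1] + [0] * 10)
        assert np.array_equal(debounce(track, 3), np.array([0] * 21))

    def test_length_always_preserved(self):
        rng = np.random.default_rng(3)
        track = rng.integers(0, 7, size=200)
        assert debounce(track, 5).size == 200

    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=40),
        st.integers(min_value=1, max_value=6),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_repeated_pass_oracle(self, track, min_run):
        got = debounce(np.array(track), min_run)
        assert list(got) == _debounce_oracle(track, min_run)


# --- event extraction ----------------------------------------------------


class TestExtractTransitions:
    def test_constant_track_no_events(self):
        assert extract_transitions(np.zeros(100, dtype=int), 100.0) == []

    def test_simple_track_at_1hz(self):
        track = np.array([0] * 5 + [5] * 3 + [1] * 4)
        events = extract_transitions(track, 1.0)
        assert [(e.time, e.from_label, e.to_label) for e in events] == [
            (5.0, 0, 5),
            (8.0, 5, 1),
        ]

    def test_event_count_equals_runs_minus_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            track = rng.integers(0, 7, size=100)
            events = extract_transitions(track, 10.0)
            assert len(events) == len(run_length_encode(track)) - 1

    def test_categories(self):
        track = np.array([0, 5, 1, 6, 0, 2, 3, 4, 0])
        cats = [e.category for e in extract_transitions(track, 1.0)]
        assert cats == ["start", "steady", "end", "steady", "start", "steady", "end", "steady"]


# --- matching ------------------------------------------------------------


def _events_from(track, rate=100.0):
    return extract_transitions(np.asarray(track), rate)


class TestMatch:
    def test_identical_tracks_all_matched_zero_dt(self):
        track = np.array([0] * 50 + [5] * 20 + [1] * 50)
        events = _events_from(track)
        res = match_transitions(events, events, max_gap=1.0)
        assert len(res.matched) == len(events)
        assert np.all(res.delta_ts == 0.0)
        assert not res.unmatched_true and not res.unmatched_pred

    def test_shifted_predictions_constant_dt(self):
        rate, k = 100.0, 40
        track = np.array([0] * 300 + [5] * 80 + [1] * 300 + [6] * 80 + [0] * 300)
        shifted = np.concatenate([np.full(k, track[0]), track[:-k]])
        res = match_transitions(_events_from(track), _events_from(shifted), max_gap=1.0)
        assert len(res.matched) == 4
        np.testing.assert_allclose(res.delta_ts, k / rate, atol=1e-12)

    def test_missing_prediction_is_unmatched(self):
        true_events = _events_from(np.array([0] * 50 + [1] * 50))
        res = match_transitions(true_events, [], max_gap=1.0)
        assert len(res.matched) == 0
        assert len(res.unmatched_true) == 1

    def test_label_mismatch_never_matched(self):
        te = [TransitionEvent(1.0, 0, 5)]
        pe = [TransitionEvent(1.0, 0, 2)]
        res = match_transitions(te, pe, max_gap=10.0)
        assert not res.matched

    def test_default_max_gap_uses_same_label_spacing(self):
        # only events with the same target label can cross-match, so
        # the 0.4 s gap between the stw event and the walking event
        # must not tighten the cap; the binding spacing is the 1.6 s
        # between the two walking entries
        events = [
            TransitionEvent(1.0, 0, 5),  # -> stw
            TransitionEvent(1.4, 5, 1),  # -> walking
            TransitionEvent(3.0, 0, 1),  # -> walking again
        ]
        assert default_max_gap(events) == pytest.approx(0.8)

    def test_default_max_gap_without_repeated_labels_is_unbounded(self):
        events = [TransitionEvent(1.0, 0, 5), TransitionEvent(1.4, 5, 1)]
        assert default_max_gap(events) == np.inf


# --- transition-time accuracy --------------------------------------------


def _match_with(dts, n_unmatched=0):
    matched = [(TransitionEvent(1.0, 0, 1), TransitionEvent(1.0, 0, 1), dt) for dt in dts]
    unmatched = [TransitionEvent(2.0, 1, 0)] * n_unmatched
    return MatchResult(matched=matched, unmatched_true=unmatched, unmatched_pred=[])


class TestTransitionTimeAccuracy:
    def test_perfect_is_100(self):
        assert transition_time_accuracy(_match_with([0.0, 0.0]), 100.0) == 100.0

    def test_direct_substitution(self):
        assert transition_time_accuracy(_match_with([5.0]), 100.0) == pytest.approx(95.0)

    def test_hand_computed_example(self):
        # sums 2 + 1 + 1 s over 63 s: (1 - 4/63) * 100
        acc = transition_time_accuracy(_match_with([2.0, 1.0, 1.0]), 63.0)
        assert acc == pytest.approx(100.0 * (1.0 - 4.0 / 63.0), abs=0.01)
        assert acc == pytest.approx(93.65, abs=0.01)

    def test_unmatched_events_penalized(self):
        with_miss = transition_time_accuracy(_match_with([], n_unmatched=1), 100.0, penalty=2.0)
        assert with_miss == pytest.approx(98.0)

    def test_clipped_at_zero(self):
        assert transition_time_accuracy(_match_with([500.0]), 100.0) == 0.0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=1, max_size=10),
        st.integers(min_value=0, max_value=9),
        st.floats(min_value=0.01, max_value=3.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_delta_t_and_misses(self, dts, idx, bump):
        base = transition_time_accuracy(_match_with(dts), 200.0)
        worse_dts = list(dts)
        worse_dts[idx % len(dts)] += bump
        assert transition_time_accuracy(_match_with(worse_dts), 200.0) <= base
        assert transition_time_accuracy(_match_with(dts, n_unmatched=1), 200.0) <= base


# --- classification report -----------------------------------------------


class TestClassificationReport:
    def test_identical_tracks(self):
        track = np.array([0, 1, 2, 3, 4, 5, 6] * 10)
        acc, conf = classification_report(track, track)
        assert acc == 100.0
        assert np.all(conf == np.diag(np.full(7, 10)))

    def test_counting(self):
        true = np.zeros(100, dtype=int)
        pred = np.zeros(100, dtype=int)
        pred[:10] = 1
        acc, conf = classification_report(true, pred)
        assert acc == pytest.approx(90.0)
        assert conf.sum() == 100
        assert conf[0, 1] == 10

    def test_row_sums_equal_true_counts(self):
        rng = np.random.default_rng(5)
        true = rng.integers(0, 7, size=500)
        pred = rng.integers(0, 7, size=500)
        _, conf = classification_report(true, pred)
        assert np.array_equal(conf.sum(axis=1), np.bincount(true, minlength=7))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            classification_report(np.zeros(5, dtype=int), np.zeros(6, dtype=int))


# --- full pipeline -------------------------------------------------------


class TestScorePredictions:
    def test_ground_truth_fixed_point(self, one_cycle_session):
        rep = score_predictions(
            one_cycle_session.labels, one_cycle_session.labels.copy(), rate=one_cycle_session.rate
        )
        assert rep.transition_time_accuracy == 100.0
        assert rep.classification_accuracy == 100.0
        assert len(rep.match.unmatched_true) == 0

    def test_shift_sensitivity(self, one_cycle_session):
        k, rate = 25, one_cycle_session.rate
        labels = one_cycle_session.labels
        shifted = np.concatenate([np.full(k, labels[0]), labels[:-k]])
        rep = score_predictions(labels, shifted, rate=rate, max_gap=1.0)
        assert rep.mean_delta_t == pytest.approx(k / rate, abs=1e-12)

    def test_report_frames_consistent(self, one_cycle_session):
        labels = one_cycle_session.labels
        rep = score_predictions(labels, labels.copy(), rate=one_cycle_session.rate)
        events = rep.events_frame()
        assert (events["status"] == "matched").all()
        assert rep.confusion_frame().to_numpy().sum() == labels.size
        cats = rep.category_summary()
        assert set(cats["category"]) == {"steady", "start", "end"}
        assert cats["n_matched"].sum() == len(rep.match.matched)


# --- group statistics ----------------------------------------------------


class TestGroupStats:
    def test_hand_arithmetic(self):
        stats, _ = delta_t_group_stats({"a": np.array([0.1, 0.2, 0.3])})
        assert stats[0].mean == pytest.approx(0.2)
        assert stats[0].sd == pytest.approx(0.1)

    def test_identical_groups(self):
        _, tests = delta_t_group_stats(
            {"a": np.array([0.1, 0.2, 0.3]), "b": np.array([0.1, 0.2, 0.3])}
        )
        assert tests[0].t_statistic == pytest.approx(0.0)
        assert tests[0].p_value == pytest.approx(1.0)
        assert not tests[0].significant

    def test_welch_closed_form(self):
        _, tests = delta_t_group_stats(
            {"a": np.array([0.1, 0.2, 0.3]), "b": np.array([0.4, 0.5, 0.6])}
        )
        assert tests[0].t_statistic == pytest.approx(-3.674, abs=1e-3)

    def test_zero_variance_pair_degenerate_not_crashing(self):
        _, tests = delta_t_group_stats(
            {"a": np.array([0.2, 0.2, 0.2]), "b": np.array([0.5, 0.5, 0.5])}
        )
        assert tests[0].degenerate
        assert not tests[0].significant
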