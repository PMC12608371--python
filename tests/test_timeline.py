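"""Timeline decoding rules: calls, misclassification flags, transitions,
durations — checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from embryostage.stages import StageLabel as S
from embryostage.timeline import (
    Flag,
    TimeGrid,
    analyze_series,
    apply_corrections,
    call_stages,
    compute_durations,
    detect_misclassifications,
    identify_transitions,
    read_probability_csv,
    series_to_frame,
    write_timeline_csv,
)

D, V, R = S.DORSAL_INTERCALATION, S.VENTRAL_ENCLOSURE, S.ROTATION


def one_hot_probs(calls, conf=1.0):
    probs = np.full((len(calls), 6), (1 - conf) / 5)
    for i, c in enumerate(calls):
        probs[i, c.value] = conf
    return probs


def series_from_calls(calls, conf=1.0):
    return call_stages(one_hot_probs(calls, conf))


def oracle_flags(calls):
    """Independent per-frame window-expansion oracle for the flag rule."""
    n = len(calls)
    flags = [Flag.CLEAN] * n
    corrected = [None] * n
    for i in range(n):
        left = i
        while left - 1 >= 0 and calls[left - 1] == calls[i]:
            left -= 1
        right = i
        while right + 1 < n and calls[right + 1] == calls[i]:
            right += 1
        if left == 0 or right == n - 1:
            continue  # run touches a series end: no two-sided context
        if calls[left - 1] == calls[right + 1] != calls[i]:
            if left == right:
                flags[i] = Flag.ISOLATED
                corrected[i] = calls[left - 1]
            else:
                flags[i] = Flag.CONSECUTIVE
    return flags, corrected


class TestCallStages:
    def test_one_hot_probs_reproduce_labels(self):
        calls = [S.BEFORE_INTERCALATION, D, D, V, R]
        series = series_from_calls(calls)
        assert series.called() == calls
        assert [c.time_min for c in series.calls] == [150, 155, 160, 165, 170]

    def test_tie_breaks_to_earlier_stage(self):
        probs = np.zeros((1, 6))
        probs[0, D.value] = 0.5
        probs[0, R.value] = 0.5
        series = call_stages(probs)
        assert series.calls[0].called_stage is D

    def test_generator_round_trip(self):
        from embryostage.synthgen import SynthTimelineSpec, generate_probability_series

        spec = SynthTimelineSpec(
            segments=((S.BEFORE_INTERCALATION, 10), (D, 20), (V, 12), (R, 8)),
            seed=6,
        )
        probs, truth = generate_probability_series(spec)
        series = call_stages(probs)
        assert series.called() == truth.true_stage

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            call_stages(np.zeros((0, 6)))

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            call_stages(np.full((2, 6), 0.5))


class TestDetect:
    def test_isolated_example(self):
        series = series_from_calls([D, D, V, D, D])
        detect_misclassifications(series)
        assert series.calls[2].flag is Flag.ISOLATED
        assert series.calls[2].corrected_stage is D
        assert all(series.calls[i].flag is Flag.CLEAN for i in (0, 1, 3, 4))

    def test_monotone_series_has_no_flags(self):
        series = series_from_calls([S.BEFORE_INTERCALATION, D, D, V, V, R])
        detect_misclassifications(series)
        assert all(c.flag is Flag.CLEAN for c in series.calls)

    def test_consecutive_example(self):
        series = series_from_calls([V, V, D, D, V, V])
        detect_misclassifications(series)
        assert series.calls[2].flag is Flag.CONSECUTIVE
        assert series.calls[3].flag is Flag.CONSECUTIVE
        assert all(series.calls[i].flag is Flag.CLEAN for i in (0, 1, 4, 5))

    def test_short_series_warns_without_flags(self):
        series = series_from_calls([D, V])
        with pytest.warns(UserWarning, match="shorter"):
            detect_misclassifications(series)
        assert all(c.flag is Flag.CLEAN for c in series.calls)

    def test_exhaustive_oracle_up_to_length_6(self):
        # the acceptance suite extends this to length 8
        for n in range(1, 7):
            for combo in itertools.product((D, V, R), repeat=n):
                series = series_from_calls(list(combo))
                if n < 3:
                    with pytest.warns(UserWarning):
                        detect_misclassifications(series)
                else:
                    detect_misclassifications(series)
                flags, corrected = oracle_flags(list(combo))
                assert [c.flag for c in series.calls] == flags, combo
                assert [c.corrected_stage for c in series.calls] == corrected, combo


class TestApplyCorrections:
    def test_isolated_corrected_and_reported(self):
        series = series_from_calls([D, D, V, D, D])
        detect_misclassifications(series)
        series, report = apply_corrections(series)
        assert series.effective() == [D, D, D, D, D]
        assert report.n_isolated == 1 and report.n_consecutive_runs == 0
        assert report.per_stage == {D: 1}

    def test_clean_series_unchanged(self):
        calls = [S.BEFORE_INTERCALATION, D, D, V, V]
        series = series_from_calls(calls)
        detect_misclassifications(series)
        series, report = apply_corrections(series)
        assert series.effective() == calls
        assert report.n_misclassified == 0 and not series.excluded_stages

    def test_consecutive_run_excludes_host_stage(self):
        series = series_from_calls([D, D, V, V, D, D, D])
        detect_misclassifications(series)
        series, report = apply_corrections(series)
        assert series.excluded_stages == {D}
        assert report.n_consecutive_runs == 1
        assert report.n_consecutive_frames == 2
        # consecutive frames are NOT corrected
        assert series.effective()[2:4] == [V, V]

    def test_disabled_mode_clears_corrections(self):
        series = series_from_calls([D, D, V, D, D])
        detect_misclassifications(series)
        series, report = apply_corrections(series, enabled=False)
        assert report.n_isolated == 1  # still counted
        assert series.effective() == [D, D, V, D, D]  # but not applied


class TestTransitions:
    def test_mixed_pattern_single_frame(self):
        probs = one_hot_probs([D, D, D, V, V], conf=0.95)
        probs[2] = 0
        probs[2, D.value], probs[2, V.value] = 0.55, 0.45
        series = call_stages(probs)
        detect_misclassifications(series)
        apply_corrections(series)
        identify_transitions(series)
        assert series.calls[2].is_transition
        assert sum(c.is_transition for c in series.calls) == 1
        assert [t.pattern for t in series.boundary_tags] == ["mixed"]

    def test_oscillation_pattern_marks_alternating_frames(self):
        # argmax D,V,D,V then stable V
        series = series_from_calls([D, V, D, V, V, V], conf=0.95)
        detect_misclassifications(series)
        apply_corrections(series)
        identify_transitions(series)
        assert [c.is_transition for c in series.calls] == [
            True, True, True, True, False, False,
        ]
        assert [t.pattern for t in series.boundary_tags] == ["oscillation"]
        # flags inside the window were revoked
        assert all(c.flag is Flag.CLEAN for c in series.calls)

    def test_hard_switch_has_no_transition(self):
        series = series_from_calls([D, D, D, V, V, V], conf=0.99)
        detect_misclassifications(series)
        apply_corrections(series)
        identify_transitions(series)
        assert not any(c.is_transition for c in series.calls)
        assert [t.pattern for t in series.boundary_tags] == ["none"]

    def test_nonadjacent_jump_tagged_anomalous(self):
        series = series_from_calls([D, D, D, R, R, R], conf=0.99)
        detect_misclassifications(series)
        apply_corrections(series)
        identify_transitions(series)
        assert [t.pattern for t in series.boundary_tags] == ["anomalous"]
        assert not any(c.is_transition for c in series.calls)

    def test_invalid_theta_rejected(self):
        series = series_from_calls([D, D, V, V])
        with pytest.raises(ValueError, match="theta"):
            identify_transitions(series, theta_mixed=0.3)


class TestDurations:
    def test_mixed_boundary_arithmetic(self):
        probs = one_hot_probs([D] * 10 + [D] + [V] * 6, conf=0.95)
        probs[10] = 0
        probs[10, D.value], probs[10, V.value] = 0.55, 0.45
        series, table, _ = analyze_series(probs)
        assert table.durations_min[D] == 50.0
        assert table.durations_min[V] == 30.0
        assert table.transitions_min[(D, V)] == 5.0

    def test_single_stage_series(self):
        series = series_from_calls([V, V, V, V])
        detect_misclassifications(series)
        apply_corrections(series)
        identify_transitions(series)
        table = compute_durations(series)
        assert table.durations_min[V] == 20.0

    def test_absent_stage_warns_when_asked(self):
        series = series_from_calls([D, D, D, D])
        detect_misclassifications(series)
        apply_corrections(series)
        identify_transitions(series)
        with pytest.warns(UserWarning, match="absent"):
            compute_durations(series, warn_missing=True)

    def test_generator_round_trip_with_declared_boundaries(self):
        from embryostage.synthgen import (
            SynthTimelineSpec,
            TransitionSpec,
            generate_probability_series,
        )

        spec = SynthTimelineSpec(
            segments=((S.BEFORE_INTERCALATION, 6), (D, 10), (V, 8), (R, 5)),
            transitions=(
                TransitionSpec("none", 0),
                TransitionSpec("mixed", 2),
                TransitionSpec("oscillation", 4),
            ),
            isolated=(10,),
            seed=13,
        )
        probs, truth = generate_probability_series(spec)
        _, table, report = analyze_series(probs)
        for stage, minutes in truth.durations_min.items():
            assert table.durations_min[stage] == minutes
        for boundary, minutes in truth.transitions_min.items():
            assert table.transitions_min[boundary] == minutes
        assert report.n_isolated == 1

    def test_frame_conservation_and_grid_multiples(self):
        from embryostage.synthgen import random_timeline_spec, generate_probability_series

        rng = np.random.default_rng(77)
        for _ in range(25):
            spec = random_timeline_spec(rng)
            probs, _ = generate_probability_series(spec)
            series, table, _ = analyze_series(probs)
            table.check_conservation()
            dt = series.grid.interval_min
            for v in list(table.durations_min.values()) + list(
                table.transitions_min.values()
            ):
                assert v % dt == 0

    def test_correction_idempotent_on_corrected_series(self):
        series = series_from_calls([D, D, V, D, D, V, V, R, V, R, R])
        detect_misclassifications(series)
        series, _ = apply_corrections(series)
        redecoded = series_from_calls(series.effective())
        detect_misclassifications(redecoded)
        _, report = apply_corrections(redecoded)
        assert report.n_misclassified == 0


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        probs = one_hot_probs([D, D, V, V], conf=0.9)
        series = call_stages(probs, TimeGrid(150, 5))
        p = write_timeline_csv(series, tmp_path / "tl.csv")
        back, grid = read_probability_csv(p)
        assert np.allclose(back, probs)
        assert grid == TimeGrid(150.0, 5.0)

    def test_frame_columns(self):
        series = series_from_calls([D, V])
        df = series_to_frame(series)
        assert list(df.columns[:2]) == ["frame", "time_min"]
        assert "called_stage" in df.columns and "is_transition" in df.columns

    def test_duration_json_round_trip(self, tmp_path):
        probs = one_hot_probs([D] * 5 + [V] * 4)
        _, table, _ = analyze_series(probs)
        path = tmp_path / "d.json"
        table.to_json(path)
        from embryostage.timeline import StageDurationTable

        back = StageDurationTable.from_json(path)
        assert back.durations_min == table.durations_min
        assert back.transitions_min == table.transitions_min
        assert back.n_frames == table.n_frames
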