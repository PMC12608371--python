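"""Confusion metrics and group-comparison statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from embryostage.stages import StageLabel as S
from embryostage.stats_eval import (
    ComparisonResult,
    ConfusionCounts,
    GroupDurations,
    compare_groups,
    comparison_table,
    confusion_metrics,
    mean_sem,
    multiclass_macro_metrics,
    percent_delay,
    significance_stars,
    unpaired_t_test,
)
from embryostage.timeline import StageDurationTable


def make_table(durations, excluded=(), embryo_id="e", group="g"):
    full = {s: 0.0 for s in S}
    full.update(durations)
    n_frames = int(sum(full.values()) / 5)
    return StageDurationTable(
        embryo_id=embryo_id,
        group=group,
        durations_min=full,
        transitions_min={},
        excluded_stages=set(excluded),
        interval_min=5.0,
        n_frames=n_frames,
    )


class TestConfusionMetrics:
    def test_segmentation_pixel_counts_from_study(self):
        m = confusion_metrics(ConfusionCounts(519293, 14760, 714840, 4483))
        rounded = {k: round(100 * v, 1) for k, v in m.items()}
        assert rounded == {
            "sensitivity": 99.1,
            "specificity": 98.0,
            "accuracy": 98.5,
            "precision": 97.2,
            "f1": 98.2,
            "iou": 96.4,
        }

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(10, 0, 10, 0))
        assert all(v == 1.0 for v in m.values())

    def test_direct_arithmetic_example(self):
        m = confusion_metrics(ConfusionCounts(3, 3, 9, 1))
        assert m["iou"] == pytest.approx(3 / 7)
        assert m["sensitivity"] == pytest.approx(3 / 4)
        assert m["precision"] == pytest.approx(1 / 2)

    def test_zero_denominator_reported_undefined(self):
        m = confusion_metrics(ConfusionCounts(0, 0, 5, 0))
        assert m["sensitivity"] is None and m["precision"] is None
        assert m["specificity"] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_f1_iou_algebraic_identity(self, seed):
        rng = np.random.default_rng(seed)
        c = ConfusionCounts(*(int(v) for v in rng.integers(1, 500, 4)))
        m = confusion_metrics(c)
        # harmonic-mean identity and iou = f1 / (2 - f1)
        assert m["f1"] == pytest.approx(
            2 / (1 / m["precision"] + 1 / m["sensitivity"])
        )
        assert m["iou"] == pytest.approx(m["f1"] / (2 - m["f1"]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 5)


class TestMacroMetrics:
    def test_matches_per_class_brute_force(self):
        rng = np.random.default_rng(4)
        cm = rng.integers(0, 30, (6, 6))
        got = multiclass_macro_metrics(cm)
        ps, rs, fs = [], [], []
        for k in range(6):
            tp = cm[k, k]
            p = tp / cm[:, k].sum() if cm[:, k].sum() else 0.0
            r = tp / cm[k].sum() if cm[k].sum() else 0.0
            ps.append(p)
            rs.append(r)
            fs.append(2 * p * r / (p + r) if p + r else 0.0)
        assert got["precision"] == pytest.approx(np.mean(ps), abs=1e-9)
        assert got["recall"] == pytest.approx(np.mean(rs), abs=1e-9)
        assert got["f1"] == pytest.approx(np.mean(fs), abs=1e-9)


class TestMeanSem:
    def test_hand_computation(self):
        mean, sem = mean_sem([10, 20, 30])
        assert mean == 20.0
        assert sem == pytest.approx(10 / np.sqrt(3))

    def test_constant_values(self):
        assert mean_sem([7, 7, 7])[1] == 0.0

    def test_sixteen_multiples_of_five_summing_to_860(self):
        # consistency with a printed group mean: 860 / 16 = 53.75
        values = [55] * 12 + [50] * 4  # 660 + 200 = 860
        mean, _ = mean_sem(values)
        assert mean == 53.75

    def test_single_value_has_no_sem(self):
        assert mean_sem([3.0]) == (3.0, None)


class TestTTest:
    def test_identical_groups(self):
        t, p = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        t, p = unpaired_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 9)
        t, p = unpaired_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        tw, pw = unpaired_t_test(a, b, equal_var=False)
        refw = sps.ttest_ind(a, b, equal_var=False)
        assert tw == pytest.approx(refw.statistic, abs=1e-12)
        assert pw == pytest.approx(refw.pvalue, abs=1e-12)

    def test_antisymmetric_in_group_order(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0]
        t1, p1 = unpaired_t_test(a, b)
        t2, p2 = unpaired_t_test(b, a)
        assert t1 == -t2 and p1 == p2

    def test_monotone_in_separation(self):
        a = [1.0, 2.0, 3.0]
        ps = [unpaired_t_test(a, [x + 1, x + 2, x + 3])[1] for x in (1, 3, 9)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_zero_variance(self):
        assert unpaired_t_test([2, 2, 2], [2, 2])[1] == 1.0
        t, p = unpaired_t_test([2, 2, 2], [5, 5])
        assert p == 0.0 and np.isinf(t)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            unpaired_t_test([1], [2, 3])


class TestPercentDelay:
    @pytest.mark.parametrize(
        "control,treated,expected",
        [
            (53.75, 64.50, 20.0),
            (28.43, 44.50, 56.5),
            (20.93, 27.50, 31.4),
            (10.62, 16.00, 50.7),
            (14.5, 76.00, 424.1),
            (10.50, 28.50, 171.4),
            (10.0, 10.0, 0.0),
        ],
    )
    def test_printed_group_mean_pairs(self, control, treated, expected):
        assert round(percent_delay(control, treated), 1) == expected

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_delay(0.0, 5.0)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.5, "ns"),
            (0.05, "ns"),  # strict inequality at the boundary
            (0.02, "*"),
            (0.005, "**"),
            (0.0005, "***"),
            (0.00005, "****"),
            (0.0, "****"),
        ],
    )
    def test_threshold_table(self, p, expected):
        assert significance_stars(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestCompareGroups:
    def test_identical_groups_all_ns(self):
        tables = [
            make_table({S.DORSAL_INTERCALATION: 50 + 5 * i, S.VENTRAL_ENCLOSURE: 30})
            for i in range(5)
        ]
        res = compare_groups(GroupDurations("a", tables), GroupDurations("b", tables))
        tested = [r for r in res if r.testable]
        assert tested and all(r.stars == "ns" for r in tested)
        assert all(r.percent_delay == 0.0 for r in tested if r.control_mean > 0)

    def test_single_stage_delay_detected(self):
        rng = np.random.default_rng(2)
        control = [
            make_table(
                {s: 5 * round((30 + rng.normal(0, 2)) / 5) for s in S if s.value}
            )
            for _ in range(10)
        ]
        treated = [
            make_table(
                {
                    s: 5
                    * round(
                        ((45 if s is S.ROTATION else 30) + rng.normal(0, 2)) / 5
                    )
                    for s in S
                    if s.value
                }
            )
            for _ in range(10)
        ]
        res = compare_groups(GroupDurations("c", control), GroupDurations("t", treated))
        by_stage = {r.name: r for r in res}
        rot = by_stage[S.ROTATION.display_name]
        assert rot.percent_delay == pytest.approx(50, abs=15)
        others = [r for r in res if r.testable and r.name != rot.name]
        assert rot.p < min(r.p for r in others)

    def test_excluded_stage_reduces_n_for_that_stage_only(self):
        control = [make_table({S.DORSAL_INTERCALATION: 50, S.ROTATION: 15})
                   for _ in range(10)]
        treated = [
            make_table(
                {S.DORSAL_INTERCALATION: 60, S.ROTATION: 20},
                excluded=(S.DORSAL_INTERCALATION,) if i == 0 else (),
            )
            for i in range(10)
        ]
        res = compare_groups(GroupDurations("c", control), GroupDurations("t", treated))
        by_stage = {r.name: r for r in res}
        assert by_stage[S.DORSAL_INTERCALATION.display_name].treated_n == 9
        assert by_stage[S.ROTATION.display_name].treated_n == 10

    def test_not_testable_marked(self):
        control = [make_table({S.ROTATION: 15}) for _ in range(4)]
        treated = [
            make_table({S.ROTATION: 20}, excluded=(S.ROTATION,) if i else ())
            for i in range(4)
        ]
        res = compare_groups(GroupDurations("c", control), GroupDurations("t", treated))
        rot = {r.name: r for r in res}[S.ROTATION.display_name]
        assert not rot.testable and rot.stars == "not-testable"

    def test_comparison_table_layout(self):
        tables = [make_table({S.FOLD_2: 10 + 5 * i}) for i in range(3)]
        res = compare_groups(GroupDurations("a", tables), GroupDurations("b", tables))
        df = comparison_table(res)
        assert {"stage", "control_mean", "treated_sem", "delay_pct", "p", "stars"} <= set(
            df.columns
        )
        assert len(df) == len(res)
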