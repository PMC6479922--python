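"""Recognition scoring: adaptable/quartile schemes, grading, confusion rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rehabfis as rf
from rehabfis.evaluate import ConfusionCounts, middle_of_second, strict_rate
from rehabfis.schedule import standard_schedule


def make_series(schedule, labels, freq=10.0):
    """Build a recognition series from raw inferred labels over the schedule."""
    t = np.arange(len(labels)) / freq
    idx = schedule.motion_index_at(t)
    return pd.DataFrame({
        "t": t,
        "label": np.asarray(labels, dtype=float),
        "motion": [schedule.decode_label(v) for v in labels],
        "scheduled": [schedule.motions[i].name for i in idx],
    })


@pytest.fixture(scope="module")
def sched_a():
    return standard_schedule("A", cycles=1)


class TestRecognize:
    def test_end_to_end_on_noiseless_stream(self, trained_a, spec_a, noiseless_a):
        """A trained system decodes ≥ 90% of middle-half samples of a
        noiseless stream to the scheduled motion."""
        _, feats = noiseless_a
        series = rf.recognize(trained_a, feats, spec_a.schedule)
        q = rf.quartile_rates(series, spec_a.schedule)
        assert q["average"][50] >= 0.9

    def test_injected_outliers_are_flagged_not_labeled(self, trained_a, spec_a):
        cfg = rf.SimulationConfig(frequency=50.0, noise_sd_accel=0.0, noise_sd_gyro=0.0)
        stream, _ = rf.simulate_exercise(rf.exercise_spec("A", cycles=1), cfg)
        origin = rf.calibrate_origin(stream)
        dirty = rf.inject_outliers(stream, fraction=0.2, magnitude=1e4, seed=3)
        feats = rf.relative_features(dirty, origin)
        series = rf.recognize(trained_a, feats, spec_a.schedule)
        assert np.isnan(series["label"]).sum() == int(0.2 * len(stream))

    def test_empty_stream_gives_empty_series(self, trained_a, spec_a):
        empty = pd.DataFrame(columns=["t", "rANGVx", "rANGx"])
        series = rf.recognize(trained_a, empty, spec_a.schedule)
        assert series.empty

    def test_missing_feature_column_rejected(self, trained_a, spec_a):
        bad = pd.DataFrame({"t": [0.0], "rANGVx": [0.0]})
        with pytest.raises(KeyError, match="rANGx"):
            rf.recognize(trained_a, bad, spec_a.schedule)


class TestMiddleOfSecond:
    def test_one_decision_per_second(self, sched_a):
        series = make_series(sched_a, np.full(120, 0.5), freq=10.0)
        decisions = middle_of_second(series, sched_a)
        assert len(decisions) == 12

    def test_constant_window_yields_its_label(self, sched_a):
        series = make_series(sched_a, np.full(40, 1.5), freq=40.0)
        decisions = middle_of_second(series, sched_a)
        assert decisions["label"].iloc[0] == pytest.approx(1.5)

    def test_edges_ignored_when_central_half_constant(self, sched_a):
        labels = np.full(40, 2.5)
        labels[:10] = 0.1
        labels[-10:] = 3.9  # edge quarter values differ
        series = make_series(sched_a, labels, freq=40.0)
        decisions = middle_of_second(series, sched_a)
        assert decisions["label"].iloc[0] == pytest.approx(2.5)

    def test_all_outlier_window_yields_outlier_decision(self, sched_a):
        series = make_series(sched_a, np.full(20, np.nan), freq=20.0)
        decisions = middle_of_second(series, sched_a)
        assert np.isnan(decisions["label"].iloc[0])


class TestAdaptableScheme:
    def test_perfect_series_rates_all_one(self, sched_a):
        labels = sched_a.label_stream(np.arange(120) / 10.0)
        rates = rf.adaptable_rate(make_series(sched_a, labels), sched_a)
        assert all(v == 1.0 for v in rates.values())

    def test_boundary_sample_decoding_to_next_motion_accepted(self, sched_a):
        """At the rest-down → flexion change, a label in the flexion range
        [3,4) within the trailing 10% of rest-down is still correct."""
        labels = sched_a.label_stream(np.arange(120) / 10.0)
        labels = labels.copy()
        labels[19] = 3.5  # last rest_down sample (trailing 10% of 20) decodes to flex
        series = make_series(sched_a, labels)
        assert rf.adaptable_rate(series, sched_a)["rest_down"] == 1.0
        assert strict_rate(series)["rest_down"] < 1.0

    def test_mid_segment_wrong_label_not_excused(self, sched_a):
        labels = sched_a.label_stream(np.arange(120) / 10.0)
        labels = labels.copy()
        labels[10] = 3.5  # middle of rest_down
        rates = rf.adaptable_rate(make_series(sched_a, labels), sched_a)
        assert rates["rest_down"] < 1.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_adaptable_never_below_strict(self, seed):
        """Motion-change tolerance only adds accepted outcomes."""
        sched = standard_schedule("A", cycles=1)
        rng = np.random.default_rng(seed)
        labels = rng.uniform(-1.0, 5.0, size=120)
        labels[rng.random(120) < 0.1] = np.nan  # sprinkle outliers
        series = make_series(sched, labels)
        adaptable = rf.adaptable_rate(series, sched)
        strict = strict_rate(series)
        for motion in sched.motion_names:
            assert adaptable[motion] >= strict[motion] - 1e-12

    def test_outliers_count_as_incorrect(self, sched_a):
        rates = rf.adaptable_rate(make_series(sched_a, np.full(120, np.nan)), sched_a)
        assert rates["average"] == 0.0


class TestQuartileScheme:
    def test_segment_of_400_splits_100_200_100(self):
        """The quartile cuts of a 400-sample segment fall at samples 100
        and 300: corrupting exactly the 100th sample hits the 25% set."""
        sched = standard_schedule("A", cycles=1)
        series = pd.DataFrame({
            "t": np.arange(400) / 400.0,
            "label": np.full(400, 0.5),
            "motion": ["rest_down"] * 400,
            "scheduled": ["rest_down"] * 400,
        })
        lab = series["label"].to_numpy().copy()
        lab[99] = -10.0   # last sample of the first quarter
        lab[100] = -10.0  # first sample of the central half
        series["label"] = lab
        series["motion"] = [sched.decode_label(v) for v in lab]
        q = rf.quartile_rates(series, sched)
        assert q["rest_down"][25] == pytest.approx(99 / 100)
        assert q["rest_down"][50] == pytest.approx(199 / 200)
        assert q["rest_down"][75] == 1.0

    def test_correct_only_in_central_half(self, sched_a):
        labels = sched_a.label_stream(np.arange(120) / 10.0)
        series = make_series(sched_a, labels)
        lab = series["label"].to_numpy().copy()
        # corrupt the outer quarters of every scheduled segment
        runs = (series["scheduled"] != series["scheduled"].shift()).cumsum()
        for _, group in series.groupby(runs):
            n = len(group)
            q1, q3 = n // 4, n - n // 4
            idx = group.index.to_numpy()
            lab[idx[:q1]] = -10.0
            lab[idx[q3:]] = -10.0
        out = series.copy()
        out["label"] = lab
        out["motion"] = [sched_a.decode_label(v) for v in lab]
        q = rf.quartile_rates(out, sched_a)
        for motion in sched_a.motion_names:
            assert q[motion] == {25: 0.0, 50: 1.0, 75: 0.0}

    def test_sets_partition_and_weighted_average_is_strict_rate(self, sched_a):
        """With one segment per motion, the quarter/half/quarter rates
        recombine into the strict per-motion rate (partition identity)."""
        rng = np.random.default_rng(1)
        labels = rng.uniform(-0.5, 4.5, size=240)
        series = make_series(sched_a, labels, freq=20.0)
        q = rf.quartile_rates(series, sched_a)
        strict = strict_rate(series)
        for motion in sched_a.motion_names:
            sel = series["scheduled"] == motion
            n = int(sel.sum())
            q1, q3 = n // 4, n - n // 4
            w = np.array([q1, q3 - q1, n - q3]) / n
            blended = w @ np.array([q[motion][25], q[motion][50], q[motion][75]])
            assert blended == pytest.approx(strict[motion])

    def test_short_segment_skipped_with_warning(self, sched_a):
        series = make_series(sched_a, [0.5, 0.5, 3.5], freq=1.0)
        with pytest.warns(UserWarning, match="skipped"):
            q = rf.quartile_rates(series, sched_a)
        assert "rest_down" not in q


class TestGrade:
    @pytest.mark.parametrize(
        "rate, level, accepted",
        [(0.85, 1, True), (1.0, 1, True), (0.7, 2, True), (0.5, 3, True),
         (0.41, 3, True), (0.3, 4, False), (0.1, 0, False), (0.4, 3, False)],
    )
    def test_bands_and_acceptance(self, rate, level, accepted):
        assert rf.grade(rate) == (level, accepted)

    def test_level_monotone_in_rate(self):
        rates = np.linspace(0.0, 1.0, 101)
        levels = [rf.grade(r)[0] if rf.grade(r)[0] != 0 else 5 for r in rates]
        assert all(a >= b for a, b in zip(levels, levels[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rf.grade(1.2)


class TestConfusion:
    def test_published_counts_reproduce_published_rates(self):
        """Feeding the published union-exercise decision counts through the
        rate formulas reproduces the printed cells at 2 dp."""
        published = {
            "A": ((15, 4, 0, 1), (0.79, 0.0, 1.0, 0.80)),
            "B": ((15, 1, 0, 4), (0.94, 0.0, 1.0, 0.95)),
            "C": ((5, 0, 6, 9), (1.0, 0.4, 0.6, 0.70)),
            "D": ((15, 4, 1, 0), (0.79, 1.0, 0.0, 0.75)),
            "E": ((7, 6, 0, 7), (0.54, 0.0, 1.0, 0.70)),
        }
        for counts, (tpr, fpr, tnr, acc) in published.values():
            r = rf.rates(ConfusionCounts(*counts))
            assert round(r["TPR"], 2) == tpr
            assert round(r["FPR"], 2) == fpr
            assert round(r["TNR"], 2) == tnr
            assert round(r["ACC"], 2) == acc

    def test_zero_denominators_reported_absent(self):
        r = rf.rates(ConfusionCounts(0, 0, 0, 0))
        assert all(v is None for v in r.values())
        r2 = rf.rates(ConfusionCounts(3, 1, 0, 0))
        assert r2["FPR"] is None and r2["TNR"] is None
        assert r2["TPR"] == pytest.approx(0.75)

    def test_counts_partition_decisions(self):
        sched = standard_schedule("A", cycles=1)
        rng = np.random.default_rng(0)
        labels = rng.uniform(-1, 5, size=60)
        labels[rng.random(60) < 0.2] = np.nan
        series = make_series(sched, labels, freq=5.0)
        decisions = middle_of_second(series, sched)
        ranges = [m.label_range for m in sched.motions]
        c = rf.confusion(decisions, sched, ranges)
        assert c.total == len(decisions)

    def test_hand_tallied_example(self):
        """Planted decisions vs a brute-force hand tally: target exercise
        owns [0,4); decisions 0.5/3.5 are in-exercise."""
        sched = standard_schedule("A", cycles=1)
        decisions = pd.DataFrame({
            "t": [0.5, 1.5, 2.5, 3.5, 4.5, 5.5],
            "label": [0.5, 0.5, 3.2, np.nan, 7.5, 25.0],
            "scheduled": ["rest_down", "rest_down", "flex", "flex", "flex", "flex"],
        })
        # all scheduled motions are in exercise A -> all positive
        # 0.5,0.5 correct TP; 3.2 decodes flex TP; NaN -> FN; 7.5 out of ranges -> FN; 25 -> FN
        c = rf.confusion(decisions, sched, [m.label_range for m in sched.motions])
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 3, 0, 0)

    def test_negative_scheduled_decisions(self):
        """Decisions whose scheduled motion is outside the target ranges
        count TN when the label stays outside too, FP when it intrudes."""
        sched = standard_schedule("A", cycles=1)
        decisions = pd.DataFrame({
            "t": [0.5, 1.5, 2.5],
            "label": [0.5, 7.0, np.nan],
            "scheduled": ["rest_down", "rest_down", "rest_down"],
        })
        # target = exercise B's ranges [4,8): scheduled rest_down is negative
        target = [(4.0, 8.0)]
        c = rf.confusion(decisions, sched, target)
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 0, 2, 1)
        # label 0.5 outside target -> TN; 7.0 inside -> FP; outlier -> FP
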