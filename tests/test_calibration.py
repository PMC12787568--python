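"""Whisker thresholds, cadences, and the stratified MCCV."""

import numpy as np
import pandas as pd
import pytest

from prosport import (
    Activity,
    MotionInterval,
    ThresholdSet,
    WindowSpec,
    cadence,
    calibrate_cadences,
    calibrate_thresholds,
    generate_short_term,
    mccv_split,
    run_mccv,
    threshold_between,
    whiskers,
)
from prosport.calibration import TRAIN_COUNTS, CalibrationWarning, concatenate_mis
from prosport.synthetic import ActivityProfile

FS = 12.5


class TestWhiskers:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 5], (1.0, 5.0)),
            # Q1=2, Q3=4 by linear interpolation; upper fence 7 -> whisker 4
            ([1, 2, 3, 4, 100], (1.0, 4.0)),
            ([3.5] * 6, (3.5, 3.5)),
        ],
    )
    def test_known_samples(self, values, expected):
        assert whiskers(np.array(values, dtype=float)) == expected

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            whiskers(np.array([1.0, 2.0, 3.0]))

    def test_whiskers_are_data_points_within_fences(self, rng):
        for _ in range(30):
            values = rng.normal(0, 1, rng.integers(4, 60))
            lo, hi = whiskers(values)
            assert lo in values and hi in values
            q1, q3 = np.percentile(values, [25, 75])
            iqr = q3 - q1
            assert lo >= q1 - 1.5 * iqr and hi <= q3 + 1.5 * iqr


class TestThresholdBetween:
    def test_midpoint_of_facing_whiskers(self):
        low = np.array([0.6, 0.8, 0.9, 1.0])
        high = np.array([1.4, 1.45, 1.5, 1.6])
        assert threshold_between(low, high) == pytest.approx(1.2)

    def test_overlap_warns_but_returns(self):
        sample = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(CalibrationWarning, match="overlap"):
            value = threshold_between(sample, sample)
        assert value == pytest.approx((sample.max() + sample.min()) / 2)

    def test_separates_generator_stop_and_walk_perfectly(self, activity_features):
        stop = activity_features[Activity.STOP]["cc_max_g"].to_numpy()
        walk = activity_features[Activity.WALK]["cc_max_g"].to_numpy()
        t1 = threshold_between(stop, walk)
        assert np.all(stop <= t1) and np.all(walk > t1)


class TestCalibrateThresholds:
    def test_threshold_ordering_on_generator_data(self, short_term):
        th = calibrate_thresholds(short_term)
        assert th.t1 > 0
        assert 0 < th.t2 < th.t3

    def test_missing_sprint_gives_absent_t3(self):
        ds = generate_short_term(ActivityProfile.triathlon(), seed=3)
        th = calibrate_thresholds(ds)
        assert th.t3 is None

    def test_missing_required_activity_is_an_error(self, short_term):
        stop_only = [
            i for i, mi in enumerate(short_term.mis) if mi.activity is Activity.STOP
        ]
        degenerate = concatenate_mis(short_term, stop_only)
        with pytest.raises(ValueError, match="Walk"):
            calibrate_thresholds(degenerate)

    def test_threshold_set_invariants(self):
        with pytest.raises(ValueError):
            ThresholdSet(t1=-1.0, t2=0.5, t3=1.0)
        with pytest.raises(ValueError):
            ThresholdSet(t1=1.0, t2=2.0, t3=1.0)


class TestCadence:
    @pytest.mark.parametrize(
        "strides,frames,expected", [(12, 180, 50.0), (10, 750, 10.0)]
    )
    def test_arithmetic(self, strides, frames, expected):
        mi = MotionInterval(Activity.WALK, 0, frames, strides)
        assert cadence(mi, FS) == pytest.approx(expected)

    def test_stop_rejected(self):
        mi = MotionInterval(Activity.STOP, 0, 300, 0)
        with pytest.raises(ValueError):
            cadence(mi, FS)

    def test_recovers_generator_cadence_per_mi(self, short_term):
        for mi in short_term.mis:
            if mi.activity is Activity.STOP:
                continue
            truth = {Activity.WALK: 53.0, Activity.JOG: 80.0, Activity.SPRINT: 120.0}[
                mi.activity
            ]
            duration_min = mi.n_frames / (FS * 60)
            assert cadence(mi, FS) == pytest.approx(
                truth, abs=1 / (2 * duration_min)
            )

    def test_aggregation_modes_agree_on_uniform_cadence(self, short_term):
        by_mean = calibrate_cadences(short_term, "mean_of_mi")
        pooled = calibrate_cadences(short_term, "pooled")
        assert by_mean.walk == pytest.approx(pooled.walk, rel=0.01)
        assert by_mean.jog == pytest.approx(pooled.jog, rel=0.01)


class TestMccvSplit:
    def test_stratified_counts(self, short_term):
        splits = mccv_split(short_term, n_iter=5, seed=0)
        for split in splits:
            train_counts = split.train.activity_counts()
            assert {a: train_counts[a] for a in TRAIN_COUNTS} == TRAIN_COUNTS
            originals = [mi for mi in split.test.mis if not mi.ignore]
            dupes = [mi for mi in split.test.mis if mi.ignore]
            assert len(split.train.mis) == 14
            assert len(originals) == 15  # 4 + 4 + 4 + 3
            assert len(dupes) == 8  # first+last per activity block
            assert not set(split.train_indices) & set(split.test_indices)

    def test_blocks_follow_the_fixed_activity_order(self, short_term):
        split = mccv_split(short_term, n_iter=1, seed=4)[0]
        for ds in (split.train, split.test):
            order = [mi.activity for mi in ds.mis]
            assert order == sorted(order)
            spans = [(mi.start_frame, mi.end_frame) for mi in ds.mis]
            assert spans[0][0] == 0
            assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))
            assert spans[-1][1] == ds.signal.n_frames

    def test_duplicates_mirror_block_edges(self, short_term):
        split = mccv_split(short_term, n_iter=1, seed=9)[0]
        for activity in Activity:
            block = [mi for mi in split.test.mis if mi.activity is activity]
            if not block:
                continue
            assert block[0].ignore and block[-1].ignore
            assert block[0].n_frames == block[1].n_frames
            assert block[-1].n_frames == block[-2].n_frames

    def test_same_seed_reproduces_the_splits(self, short_term):
        a = mccv_split(short_term, n_iter=3, seed=11)
        b = mccv_split(short_term, n_iter=3, seed=11)
        assert [s.train_indices for s in a] == [s.train_indices for s in b]
        assert [s.test_indices for s in a] == [s.test_indices for s in b]

    def test_triathlon_sessions_split_without_sprint(self):
        ds = generate_short_term(ActivityProfile.triathlon(), seed=3)
        assert len(ds.mis) == 24
        split = mccv_split(ds, n_iter=1, seed=0)[0]
        counts = split.train.activity_counts()
        assert counts[Activity.SPRINT] == 0
        assert all(counts[a] == 4 for a in (Activity.STOP, Activity.WALK, Activity.JOG))
        test_counts = split.test.activity_counts()
        assert test_counts[Activity.SPRINT] == 0

    def test_insufficient_mis_reported_with_counts(self, short_term):
        few = concatenate_mis(short_term, list(range(12)))
        with pytest.raises(ValueError, match="have"):
            mccv_split(few, n_iter=1, seed=0)


class TestRunMccv:
    def test_final_values_are_iteration_means(self, mccv_result):
        mccv = mccv_result.mccv
        assert mccv.thresholds.t1 == pytest.approx(
            mccv.thresholds_by_iter["t1"].mean()
        )
        assert mccv.cadences.jog == pytest.approx(
            mccv.cadences_by_iter["jog"].mean()
        )
        assert len(mccv.thresholds_by_iter) == 50

    def test_identical_seed_is_bit_identical(self, short_term):
        a = run_mccv(short_term, n_iter=3, seed=21)
        b = run_mccv(short_term, n_iter=3, seed=21)
        pd.testing.assert_frame_equal(a.thresholds_by_iter, b.thresholds_by_iter)
        pd.testing.assert_frame_equal(a.cadences_by_iter, b.cadences_by_iter)
        for x, y in zip(a.pred, b.pred):
            np.testing.assert_array_equal(x, y)

    def test_threshold_ordering_holds_every_iteration(self, mccv_result):
        by_iter = mccv_result.mccv.thresholds_by_iter
        assert (by_iter["t2"] < by_iter["t3"]).all()
        assert (by_iter["t1"] > 0).all()

    def test_ignored_frames_are_excluded_from_scoring(self, mccv_result):
        mccv = mccv_result.mccv
        for gold, mask in zip(mccv.gold, mccv.mask):
            assert mask.sum() < gold.size  # duplicates exist and are masked
            assert gold[mask].min() >= 1
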