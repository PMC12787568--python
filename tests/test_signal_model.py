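"""Data types, CSV round-trips, and axis reorientation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prosport import (
    AccelSignal,
    Activity,
    LabelledDataset,
    MotionInterval,
    MountingConfig,
    read_labels_csv,
    read_signal_csv,
    reorient,
    write_labels_csv,
    write_signal_csv,
)
from prosport.signal_model import LabelFormatError, SignalFormatError

FS = 12.5


def make_signal(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return AccelSignal(
        ap=rng.normal(0, 1, n), cc=1 + rng.normal(0, 0.1, n), ml=rng.normal(0, 1, n),
        fs=FS,
    )


class TestAccelSignal:
    def test_validation_rejects_bad_shapes_and_values(self):
        with pytest.raises(ValueError):
            AccelSignal(ap=np.zeros(3), cc=np.zeros(4), ml=np.zeros(3))
        with pytest.raises(ValueError):
            AccelSignal(ap=np.array([np.nan]), cc=np.zeros(1), ml=np.zeros(1))
        with pytest.raises(ValueError):
            AccelSignal(ap=np.array([20.0]), cc=np.zeros(1), ml=np.zeros(1))
        with pytest.raises(ValueError):
            AccelSignal(ap=np.zeros(0), cc=np.zeros(0), ml=np.zeros(0))

    def test_slice_and_concatenate_are_inverse(self):
        sig = make_signal(100)
        parts = [sig.slice(0, 40), sig.slice(40, 100)]
        back = AccelSignal.concatenate(parts)
        np.testing.assert_array_equal(back.ap, sig.ap)
        np.testing.assert_array_equal(back.cc, sig.cc)
        assert parts[1].t0 == sig.time_at(40)


class TestSignalCsv:
    def test_identity_read_back(self, tmp_path):
        path = tmp_path / "sig.csv"
        sig = AccelSignal(ap=np.zeros(4), cc=np.ones(4), ml=np.zeros(4), fs=FS)
        write_signal_csv(path, sig)
        back = read_signal_csv(path, fs=FS)
        assert back.n_frames == 4
        np.testing.assert_array_equal(back.cc, np.ones(4))

    def test_round_trip_preserves_values(self, tmp_path):
        path = tmp_path / "sig.csv"
        sig = make_signal(60)
        write_signal_csv(path, sig)
        back = read_signal_csv(path, fs=FS)
        assert back.n_frames == sig.n_frames
        np.testing.assert_allclose(back.ap, sig.ap, rtol=1e-9)
        np.testing.assert_allclose(back.cc, sig.cc, rtol=1e-9)
        np.testing.assert_allclose(back.ml, sig.ml, rtol=1e-9)

    def test_timestamp_gap_is_an_error_naming_the_row(self, tmp_path):
        path = tmp_path / "sig.csv"
        sig = make_signal(10)
        write_signal_csv(path, sig)
        lines = path.read_text().splitlines()
        # open a 1 s hole before the last row
        t, rest = lines[-1].split(",", 1)
        from datetime import datetime, timedelta

        lines[-1] = (datetime.fromisoformat(t) + timedelta(seconds=1)).isoformat() + "," + rest
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SignalFormatError, match="row 11"):
            read_signal_csv(path, fs=FS)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        path = tmp_path / "sig.csv"
        sig = make_signal(5)
        write_signal_csv(path, sig)
        lines = path.read_text().splitlines()
        # repeat the previous timestamp: zero gap
        t_prev = lines[2].split(",", 1)[0]
        lines[3] = t_prev + "," + lines[3].split(",", 1)[1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SignalFormatError, match="non-monotone"):
            read_signal_csv(path, fs=FS)

    def test_malformed_row_rejected(self, tmp_path):
        path = tmp_path / "sig.csv"
        path.write_text("time_iso8601,ax_g,ay_g,az_g\n2024-07-01T08:00:00,a,0,0\n")
        with pytest.raises(SignalFormatError, match="malformed"):
            read_signal_csv(path, fs=FS)


class TestReorient:
    def test_identity_config_is_a_no_op(self):
        sig = make_signal(20)
        out = reorient(sig, MountingConfig.identity())
        np.testing.assert_array_equal(out.ap, sig.ap)
        np.testing.assert_array_equal(out.cc, sig.cc)
        np.testing.assert_array_equal(out.ml, sig.ml)

    def test_permutation_with_sign_flip(self):
        sig = AccelSignal(ap=np.array([1.0]), cc=np.array([2.0]), ml=np.array([3.0]))
        cfg = MountingConfig(ap=(2, -1), cc=(3, 1), ml=(1, 1))
        out = reorient(sig, cfg)
        assert (out.ap[0], out.cc[0], out.ml[0]) == (-2.0, 3.0, 1.0)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            MountingConfig(ap=(1, 1), cc=(1, 1), ml=(3, 1))

    @given(
        perm=st.permutations([1, 2, 3]),
        signs=st.tuples(*[st.sampled_from([-1, 1])] * 3),
    )
    def test_inverse_config_restores_input_bit_exactly(self, perm, signs):
        sig = make_signal(16, seed=7)
        cfg = MountingConfig(
            ap=(perm[0], signs[0]), cc=(perm[1], signs[1]), ml=(perm[2], signs[2])
        )
        back = reorient(reorient(sig, cfg), cfg.inverse())
        np.testing.assert_array_equal(back.ap, sig.ap)
        np.testing.assert_array_equal(back.cc, sig.cc)
        np.testing.assert_array_equal(back.ml, sig.ml)

    def test_gravity_moves_to_cc(self):
        # standing still with gravity on device axis 3
        rng = np.random.default_rng(0)
        sig = AccelSignal(
            ap=rng.normal(0, 0.01, 200),
            cc=rng.normal(0, 0.01, 200),
            ml=1.0 + rng.normal(0, 0.01, 200),
            fs=FS,
        )
        cfg = MountingConfig(ap=(1, 1), cc=(3, 1), ml=(2, 1))
        out = reorient(sig, cfg)
        assert abs(out.cc.mean() - 1.0) < 0.01
        assert abs(out.ap.mean()) < 0.01 and abs(out.ml.mean()) < 0.01

    def test_mounting_yaml_round_trip(self, tmp_path):
        cfg = MountingConfig(ap=(3, -1), cc=(1, 1), ml=(2, -1))
        path = tmp_path / "mount.yaml"
        cfg.to_yaml(path)
        assert MountingConfig.from_yaml(path) == cfg


class TestLabels:
    def test_walk_row_parses(self, tmp_path):
        sig = make_signal(200)
        path = tmp_path / "labels.csv"
        path.write_text("activity,start_frame,end_frame,strides\nWalk,0,180,12\n")
        ds = read_labels_csv(path, sig)
        (mi,) = ds.mis
        assert mi.activity is Activity.WALK
        assert (mi.start_frame, mi.end_frame, mi.strides) == (0, 180, 12)

    def test_stop_with_strides_rejected(self, tmp_path):
        sig = make_signal(400)
        path = tmp_path / "labels.csv"
        path.write_text("activity,start_frame,end_frame,strides\nStop,0,300,3\n")
        with pytest.raises(LabelFormatError, match="0 strides"):
            read_labels_csv(path, sig)

    def test_overlapping_intervals_rejected(self, tmp_path):
        sig = make_signal(200)
        path = tmp_path / "labels.csv"
        path.write_text(
            "activity,start_frame,end_frame,strides\nWalk,0,100,8\nJog,50,150,8\n"
        )
        with pytest.raises(LabelFormatError, match="overlap"):
            read_labels_csv(path, sig)

    def test_unknown_activity_rejected(self, tmp_path):
        sig = make_signal(200)
        path = tmp_path / "labels.csv"
        path.write_text("activity,start_frame,end_frame,strides\nSwim,0,100,8\n")
        with pytest.raises(LabelFormatError, match="Swim"):
            read_labels_csv(path, sig)

    def test_short_stop_warns_but_loads(self, tmp_path):
        sig = make_signal(200)
        path = tmp_path / "labels.csv"
        path.write_text("activity,start_frame,end_frame,strides\nStop,0,100,0\n")
        with pytest.warns(UserWarning, match="20 s"):
            ds = read_labels_csv(path, sig)
        assert len(ds.mis) == 1

    def test_out_of_range_interval_rejected(self):
        sig = make_signal(100)
        with pytest.raises(LabelFormatError, match="beyond"):
            LabelledDataset(
                signal=sig, mis=(MotionInterval(Activity.WALK, 50, 150, 10),)
            )

    def test_order_is_preserved(self, short_term, tmp_path):
        path = tmp_path / "labels.csv"
        write_labels_csv(path, short_term)
        back = read_labels_csv(path, short_term.signal)
        assert [mi.activity for mi in back.mis] == [
            mi.activity for mi in short_term.mis
        ]
        assert [mi.start_frame for mi in back.mis] == [
            mi.start_frame for mi in short_term.mis
        ]
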