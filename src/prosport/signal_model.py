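"""Core data types and file I/O for low-rate prosthesis-mounted accelerometry.

The package works on triaxial acceleration recorded at the prosthetic socket
(or running-foot pylon) at 12.5 Hz, expressed in g.  Raw device axes are
remapped to a standardized anatomical frame -- anterior-posterior (AP),
caudal-cranial (CC) and medio-lateral (ML) -- so that features and thresholds
are comparable across athletes regardless of how the sensor was taped on.

A labelled recording is a sequence of *motion intervals* (MIs): contiguous
bursts of a single activity (Stop, Walk, Jog, Sprint), each carrying a
manually counted gold-standard stride count.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import yaml

__all__ = [
    "Activity",
    "AccelSignal",
    "MountingConfig",
    "MotionInterval",
    "LabelledDataset",
    "SignalFormatError",
    "LabelFormatError",
    "read_signal_csv",
    "write_signal_csv",
    "read_labels_csv",
    "write_labels_csv",
    "reorient",
    "DEFAULT_FS",
    "MIN_STOP_DURATION_S",
]

DEFAULT_FS = 12.5
#: labelled Stop intervals are expected to last at least this long
MIN_STOP_DURATION_S = 20.0
#: accelerometer full-scale range in g (AX6-class MEMS device)
DEFAULT_ACCEL_RANGE_G = 16.0


class SignalFormatError(ValueError):
    """Raised for malformed or inconsistent signal CSV files."""


class LabelFormatError(ValueError):
    """Raised for malformed or inconsistent motion-interval label files."""


class Activity(enum.IntEnum):
    """Activity classes, ordered by intensity; values are evaluation-array tags."""

    STOP = 1
    WALK = 2
    JOG = 3
    SPRINT = 4

    @classmethod
    def parse(cls, token: str) -> "Activity":
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise LabelFormatError(
                f"unknown activity token {token!r}; expected one of "
                f"{[a.name.capitalize() for a in cls]}"
            ) from None

    @property
    def label(self) -> str:
        return self.name.capitalize()


@dataclass(frozen=True)
class AccelSignal:
    """Uniformly sampled triaxial acceleration in g.

    The three axis arrays are interpreted as AP/CC/ML once :func:`reorient`
    has been applied; straight from :func:`read_signal_csv` they carry the
    raw device columns 1..3 in file order.
    """

    ap: np.ndarray
    cc: np.ndarray
    ml: np.ndarray
    fs: float = DEFAULT_FS
    t0: datetime = field(default_factory=lambda: datetime(2024, 7, 1, 8, 0, 0))
    accel_range_g: float = DEFAULT_ACCEL_RANGE_G

    def __post_init__(self):
        for name in ("ap", "cc", "ml"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.ap.shape[0]
        if self.cc.shape != (n,) or self.ml.shape != (n,) or self.ap.ndim != 1:
            raise ValueError("axis arrays must be 1-D and of identical length")
        if n < 1:
            raise ValueError("signal must contain at least one frame")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        for name in ("ap", "cc", "ml"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values on axis {name!r}")
            if np.any(np.abs(arr) > self.accel_range_g):
                raise ValueError(
                    f"axis {name!r} exceeds the accelerometer range "
                    f"of +/-{self.accel_range_g} g"
                )

    @property
    def n_frames(self) -> int:
        return self.ap.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs

    def time_at(self, frame: int) -> datetime:
        """Absolute time of a frame index (frame 0 is t0)."""
        return self.t0 + timedelta(seconds=frame / self.fs)

    def slice(self, start: int, end: int) -> "AccelSignal":
        """Frame span [start, end) as a new signal; t0 is shifted accordingly."""
        if not (0 <= start < end <= self.n_frames):
            raise ValueError(f"invalid frame span [{start}, {end})")
        return replace(
            self,
            ap=self.ap[start:end].copy(),
            cc=self.cc[start:end].copy(),
            ml=self.ml[start:end].copy(),
            t0=self.time_at(start),
        )

    @staticmethod
    def concatenate(parts: list["AccelSignal"]) -> "AccelSignal":
        if not parts:
            raise ValueError("nothing to concatenate")
        fs = parts[0].fs
        if any(p.fs != fs for p in parts):
            raise ValueError("all parts must share the sampling rate")
        return replace(
            parts[0],
            ap=np.concatenate([p.ap for p in parts]),
            cc=np.concatenate([p.cc for p in parts]),
            ml=np.concatenate([p.ml for p in parts]),
        )


@dataclass(frozen=True)
class MountingConfig:
    """Mapping from device axis columns to anatomical axes.

    Each anatomical axis names the 1-based device column it comes from and a
    sign flip; the three source columns must form a permutation of {1, 2, 3}.
    Only permutation and sign are supported: a small residual tilt of the
    sensor relative to gravity (as with foot-pylon mounting) is deliberately
    not corrected.
    """

    ap: tuple[int, int] = (1, 1)
    cc: tuple[int, int] = (2, 1)
    ml: tuple[int, int] = (3, 1)

    def __post_init__(self):
        axes = [self.ap[0], self.cc[0], self.ml[0]]
        if sorted(axes) != [1, 2, 3]:
            raise ValueError(
                f"source device axes {axes} must be a permutation of (1, 2, 3)"
            )
        for name in ("ap", "cc", "ml"):
            if getattr(self, name)[1] not in (-1, 1):
                raise ValueError(f"sign for {name} must be +1 or -1")

    @classmethod
    def identity(cls) -> "MountingConfig":
        return cls()

    def inverse(self) -> "MountingConfig":
        """Config that undoes this one (device <- anatomical)."""
        inv = {}
        for i, name in enumerate(("ap", "cc", "ml"), start=1):
            axis, sign = getattr(self, name)
            inv[axis] = (i, sign)
        return MountingConfig(ap=inv[1], cc=inv[2], ml=inv[3])

    @classmethod
    def from_yaml(cls, path) -> "MountingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            kwargs = {
                name: (int(raw[name]["axis"]), int(raw[name]["sign"]))
                for name in ("ap", "cc", "ml")
            }
        except (KeyError, TypeError) as exc:
            raise ValueError(
                f"mounting config {path} must define ap/cc/ml with axis and sign"
            ) from exc
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = {
            name: {"axis": getattr(self, name)[0], "sign": getattr(self, name)[1]}
            for name in ("ap", "cc", "ml")
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def reorient(raw: AccelSignal, cfg: MountingConfig) -> AccelSignal:
    """Realign raw device axes into the anatomical AP/CC/ML frame."""
    device = {1: raw.ap, 2: raw.cc, 3: raw.ml}
    out = {}
    for name in ("ap", "cc", "ml"):
        axis, sign = getattr(cfg, name)
        out[name] = sign * device[axis]
    return replace(raw, **out)


@dataclass(frozen=True)
class MotionInterval:
    """A burst of one activity over the half-open frame span [start, end).

    ``strides`` is the gold-standard manual stride count (0 for Stop); it is
    ``None`` for intervals produced by automatic segmentation, where strides
    are estimated from cadence instead.  ``ignore`` flags edge-duplicated
    copies inserted in cross-validation test sets, which provide realistic
    activity transitions but are excluded from all scoring.
    """

    activity: Activity
    start_frame: int
    end_frame: int
    strides: int | None = None
    ignore: bool = False

    def __post_init__(self):
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(
                f"invalid frame span [{self.start_frame}, {self.end_frame})"
            )
        if self.strides is not None:
            if self.strides < 0:
                raise ValueError("stride count must be non-negative")
            if self.activity is Activity.STOP and self.strides != 0:
                raise LabelFormatError(
                    f"Stop interval [{self.start_frame}, {self.end_frame}) "
                    f"must have 0 strides, got {self.strides}"
                )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def duration_s(self, fs: float) -> float:
        return self.n_frames / fs

    def shifted(self, offset: int) -> "MotionInterval":
        return replace(
            self, start_frame=self.start_frame + offset, end_frame=self.end_frame + offset
        )


@dataclass(frozen=True)
class LabelledDataset:
    """An accelerometer signal together with its ordered motion intervals."""

    signal: AccelSignal
    mis: tuple[MotionInterval, ...]

    def __post_init__(self):
        object.__setattr__(self, "mis", tuple(self.mis))
        bad = [
            mi for mi in self.mis
            if mi.start_frame < 0 or mi.end_frame > self.signal.n_frames
        ]
        if bad:
            raise LabelFormatError(
                f"{len(bad)} motion interval(s) extend beyond the signal of "
                f"{self.signal.n_frames} frames: first offender "
                f"[{bad[0].start_frame}, {bad[0].end_frame})"
            )
        spans = sorted((mi.start_frame, mi.end_frame) for mi in self.mis)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise LabelFormatError(
                    f"overlapping motion intervals: [{s1}, {e1}) and [{s2}, {e2})"
                )

    def by_activity(self, activity: Activity) -> list[MotionInterval]:
        return [mi for mi in self.mis if mi.activity is activity]

    def activity_counts(self) -> dict[Activity, int]:
        return {a: len(self.by_activity(a)) for a in Activity}

    @property
    def has_sprint(self) -> bool:
        return any(mi.activity is Activity.SPRINT for mi in self.mis)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

SIGNAL_HEADER = ["time_iso8601", "ax_g", "ay_g", "az_g"]
LABEL_HEADER = ["activity", "start_frame", "end_frame", "strides"]


def read_signal_csv(path, fs: float = DEFAULT_FS) -> AccelSignal:
    """Read a triaxial signal CSV (timestamp + three device-axis columns in g).

    The returned signal is in DEVICE axis order: apply :func:`reorient` with
    the athlete's :class:`MountingConfig` before feature extraction.
    Timestamps must be monotone and uniformly spaced at 1/fs within 10%.
    """
    times: list[datetime] = []
    cols: tuple[list[float], list[float], list[float]] = ([], [], [])
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != SIGNAL_HEADER:
            raise SignalFormatError(
                f"{path}: expected header {','.join(SIGNAL_HEADER)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise SignalFormatError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            try:
                times.append(datetime.fromisoformat(row[0]))
                for c, v in zip(cols, row[1:]):
                    c.append(float(v))
            except ValueError as exc:
                raise SignalFormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
    if not times:
        raise SignalFormatError(f"{path}: no data rows")
    expected = 1.0 / fs
    for i, (t_prev, t_next) in enumerate(zip(times, times[1:])):
        gap = (t_next - t_prev).total_seconds()
        if gap <= 0:
            raise SignalFormatError(
                f"{path}: non-monotone timestamp at row {i + 3}"
            )
        if abs(gap - expected) > 0.1 * expected:
            raise SignalFormatError(
                f"{path}: timestamp gap of {gap:.6g} s at row {i + 3} deviates "
                f"more than 10% from the {expected:.6g} s sampling period"
            )
    return AccelSignal(
        ap=np.array(cols[0]), cc=np.array(cols[1]), ml=np.array(cols[2]),
        fs=fs, t0=times[0],
    )


def write_signal_csv(path, signal: AccelSignal) -> None:
    """Write a signal in the package's CSV dialect (device or anatomical order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SIGNAL_HEADER)
        for i in range(signal.n_frames):
            t = signal.time_at(i)
            writer.writerow(
                [t.isoformat(), repr(float(signal.ap[i])),
                 repr(float(signal.cc[i])), repr(float(signal.ml[i]))]
            )


def read_labels_csv(path, signal: AccelSignal) -> LabelledDataset:
    """Read motion-interval labels (activity, start_frame, end_frame, strides).

    Stop intervals shorter than the conventional 20 s minimum trigger a
    warning but are kept; structural problems (unknown activity, non-zero
    Stop strides, overlap, out-of-range spans) are rejected.
    """
    mis: list[MotionInterval] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != LABEL_HEADER:
            raise LabelFormatError(
                f"{path}: expected header {','.join(LABEL_HEADER)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LabelFormatError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            activity = Activity.parse(row[0])
            try:
                start, end, strides = int(row[1]), int(row[2]), int(row[3])
            except ValueError as exc:
                raise LabelFormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            try:
                mi = MotionInterval(activity, start, end, strides)
            except ValueError as exc:
                raise LabelFormatError(f"{path}:{lineno}: {exc}") from exc
            if activity is Activity.STOP and mi.duration_s(signal.fs) < MIN_STOP_DURATION_S:
                warnings.warn(
                    f"{path}:{lineno}: Stop interval lasts "
                    f"{mi.duration_s(signal.fs):.1f} s, shorter than the "
                    f"conventional {MIN_STOP_DURATION_S:.0f} s minimum",
                    stacklevel=2,
                )
            mis.append(mi)
    return LabelledDataset(signal=signal, mis=tuple(mis))


def write_labels_csv(path, dataset: LabelledDataset) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LABEL_HEADER)
        for mi in dataset.mis:
            writer.writerow(
                [mi.activity.label, mi.start_frame, mi.end_frame,
                 0 if mi.strides is None else mi.strides]
            )
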