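"""Seedable generator of prosthetic-gait accelerometer fixtures.

The study population's raw recordings are privacy-restricted, so tests and
examples run on synthetic signals with a known activity schedule, cadence
and stride count per motion interval.

Each non-Stop segment is built from a smooth impact train: the caudal-cranial
axis carries +1 g of gravity plus one raised-cosine-shaped impact per stride
(``sin^4(pi * f0 * t)``, i.e. a positive bump train with mean 3/8, a
fundamental at the stride frequency f0 = cadence/60 and a single harmonic at
2*f0); the anterior-posterior axis carries the same impact train plus a slow
propulsion/sway oscillation at 0.5 Hz whose in-band energy makes the
low-frequency wavelet peak grow proportionally with activity amplitude.
White Gaussian noise is added per axis.  Sprint segments ramp their
amplitude envelope linearly from half to full scale over the first ~2 s
(the start from a still position); cadence is kept constant within a
segment so gold stride counts stay exactly integer.

Segment durations are snapped so a whole number of impact peaks falls inside
the segment: the gold stride count both equals ``round(cadence * duration)``
and is recoverable from the noiseless waveform by peak counting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np
import yaml

from .signal_model import (
    AccelSignal,
    Activity,
    LabelledDataset,
    MotionInterval,
    write_labels_csv,
    write_signal_csv,
)

__all__ = [
    "ActivityParams",
    "ActivityProfile",
    "generate",
    "generate_short_term",
    "short_term_schedule",
    "write_fixture",
    "profile_from_yaml",
    "profile_to_yaml",
]

Schedule = list[tuple[Activity, float]]


@dataclass(frozen=True)
class ActivityParams:
    """Waveform parameters of one cyclic activity."""

    cadence_spm: float        # strides per minute
    ap_amplitude_g: float     # scales the whole AP oscillation
    cc_amplitude_g: float     # peak height of the CC impact train
    noise_sd_g: float

    def __post_init__(self):
        if self.cadence_spm <= 0:
            raise ValueError("cadence must be positive")
        if min(self.ap_amplitude_g, self.cc_amplitude_g, self.noise_sd_g) < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")


@dataclass(frozen=True)
class ActivityProfile:
    """Per-activity waveform parameters for one synthetic athlete.

    Default cadences follow typical elite running-prosthesis values
    (Walk 53, Jog 80, Sprint 120 strides/min); amplitudes are ordered so the
    classifier's two features separate the activities by construction, with
    cc_max at Stop near 1 g and the Stop/Walk threshold landing near 1.2 g.
    ``sprint=None`` models triathletes, whose sessions contain no Sprint.
    """

    walk: ActivityParams = ActivityParams(53.0, 0.55, 0.5, 0.05)
    jog: ActivityParams = ActivityParams(80.0, 1.2, 2.2, 0.08)
    sprint: ActivityParams | None = ActivityParams(120.0, 3.5, 4.5, 0.12)
    stop_noise_sd_g: float = 0.02
    gravity_g: float = 1.0
    sway_freq_hz: float = 0.5
    sway_weight: float = 0.6
    sprint_ramp_s: float = 2.0
    sprint_ramp_start: float = 0.5

    @classmethod
    def triathlon(cls) -> "ActivityProfile":
        """Variant without Sprint, as for triathlon training sessions."""
        return replace(cls(), sprint=None)

    def params(self, activity: Activity) -> ActivityParams | None:
        return {
            Activity.WALK: self.walk,
            Activity.JOG: self.jog,
            Activity.SPRINT: self.sprint,
        }.get(activity)


def _snap_segment(activity: Activity, duration_s: float, fs: float,
                  profile: ActivityProfile) -> tuple[int, int]:
    """Frames and gold strides of a segment, snapped to whole strides.

    The frame count is floored so that exactly ``round(cadence * duration)``
    impact peaks (at phase 0.5, 1.5, ...) fall inside the half-open segment.
    """
    if duration_s <= 0:
        raise ValueError("segment durations must be positive")
    if activity is Activity.STOP:
        return max(int(round(duration_s * fs)), 1), 0
    params = profile.params(activity)
    if params is None:
        raise ValueError(f"profile defines no parameters for {activity.label}")
    f0 = params.cadence_spm / 60.0
    if f0 > fs / 2:
        raise ValueError(
            f"{activity.label} stride frequency {f0:.2f} Hz exceeds the "
            f"Nyquist frequency {fs / 2:.2f} Hz"
        )
    strides = max(int(round(f0 * duration_s)), 1)
    n = int(np.floor(strides / f0 * fs))
    return n, strides


def _segment_waveform(
    activity: Activity, n: int, fs: float, profile: ActivityProfile,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.arange(n) / fs
    if activity is Activity.STOP:
        sd = profile.stop_noise_sd_g
        return (
            rng.normal(0.0, sd, n),
            profile.gravity_g + rng.normal(0.0, sd, n),
            rng.normal(0.0, sd, n),
        )
    params = profile.params(activity)
    f0 = params.cadence_spm / 60.0
    bump = np.sin(np.pi * f0 * t) ** 4          # one impact per stride
    env = np.ones(n)
    if activity is Activity.SPRINT:
        ramp_n = min(int(round(profile.sprint_ramp_s * fs)), n)
        if ramp_n > 0:
            env[:ramp_n] = np.linspace(profile.sprint_ramp_start, 1.0, ramp_n)
    sway_phase = rng.uniform(0.0, 2.0 * np.pi)
    sway = np.sin(2.0 * np.pi * profile.sway_freq_hz * t + sway_phase)
    sd = params.noise_sd_g
    ap = params.ap_amplitude_g * env * (profile.sway_weight * sway + bump)
    ap = ap + rng.normal(0.0, sd, n)
    cc = profile.gravity_g + params.cc_amplitude_g * env * bump + rng.normal(0.0, sd, n)
    ml = rng.normal(0.0, sd, n)
    return ap, cc, ml


def generate(
    profile: ActivityProfile,
    schedule: Schedule,
    fs: float = 12.5,
    seed: int | np.random.Generator | None = None,
    t0: datetime | None = None,
) -> tuple[AccelSignal, LabelledDataset]:
    """Synthesize a reoriented signal and its gold labels from a schedule.

    ``schedule`` is an ordered list of (activity, duration in seconds);
    activities may be given as :class:`Activity` members or name strings.
    Identical seeds give bit-identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not schedule:
        raise ValueError("schedule is empty")
    aps, ccs, mls, mis = [], [], [], []
    cursor = 0
    for entry, duration_s in schedule:
        activity = entry if isinstance(entry, Activity) else Activity.parse(entry)
        n, strides = _snap_segment(activity, float(duration_s), fs, profile)
        ap, cc, ml = _segment_waveform(activity, n, fs, profile, rng)
        aps.append(ap)
        ccs.append(cc)
        mls.append(ml)
        mis.append(
            MotionInterval(
                activity=activity, start_frame=cursor, end_frame=cursor + n,
                strides=strides,
            )
        )
        cursor += n
    kwargs = {} if t0 is None else {"t0": t0}
    signal = AccelSignal(
        ap=np.concatenate(aps), cc=np.concatenate(ccs), ml=np.concatenate(mls),
        fs=fs, **kwargs,
    )
    return signal, LabelledDataset(signal=signal, mis=tuple(mis))


def short_term_schedule(
    profile: ActivityProfile, rng: np.random.Generator
) -> Schedule:
    """A randomized calibration-session schedule.

    8 Stop (20-30 s each), 8 Walk and 8 Jog (10-15 strides each), and, when
    the profile has Sprint parameters, 5 Sprint (16-24 strides each), in
    shuffled order.
    """
    entries: Schedule = []
    for _ in range(8):
        entries.append((Activity.STOP, float(rng.uniform(20.0, 30.0))))
    for activity, n_mi, lo, hi in (
        (Activity.WALK, 8, 10, 15),
        (Activity.JOG, 8, 10, 15),
        (Activity.SPRINT, 5, 16, 24),
    ):
        params = profile.params(activity)
        if params is None:
            continue
        f0 = params.cadence_spm / 60.0
        for _ in range(n_mi):
            strides = int(rng.integers(lo, hi + 1))
            entries.append((activity, strides / f0))
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


def generate_short_term(
    profile: ActivityProfile | None = None,
    seed: int | None = None,
    fs: float = 12.5,
    t0: datetime | None = None,
) -> LabelledDataset:
    """A labelled short-term calibration session for one synthetic athlete."""
    profile = profile or ActivityProfile()
    rng = np.random.default_rng(seed)
    schedule = short_term_schedule(profile, rng)
    _, dataset = generate(profile, schedule, fs=fs, seed=rng, t0=t0)
    return dataset


def write_fixture(dataset: LabelledDataset, signal_path, labels_path) -> None:
    """Dump a generated dataset in the package's CSV dialects."""
    write_signal_csv(signal_path, dataset.signal)
    write_labels_csv(labels_path, dataset)


# --- profile (de)serialization for the command line ------------------------

_PARAM_FIELDS = ("cadence_spm", "ap_amplitude_g", "cc_amplitude_g", "noise_sd_g")


def profile_to_yaml(profile: ActivityProfile, path) -> None:
    data = {
        "stop_noise_sd_g": profile.stop_noise_sd_g,
        "gravity_g": profile.gravity_g,
        "sway_freq_hz": profile.sway_freq_hz,
        "sway_weight": profile.sway_weight,
        "sprint_ramp_s": profile.sprint_ramp_s,
        "sprint_ramp_start": profile.sprint_ramp_start,
    }
    for name in ("walk", "jog", "sprint"):
        params = getattr(profile, name)
        data[name] = (
            None if params is None
            else {f: getattr(params, f) for f in _PARAM_FIELDS}
        )
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def profile_from_yaml(path) -> ActivityProfile:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for name in ("walk", "jog", "sprint"):
        if name in raw:
            entry = raw[name]
            kwargs[name] = None if entry is None else ActivityParams(
                **{f: float(entry[f]) for f in _PARAM_FIELDS}
            )
    for name in (
        "stop_noise_sd_g", "gravity_g", "sway_freq_hz", "sway_weight",
        "sprint_ramp_s", "sprint_ramp_start",
    ):
        if name in raw:
            kwargs[name] = float(raw[name])
    return ActivityProfile(**kwargs)
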