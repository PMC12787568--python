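"""Subject-specific calibration via stratified Monte-Carlo cross-validation.

Thresholds between adjacent-intensity activities are placed midway between
the boxplot whiskers of the two feature distributions:

    T = (upper_whisker(lower activity) + lower_whisker(higher activity)) / 2

with T1 separating Stop from Walk on ``cc_max`` and T2, T3 separating
Walk/Jog and Jog/Sprint on ``l_ap``.  Per-activity cadences (strides/min)
come from the gold-standard stride counts:

    cadence = strides / T,   T = L / (fs * 60)  minutes for an L-frame MI.

Both are estimated 50 times on random stratified train/test partitions of
the labelled short-term session (4 MIs each of Stop/Walk/Jog and 2 of Sprint
in train, the remainder in test); the final calibration is the mean across
iterations, and the held-out test sets provide subject-specific error
estimates for the classifier, the stride counter, and the chained workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import WindowSpec, extract_features
from .signal_model import (
    AccelSignal,
    Activity,
    LabelledDataset,
    MotionInterval,
)

__all__ = [
    "ThresholdSet",
    "CadenceSet",
    "MccvSplit",
    "MccvResult",
    "CalibrationWarning",
    "whiskers",
    "threshold_between",
    "calibrate_thresholds",
    "cadence",
    "calibrate_cadences",
    "concatenate_mis",
    "mccv_split",
    "run_mccv",
    "TRAIN_COUNTS",
    "MIN_MI_COUNTS",
]

#: MIs drawn into the training set per activity at each iteration
TRAIN_COUNTS = {Activity.STOP: 4, Activity.WALK: 4, Activity.JOG: 4, Activity.SPRINT: 2}
#: minimum MIs per activity for the split to leave a non-empty test set
MIN_MI_COUNTS = {Activity.STOP: 8, Activity.WALK: 8, Activity.JOG: 8, Activity.SPRINT: 5}

ACTIVITY_ORDER = (Activity.STOP, Activity.WALK, Activity.JOG, Activity.SPRINT)


class CalibrationWarning(UserWarning):
    """Non-fatal calibration issues (overlapping feature distributions etc.)."""


@dataclass(frozen=True)
class ThresholdSet:
    """Decision boundaries in g.

    ``t1`` separates Stop/Walk on cc_max; ``t2`` and ``t3`` separate
    Walk/Jog and Jog/Sprint on l_ap.  ``t3`` is ``None`` for athletes whose
    calibration session contains no Sprint (triathletes), in which case the
    classifier never emits Sprint.
    """

    t1: float
    t2: float
    t3: float | None = None

    def __post_init__(self):
        if not self.t1 > 0:
            raise ValueError(f"t1 must be positive, got {self.t1}")
        if self.t3 is not None and not self.t2 < self.t3:
            raise ValueError(
                f"thresholds must be ordered t2 < t3, got t2={self.t2}, t3={self.t3}"
            )


@dataclass(frozen=True)
class CadenceSet:
    """Per-activity cadences in strides/min; sprint is absent for triathletes."""

    walk: float
    jog: float
    sprint: float | None = None

    def __post_init__(self):
        vals = [self.walk, self.jog] + ([] if self.sprint is None else [self.sprint])
        if any(not v > 0 for v in vals):
            raise ValueError(f"cadences must be positive, got {vals}")
        ordered = self.walk < self.jog and (self.sprint is None or self.jog < self.sprint)
        if not ordered:
            warnings.warn(
                f"cadences are not ordered walk < jog < sprint: "
                f"{self.walk:.1f}, {self.jog:.1f}, {self.sprint}",
                CalibrationWarning,
                stacklevel=2,
            )

    def get(self, activity: Activity) -> float | None:
        return {
            Activity.WALK: self.walk,
            Activity.JOG: self.jog,
            Activity.SPRINT: self.sprint,
        }.get(activity)


def whiskers(values: np.ndarray) -> tuple[float, float]:
    """Tukey boxplot whiskers of a sample.

    Quartiles use linear interpolation between order statistics; the fences
    sit 1.5 IQR beyond them, and each whisker is the most extreme datum
    within its fence.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError(
            f"whiskers need at least 4 values, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("whiskers: sample contains non-finite values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lower = values[values >= low_fence].min()
    upper = values[values <= high_fence].max()
    return float(lower), float(upper)


def threshold_between(
    low_activity_values: np.ndarray, high_activity_values: np.ndarray
) -> float:
    """Threshold midway between the whiskers of two adjacent intensity classes.

    Warns (and still returns the midpoint) when the distributions overlap,
    i.e. the upper whisker of the lower-intensity activity exceeds the lower
    whisker of the higher-intensity one.
    """
    _, upper_low = whiskers(low_activity_values)
    lower_high, _ = whiskers(high_activity_values)
    if upper_low > lower_high:
        warnings.warn(
            f"feature distributions overlap (upper whisker {upper_low:.3g} > "
            f"lower whisker {lower_high:.3g}); calibration may not separate "
            f"these activities",
            CalibrationWarning,
            stacklevel=2,
        )
    return (upper_low + lower_high) / 2.0


def _per_mi_features(
    dataset: LabelledDataset,
    spec: WindowSpec,
    freqs: np.ndarray | None,
) -> dict[int, pd.DataFrame]:
    """Features of each MI computed on its own frames (windows never straddle MIs)."""
    out = {}
    for i, mi in enumerate(dataset.mis):
        sub = dataset.signal.slice(mi.start_frame, mi.end_frame)
        out[i] = extract_features(sub, spec, freqs)
    return out


def _activity_feature_samples(
    dataset: LabelledDataset,
    spec: WindowSpec,
    freqs: np.ndarray | None = None,
    cached: dict[int, pd.DataFrame] | None = None,
    indices: list[int] | None = None,
) -> dict[Activity, pd.DataFrame]:
    if cached is None:
        cached = _per_mi_features(dataset, spec, freqs)
    if indices is None:
        indices = list(cached)
    groups: dict[Activity, list[pd.DataFrame]] = {}
    for i in indices:
        groups.setdefault(dataset.mis[i].activity, []).append(cached[i])
    return {a: pd.concat(fr, ignore_index=True) for a, fr in groups.items()}


def calibrate_thresholds(
    train: LabelledDataset,
    spec: WindowSpec = WindowSpec(),
    freqs: np.ndarray | None = None,
    _samples: dict[Activity, pd.DataFrame] | None = None,
) -> ThresholdSet:
    """Whisker-based thresholds from a labelled training dataset.

    Requires Stop, Walk and Jog intervals; Sprint is optional, and without it
    ``t3`` is absent.
    """
    samples = _samples if _samples is not None else _activity_feature_samples(
        train, spec, freqs
    )
    for required in (Activity.STOP, Activity.WALK, Activity.JOG):
        if required not in samples:
            raise ValueError(
                f"calibration requires at least one {required.label} motion interval"
            )
    t1 = threshold_between(
        samples[Activity.STOP]["cc_max_g"].to_numpy(),
        samples[Activity.WALK]["cc_max_g"].to_numpy(),
    )
    t2 = threshold_between(
        samples[Activity.WALK]["l_ap_g"].to_numpy(),
        samples[Activity.JOG]["l_ap_g"].to_numpy(),
    )
    t3 = None
    if Activity.SPRINT in samples:
        t3 = threshold_between(
            samples[Activity.JOG]["l_ap_g"].to_numpy(),
            samples[Activity.SPRINT]["l_ap_g"].to_numpy(),
        )
    return ThresholdSet(t1=t1, t2=t2, t3=t3)


def cadence(mi: MotionInterval, fs: float) -> float:
    """Cadence of one gold-standard MI in strides per minute."""
    if mi.activity is Activity.STOP:
        raise ValueError("cadence is undefined for Stop intervals")
    if mi.strides is None or mi.strides < 1:
        raise ValueError(
            f"cadence needs a gold-standard stride count >= 1, got {mi.strides}"
        )
    duration_min = mi.n_frames / (fs * 60.0)
    return mi.strides / duration_min


def calibrate_cadences(
    train: LabelledDataset, aggregation: str = "mean_of_mi"
) -> CadenceSet:
    """Per-activity cadences from a training dataset.

    ``aggregation`` chooses how per-MI cadences combine within the set:
    ``"mean_of_mi"`` (default) averages the per-MI cadences;
    ``"pooled"`` divides total strides by total time.
    """
    if aggregation not in ("mean_of_mi", "pooled"):
        raise ValueError(f"unknown cadence aggregation {aggregation!r}")
    fs = train.signal.fs
    values: dict[Activity, float] = {}
    for activity in (Activity.WALK, Activity.JOG, Activity.SPRINT):
        mis = train.by_activity(activity)
        if not mis:
            continue
        if aggregation == "mean_of_mi":
            values[activity] = float(np.mean([cadence(mi, fs) for mi in mis]))
        else:
            total_strides = sum(mi.strides for mi in mis)
            total_min = sum(mi.n_frames for mi in mis) / (fs * 60.0)
            values[activity] = total_strides / total_min
    for required in (Activity.WALK, Activity.JOG):
        if required not in values:
            raise ValueError(
                f"cadence calibration requires {required.label} motion intervals"
            )
    return CadenceSet(
        walk=values[Activity.WALK],
        jog=values[Activity.JOG],
        sprint=values.get(Activity.SPRINT),
    )


# ---------------------------------------------------------------------------
# Stratified Monte-Carlo cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MccvSplit:
    """One train/test partition; both sides are concatenated signals.

    The test set carries duplicated copies of the first and last MI of each
    activity block, flagged ``ignore``: they make the block transitions as
    abrupt as in the original concatenation without letting that artificial
    boundary contaminate the scores.
    """

    iteration: int
    train: LabelledDataset
    test: LabelledDataset
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]


def concatenate_mis(
    dataset: LabelledDataset,
    indices: list[int],
    duplicate_edges: bool = False,
) -> LabelledDataset:
    """New dataset from the given MIs, concatenated in activity-block order.

    Blocks follow the fixed order Stop, Walk, Jog, Sprint; within a block MIs
    keep their chronological order.  With ``duplicate_edges`` the first and
    last MI of each block are copied to its edges and flagged ``ignore``.
    """
    by_act: dict[Activity, list[int]] = {a: [] for a in ACTIVITY_ORDER}
    for i in sorted(indices, key=lambda i: dataset.mis[i].start_frame):
        by_act[dataset.mis[i].activity].append(i)
    parts: list[AccelSignal] = []
    new_mis: list[MotionInterval] = []
    cursor = 0

    def append(mi_index: int, ignore: bool) -> None:
        nonlocal cursor
        mi = dataset.mis[mi_index]
        parts.append(dataset.signal.slice(mi.start_frame, mi.end_frame))
        new_mis.append(
            MotionInterval(
                activity=mi.activity,
                start_frame=cursor,
                end_frame=cursor + mi.n_frames,
                strides=mi.strides,
                ignore=ignore,
            )
        )
        cursor += mi.n_frames

    for activity in ACTIVITY_ORDER:
        block = by_act[activity]
        if not block:
            continue
        if duplicate_edges:
            append(block[0], ignore=True)
        for i in block:
            append(i, ignore=False)
        if duplicate_edges:
            append(block[-1], ignore=True)
    return LabelledDataset(signal=AccelSignal.concatenate(parts), mis=tuple(new_mis))


def mccv_split(
    dataset: LabelledDataset,
    n_iter: int = 50,
    seed: int | np.random.Generator | None = None,
) -> list[MccvSplit]:
    """Stratified random train/test partitions of the labelled session.

    Each iteration draws, without replacement, 4 Stop + 4 Walk + 4 Jog
    (+ 2 Sprint when the session has Sprint MIs) into the training set; the
    remaining MIs form the test set with ignore-flagged edge duplicates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = dataset.activity_counts()
    active = [a for a in ACTIVITY_ORDER if a is not Activity.SPRINT or counts[a] > 0]
    deficits = [
        f"{a.label}: have {counts[a]}, need >= {MIN_MI_COUNTS[a]}"
        for a in active
        if counts[a] < MIN_MI_COUNTS[a]
    ]
    if deficits:
        raise ValueError(
            "not enough motion intervals for the stratified split "
            f"({'; '.join(deficits)})"
        )
    index_by_act = {
        a: [i for i, mi in enumerate(dataset.mis) if mi.activity is a] for a in active
    }
    splits = []
    for it in range(n_iter):
        train_idx: list[int] = []
        test_idx: list[int] = []
        for a in active:
            picked = rng.permutation(len(index_by_act[a]))[: TRAIN_COUNTS[a]]
            chosen = {index_by_act[a][j] for j in picked}
            train_idx.extend(sorted(chosen))
            test_idx.extend(sorted(set(index_by_act[a]) - chosen))
        splits.append(
            MccvSplit(
                iteration=it,
                train=concatenate_mis(dataset, train_idx),
                test=concatenate_mis(dataset, test_idx, duplicate_edges=True),
                train_indices=tuple(sorted(train_idx)),
                test_indices=tuple(sorted(test_idx)),
            )
        )
    return splits


@dataclass
class MccvResult:
    """Everything the 50-iteration MCCV produced.

    Per-iteration thresholds and cadences live in tidy DataFrames; the final
    calibration is their arithmetic mean.  ``gold``/``pred`` hold the frame
    label arrays of each iteration's test signal and ``mask`` marks frames
    that count towards scores (edge-duplicate frames are False).
    """

    thresholds_by_iter: pd.DataFrame
    cadences_by_iter: pd.DataFrame
    counts_by_iter: pd.DataFrame
    gold: list[np.ndarray]
    pred: list[np.ndarray]
    mask: list[np.ndarray]
    seed: int | None
    n_iter: int
    spec: WindowSpec
    mi_counts: dict[Activity, int]
    cadence_aggregation: str = "mean_of_mi"

    @property
    def thresholds(self) -> ThresholdSet:
        t = self.thresholds_by_iter.mean()
        t3 = None if np.isnan(t.get("t3", np.nan)) else float(t["t3"])
        return ThresholdSet(t1=float(t["t1"]), t2=float(t["t2"]), t3=t3)

    @property
    def cadences(self) -> CadenceSet:
        c = self.cadences_by_iter.mean()
        sprint = None if np.isnan(c.get("sprint", np.nan)) else float(c["sprint"])
        return CadenceSet(walk=float(c["walk"]), jog=float(c["jog"]), sprint=sprint)

    def pooled_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Scored gold and predicted frame labels concatenated over iterations."""
        gold = np.concatenate([g[m] for g, m in zip(self.gold, self.mask)])
        pred = np.concatenate([p[m] for p, m in zip(self.pred, self.mask)])
        return gold, pred


def run_mccv(
    dataset: LabelledDataset,
    spec: WindowSpec = WindowSpec(),
    n_iter: int = 50,
    seed: int | None = None,
    freqs: np.ndarray | None = None,
    cadence_aggregation: str = "mean_of_mi",
) -> MccvResult:
    """Full Monte-Carlo cross-validated calibration of one athlete.

    Per iteration: thresholds and cadences are fitted on the training
    concatenation, the classifier runs over the test concatenation, and the
    per-frame gold/predicted labels plus gold-span and detected-span stride
    counts are recorded.  Identical seeds give bit-identical results.
    """
    from .detection import evaluate_signal  # deferred: detection uses ThresholdSet

    fs = dataset.signal.fs
    cached = _per_mi_features(dataset, spec, freqs)
    splits = mccv_split(dataset, n_iter=n_iter, seed=seed)

    thr_rows, cad_rows, cnt_rows = [], [], []
    gold_arrays, pred_arrays, mask_arrays = [], [], []
    for split in splits:
        samples = _activity_feature_samples(
            dataset, spec, freqs, cached=cached, indices=list(split.train_indices)
        )
        th = calibrate_thresholds(split.train, spec, freqs, _samples=samples)
        cad = calibrate_cadences(split.train, aggregation=cadence_aggregation)
        thr_rows.append(
            {"iteration": split.iteration, "t1": th.t1, "t2": th.t2,
             "t3": np.nan if th.t3 is None else th.t3}
        )
        cad_rows.append(
            {"iteration": split.iteration, "walk": cad.walk, "jog": cad.jog,
             "sprint": np.nan if cad.sprint is None else cad.sprint}
        )

        test = split.test
        pred = evaluate_signal(test.signal, th, spec, freqs)
        gold = np.zeros(test.signal.n_frames, dtype=np.int8)
        mask = np.zeros(test.signal.n_frames, dtype=bool)
        for mi in test.mis:
            gold[mi.start_frame:mi.end_frame] = int(mi.activity)
            if not mi.ignore:
                mask[mi.start_frame:mi.end_frame] = True
        gold_arrays.append(gold)
        pred_arrays.append(pred)
        mask_arrays.append(mask)

        for activity in (Activity.WALK, Activity.JOG, Activity.SPRINT):
            rate = cad.get(activity)
            if rate is None:
                continue
            scored = [
                mi for mi in test.mis if mi.activity is activity and not mi.ignore
            ]
            if not scored:
                continue
            labelled = sum(mi.strides for mi in scored)
            gold_min = sum(mi.n_frames for mi in scored) / (fs * 60.0)
            detected_min = np.count_nonzero(pred[mask] == int(activity)) / (fs * 60.0)
            cnt_rows.append(
                {
                    "iteration": split.iteration,
                    "activity": activity.label,
                    "labelled": labelled,
                    "detected_gold_spans": rate * gold_min,
                    "detected_workflow": rate * detected_min,
                }
            )

    return MccvResult(
        thresholds_by_iter=pd.DataFrame(thr_rows).set_index("iteration"),
        cadences_by_iter=pd.DataFrame(cad_rows).set_index("iteration"),
        counts_by_iter=pd.DataFrame(cnt_rows),
        gold=gold_arrays,
        pred=pred_arrays,
        mask=mask_arrays,
        seed=seed if isinstance(seed, int) else None,
        n_iter=n_iter,
        spec=spec,
        mi_counts=dataset.activity_counts(),
        cadence_aggregation=cadence_aggregation,
    )
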