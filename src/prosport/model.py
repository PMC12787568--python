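"""Statsmodels-style front end: a model fitted to one athlete's session.

``ActivityModel`` wraps a labelled short-term session; ``fit()`` runs the
stratified Monte-Carlo cross-validation and returns ``ActivityResults``,
which carries the calibrated thresholds and cadences with their
across-iteration spread, classification and stride-counting diagnostics, a
text ``summary()``, and the application methods used on long-term
recordings (detection, segmentation, stride counting, daily reports).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import counting, metrics
from .calibration import (
    CadenceSet,
    MccvResult,
    ThresholdSet,
    run_mccv,
)
from .detection import evaluate_signal, segment
from .features import WindowSpec, default_freq_grid
from .signal_model import (
    AccelSignal,
    LabelledDataset,
    MountingConfig,
    read_labels_csv,
    read_signal_csv,
    reorient,
)

__all__ = ["ActivityModel", "ActivityResults"]


class ActivityModel:
    """Subject-specific activity-detection and stride-counting model.

    Parameters
    ----------
    dataset : LabelledDataset
        Reoriented short-term session with gold-standard motion intervals
        (at least 8 each of Stop/Walk/Jog and 5 of Sprint, or no Sprint at
        all for triathlon athletes).
    window : WindowSpec, optional
        Sliding-window geometry (48 frames advancing by 24 by default).
    freq_grid : array-like, optional
        Wavelet analysis frequencies in Hz; defaults to a linear grid from
        0.1 Hz to Nyquist in 0.05 Hz steps.
    cadence_aggregation : str, optional
        How per-MI cadences combine within a training set: "mean_of_mi"
        (default) or "pooled" (total strides over total time).
    """

    def __init__(
        self,
        dataset: LabelledDataset,
        window: WindowSpec | None = None,
        freq_grid=None,
        cadence_aggregation: str = "mean_of_mi",
    ):
        self.dataset = dataset
        self.window = window or WindowSpec()
        self.freq_grid = (
            default_freq_grid(dataset.signal.fs)
            if freq_grid is None
            else np.asarray(freq_grid, dtype=float)
        )
        self.cadence_aggregation = cadence_aggregation

    @classmethod
    def from_csv(
        cls,
        signal_path,
        labels_path,
        mounting: MountingConfig | None = None,
        fs: float = 12.5,
        **kwargs,
    ) -> "ActivityModel":
        """Build the model from the signal/label CSV dialects.

        ``mounting`` remaps raw device axes into the anatomical frame; omit
        it when the file is already in AP/CC/ML order.
        """
        signal = read_signal_csv(signal_path, fs=fs)
        if mounting is not None:
            signal = reorient(signal, mounting)
        dataset = read_labels_csv(labels_path, signal)
        return cls(dataset, **kwargs)

    def fit(self, n_iter: int = 50, seed: int | None = None) -> "ActivityResults":
        """Run the stratified MCCV calibration (bit-reproducible per seed)."""
        mccv = run_mccv(
            self.dataset,
            spec=self.window,
            n_iter=n_iter,
            seed=seed,
            freqs=self.freq_grid,
            cadence_aggregation=self.cadence_aggregation,
        )
        return ActivityResults(model=self, mccv=mccv)


@dataclass
class ActivityResults:
    """Fitted calibration plus held-out diagnostics for one athlete."""

    model: ActivityModel
    mccv: MccvResult

    # -- calibrated parameters ---------------------------------------------

    @property
    def thresholds(self) -> ThresholdSet:
        """Mean decision thresholds (g) across MCCV iterations."""
        return self.mccv.thresholds

    @property
    def cadences(self) -> CadenceSet:
        """Mean per-activity cadences (strides/min) across MCCV iterations."""
        return self.mccv.cadences

    @property
    def thresholds_std(self) -> pd.Series:
        return self.mccv.thresholds_by_iter.std()

    @property
    def cadences_std(self) -> pd.Series:
        return self.mccv.cadences_by_iter.std()

    # -- held-out diagnostics ----------------------------------------------

    def classification_report(self) -> metrics.ClassificationReport:
        """One-vs-all metrics on all pooled held-out frames."""
        gold, pred = self.mccv.pooled_arrays()
        return metrics.report(gold, pred)

    def stride_counting_validation(self) -> pd.DataFrame:
        """Relative stride-count error (%) per activity on gold spans."""
        return counting.validate_stride_counting(self.mccv)

    def workflow_validation(self) -> pd.DataFrame:
        """Relative stride-count error (%) per activity on detected spans."""
        return counting.validate_workflow(self.mccv)

    def summary(self) -> str:
        """Human-readable calibration summary."""
        th, cad = self.thresholds, self.cadences
        th_sd, cad_sd = self.thresholds_std, self.cadences_std
        rep = self.classification_report()
        sc = self.stride_counting_validation()
        wf = self.workflow_validation()
        lines = [
            "Subject-specific activity calibration "
            f"({self.mccv.n_iter} MCCV iterations, seed={self.mccv.seed})",
            "=" * 66,
            "Thresholds (g, mean +/- sd over iterations)",
            f"  T1 Stop|Walk   (cc_max): {th.t1:7.3f} +/- {th_sd['t1']:.3f}",
            f"  T2 Walk|Jog    (l_ap):   {th.t2:7.3f} +/- {th_sd['t2']:.3f}",
        ]
        if th.t3 is not None:
            lines.append(
                f"  T3 Jog|Sprint  (l_ap):   {th.t3:7.3f} +/- {th_sd['t3']:.3f}"
            )
        else:
            lines.append("  T3 Jog|Sprint  (l_ap):   absent (no Sprint data)")
        lines += [
            "Cadences (strides/min, mean +/- sd over iterations)",
            f"  Walk:   {cad.walk:6.1f} +/- {cad_sd['walk']:.1f}",
            f"  Jog:    {cad.jog:6.1f} +/- {cad_sd['jog']:.1f}",
        ]
        if cad.sprint is not None:
            lines.append(f"  Sprint: {cad.sprint:6.1f} +/- {cad_sd['sprint']:.1f}")
        lines += [
            "Held-out classification (pooled over iterations)",
            f"  overall accuracy: {100 * rep.accuracy:.2f}%",
            "Held-out stride counting, relative error (%)",
        ]
        for activity, row in sc.iterrows():
            wf_err = wf.loc[activity, "error_pct"]
            lines.append(
                f"  {activity:<7} gold spans: {row['error_pct']:+6.2f}   "
                f"full workflow: {wf_err:+6.2f}"
            )
        return "\n".join(lines)

    # -- application to long-term recordings -------------------------------

    def evaluate(self, signal: AccelSignal) -> np.ndarray:
        """Per-frame activity tags of an unlabelled (reoriented) signal."""
        return evaluate_signal(
            signal, self.thresholds, self.model.window, self.model.freq_grid
        )

    def detect(self, signal: AccelSignal):
        """Segment an unlabelled signal into detected motion intervals."""
        return segment(self.evaluate(signal), signal.t0, signal.fs)

    def count(self, signal: AccelSignal) -> counting.StrideSummary:
        """Per-activity durations and stride estimates of a signal."""
        return counting.count_strides(self.detect(signal), self.cadences, signal.fs)

    def daily_summary(
        self, signal: AccelSignal,
        day_use_threshold_s: float = counting.DEFAULT_DAY_USE_THRESHOLD_S,
    ) -> counting.StrideSummary:
        """Calendar-day usage report of a long-term recording."""
        return counting.daily_summary(
            self.detect(signal), self.cadences, signal.t0, signal.fs,
            day_use_threshold_s=day_use_threshold_s,
        )

    # -- persistence and plotting ------------------------------------------

    def calibration_dict(self) -> dict:
        th, cad = self.thresholds, self.cadences
        return {
            "seed": self.mccv.seed,
            "n_iter": self.mccv.n_iter,
            "cadence_aggregation": self.mccv.cadence_aggregation,
            "mi_counts": {a.label: c for a, c in self.mccv.mi_counts.items()},
            "thresholds_g": {"t1": th.t1, "t2": th.t2, "t3": th.t3},
            "cadences_spm": {
                "walk": cad.walk, "jog": cad.jog, "sprint": cad.sprint,
            },
            "thresholds_by_iter": self.mccv.thresholds_by_iter.reset_index()
            .to_dict(orient="list"),
            "cadences_by_iter": self.mccv.cadences_by_iter.reset_index()
            .to_dict(orient="list"),
        }

    def save_calibration(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.calibration_dict(), fh, indent=2)

    def plot_threshold_variability(self, ax=None):
        """Per-iteration threshold values (one line per threshold)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col, label in (("t1", "T1 Stop|Walk"), ("t2", "T2 Walk|Jog"),
                           ("t3", "T3 Jog|Sprint")):
            series = self.mccv.thresholds_by_iter[col]
            if series.notna().any():
                ax.plot(series.index, series, marker=".", label=label)
        ax.set_xlabel("MCCV iteration")
        ax.set_ylabel("threshold (g)")
        ax.legend()
        return ax

    def plot_cadence_variability(self, ax=None):
        """Per-iteration cadence values (one line per activity)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col in ("walk", "jog", "sprint"):
            series = self.mccv.cadences_by_iter[col]
            if series.notna().any():
                ax.plot(series.index, series, marker=".", label=col.capitalize())
        ax.set_xlabel("MCCV iteration")
        ax.set_ylabel("cadence (strides/min)")
        ax.legend()
        return ax


def load_calibration(path) -> tuple[ThresholdSet, CadenceSet]:
    """Read a calibration JSON back into threshold and cadence sets."""
    with open(path) as fh:
        data = json.load(fh)
    th = data["thresholds_g"]
    cad = data["cadences_spm"]
    return (
        ThresholdSet(t1=th["t1"], t2=th["t2"], t3=th.get("t3")),
        CadenceSet(walk=cad["walk"], jog=cad["jog"], sprint=cad.get("sprint")),
    )
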