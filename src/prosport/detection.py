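"""Binary decision-tree activity classifier and signal segmentation.

The classifier descends a fixed tree on the two window features: a window is
Stop when ``cc_max <= T1``; otherwise Walk when ``l_ap <= T2``; otherwise
Jog when ``l_ap <= T3`` (or when T3 is absent); otherwise Sprint.  Ties at a
threshold resolve to the lower-intensity class.

Each 48-frame window labels its first 24-frame half, so the evaluation array
has a resolution of 24 frames (~1.9 s at 12.5 Hz); the final window also
labels its second half and any trailing frames inherit the last label, which
tiles the signal exactly.  Maximal runs of one label become motion intervals.
"""

from __future__ import annotations

import numpy as np

from .calibration import ThresholdSet
from .features import WindowSpec, extract_features, windows
from .signal_model import AccelSignal, Activity, MotionInterval

__all__ = [
    "classify_window",
    "classify_features",
    "evaluate_signal",
    "segment",
]


def classify_window(cc_max_g: float, l_ap_g: float, th: ThresholdSet) -> Activity:
    """Activity of one window from its features (total on valid input)."""
    return Activity(int(classify_features(
        np.asarray([cc_max_g]), np.asarray([l_ap_g]), th
    )[0]))


def classify_features(
    cc_max_g: np.ndarray, l_ap_g: np.ndarray, th: ThresholdSet
) -> np.ndarray:
    """Vectorized decision tree; returns int8 tags (1=Stop .. 4=Sprint)."""
    cc_max_g = np.asarray(cc_max_g, dtype=float)
    l_ap_g = np.asarray(l_ap_g, dtype=float)
    if not (np.all(np.isfinite(cc_max_g)) and np.all(np.isfinite(l_ap_g))):
        raise ValueError("features must be finite")
    tags = np.full(cc_max_g.shape, int(Activity.SPRINT), dtype=np.int8)
    if th.t3 is None:
        tags[:] = int(Activity.JOG)
    else:
        tags[l_ap_g <= th.t3] = int(Activity.JOG)
    tags[l_ap_g <= th.t2] = int(Activity.WALK)
    tags[cc_max_g <= th.t1] = int(Activity.STOP)
    return tags


def evaluate_signal(
    signal: AccelSignal,
    th: ThresholdSet,
    spec: WindowSpec = WindowSpec(),
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame activity tags for a reoriented signal.

    Window k writes its tag to frames [k*step, (k+1)*step); the last window
    also covers its second half, and trailing frames that could not fill a
    window inherit the final tag.  The result has exactly ``n_frames`` tags.
    """
    feats = extract_features(signal, spec, freqs)
    tags = classify_features(
        feats["cc_max_g"].to_numpy(), feats["l_ap_g"].to_numpy(), th
    )
    out = np.empty(signal.n_frames, dtype=np.int8)
    spans = windows(signal.n_frames, spec)
    for (start, _), tag in zip(spans, tags):
        out[start:start + spec.step] = tag
    last_covered = spans[-1][0] + spec.step
    out[last_covered:] = tags[-1]
    return out


def segment(
    evaluation: np.ndarray, t0=None, fs: float | None = None
) -> list[MotionInterval]:
    """Maximal runs of identical tags as motion intervals (strides unset).

    The intervals tile the evaluation array exactly.  ``t0`` and ``fs`` are
    accepted for interface symmetry with absolute-time reporting; the
    returned intervals are frame-indexed into the same signal.
    """
    evaluation = np.asarray(evaluation)
    if evaluation.ndim != 1 or evaluation.size == 0:
        raise ValueError("evaluation array must be a non-empty 1-D array")
    boundaries = np.flatnonzero(np.diff(evaluation)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [evaluation.size]])
    return [
        MotionInterval(
            activity=Activity(int(evaluation[s])),
            start_frame=int(s),
            end_frame=int(e),
            strides=None,
        )
        for s, e in zip(starts, ends)
    ]
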