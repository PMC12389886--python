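"""Pseudo-online decision streams, smoothing and maxAP estimation.

A trained classifier is replayed causally over a trial's sliding
windows, producing a signed score and label every 125 ms.  The raw
label stream is smoothed with a causal majority vote to remove sporadic
isolated flips, the first painless→pain transition is located, and the
joint angle at that moment is compared with the true maximum angle
position (maxAP).  Positive bias (true maxAP minus detected angle)
means early — safe-side — detection; detections after the pain mark are
flagged *delayed* and carry no bias, since the robot has already
stopped at the maxAP and the angle difference is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classification import TrainedModel
from .features import PAIN, PAINLESS, FeatureConfig, slide_windows, window_features
from .io import TrialSegment


@dataclass
class DecisionStream:
    """Per-window scores and labels over one trial, in time order."""

    trial_id: int
    times_s: np.ndarray  # window end times, relative to trial start
    scores: np.ndarray  # signed; positive => pain
    raw_labels: np.ndarray  # str array
    smoothed_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("window times must be strictly increasing")

    @property
    def labels(self) -> np.ndarray:
        return self.smoothed_labels if self.smoothed_labels is not None else self.raw_labels

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_s": self.times_s, "score": self.scores, "raw_label": self.raw_labels}
        )
        if self.smoothed_labels is not None:
            df["smoothed_label"] = self.smoothed_labels
        df.insert(0, "trial_id", self.trial_id)
        return df


@dataclass
class MaxApEstimate:
    """Angle at the first detected pain state versus the true maxAP."""

    trial_id: int
    t_detect: float | None  # None: no detection in the trial
    detected_angle: float | None
    true_maxap: float
    bias_deg: float | None  # true - detected; only for early detections
    timing: str  # early | delayed | none


def predict_stream(
    model: TrainedModel,
    trial: TrialSegment,
    cfg: FeatureConfig = FeatureConfig(),
) -> DecisionStream:
    """Score every sliding window of a trial causally.

    Each window's features depend only on samples inside it, so the
    stream a real-time system would produce is recovered exactly.
    """
    windows = slide_windows(trial, cfg)
    X = np.vstack([window_features(w, trial.fs, cfg) for w in windows])
    scores = model.decision_scores(X)
    return DecisionStream(
        trial_id=trial.trial_id,
        times_s=np.array([w.end_s for w in windows]),
        scores=scores,
        raw_labels=np.where(scores > 0, PAIN, PAINLESS),
    )


def stream_from_features(
    model: TrainedModel, features: pd.DataFrame, trial_id: int
) -> DecisionStream:
    """Build a decision stream from precomputed feature-table rows.

    Produces the same stream as :func:`predict_stream` (features are
    deterministic functions of the windows) without re-extracting them.
    """
    sub = features[features["trial_id"] == trial_id].sort_values("end_s")
    if sub.empty:
        raise ValueError(f"no feature rows for trial {trial_id}")
    cols = [c for c in features.columns
            if c not in ("trial_id", "onset_s", "end_s", "label", "subject_id")]
    scores = model.decision_scores(sub[cols].to_numpy(dtype=float))
    return DecisionStream(
        trial_id=trial_id,
        times_s=sub["end_s"].to_numpy(dtype=float),
        scores=scores,
        raw_labels=np.where(scores > 0, PAIN, PAINLESS),
    )


def majority_filter(labels: np.ndarray, width: int, mode: str = "causal") -> np.ndarray:
    """Majority vote over a window of raw labels.

    ``causal`` votes over the last ``width`` labels (the available
    prefix early on); ``centered`` votes over a symmetric window
    truncated at the edges.  Ties go to painless — the conservative
    reading for a detector that must not invent pain states.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"width must be a positive odd integer, got {width}")
    if mode not in ("causal", "centered"):
        raise ValueError(f"unknown mode {mode!r}")
    is_pain = np.asarray(labels) == PAIN
    n = is_pain.size
    out = np.empty(n, dtype=bool)
    half = width // 2
    for i in range(n):
        if mode == "causal":
            lo, hi = max(0, i - width + 1), i + 1
        else:
            lo, hi = max(0, i - half), min(n, i + half + 1)
        votes = is_pain[lo:hi]
        out[i] = votes.sum() * 2 > votes.size
    return np.where(out, PAIN, PAINLESS)


def smooth_decisions(stream: DecisionStream, width: int = 5, mode: str = "causal") -> DecisionStream:
    """Return a copy of the stream with majority-vote smoothed labels.

    The default causal width of 5 spans 0.75 s of decisions at the
    125 ms step.
    """
    return replace(
        stream, smoothed_labels=majority_filter(stream.raw_labels, width, mode)
    )


def detect_transition(stream: DecisionStream) -> float | None:
    """End time of the first window labelled pain, or None."""
    labels = stream.labels
    idx = np.flatnonzero(labels == PAIN)
    return float(stream.times_s[idx[0]]) if idx.size else None


def estimate_maxap(stream: DecisionStream, trial: TrialSegment) -> MaxApEstimate:
    """Compare the angle at the first detected pain state with the true maxAP."""
    if trial.angle is None or trial.true_maxap is None:
        raise ValueError(f"trial {trial.trial_id} has no angle trace / true maxAP")
    t = detect_transition(stream)
    if t is None:
        return MaxApEstimate(trial.trial_id, None, None, trial.true_maxap, None, "none")
    t_abs = trial.t_start + t
    angle = trial.angle_at(t_abs)
    if t_abs >= trial.t_pain:
        return MaxApEstimate(trial.trial_id, t, angle, trial.true_maxap, None, "delayed")
    return MaxApEstimate(
        trial.trial_id, t, angle, trial.true_maxap, trial.true_maxap - angle, "early"
    )


def bias_summary(estimates_by_subject: dict[int | str, list[MaxApEstimate]]) -> dict:
    """Cohort bias statistics over per-subject trial estimates.

    Per-subject mean bias is taken over early-detection trials only (a
    delayed trial's angle equals the maxAP by construction, so its
    difference is not an estimation error); the across-subject mean
    also including delayed trials as zero-bias is reported alongside.
    The early fraction counts early / (early + delayed) over all
    detected trials.
    """
    per_subject, per_subject_incl = {}, {}
    early = delayed = none = 0
    for sid, ests in estimates_by_subject.items():
        biases = [e.bias_deg for e in ests if e.timing == "early"]
        incl = [e.bias_deg if e.timing == "early" else 0.0 for e in ests if e.timing != "none"]
        early += sum(e.timing == "early" for e in ests)
        delayed += sum(e.timing == "delayed" for e in ests)
        none += sum(e.timing == "none" for e in ests)
        if biases:
            per_subject[sid] = float(np.mean(biases))
        if incl:
            per_subject_incl[sid] = float(np.mean(incl))
    vals = np.array(list(per_subject.values()))
    vals_incl = np.array(list(per_subject_incl.values()))
    detected = early + delayed
    return {
        "per_subject_mean_bias_deg": per_subject,
        "cohort_mean_bias_deg": float(vals.mean()) if vals.size else float("nan"),
        "cohort_std_bias_deg": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        "cohort_mean_bias_incl_delayed_deg": float(vals_incl.mean()) if vals_incl.size else float("nan"),
        "n_early": early,
        "n_delayed": delayed,
        "n_no_detection": none,
        "early_fraction": early / detected if detected else float("nan"),
    }
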