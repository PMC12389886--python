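"""Recording data model, delimited-text I/O, filtering and trial segmentation.

Surface EMG is recorded from four muscles around the knee — two extensors
(rectus femoris, vastus medialis) and two flexors (biceps femoris caput
longum, semitendinosus) — at 2000 Hz, with event markers splitting each
recording into mobility-training trials: a *start* mark when flexion
begins, a *pain* mark when the patient's pain reaches the training
threshold (the joint then holds at the maximum angle position, maxAP), and
an *end* mark when extension starts.  Robot-assisted trials additionally
carry a per-sample joint-angle trace in degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

#: canonical channel order: extensors first, then flexors
CHANNELS = ("MRF", "MVM", "MBF-CL", "MS")
EXTENSORS = ("MRF", "MVM")
FLEXORS = ("MBF-CL", "MS")

MARKER_KINDS = ("start", "pain", "end")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


@dataclass
class EmgRecording:
    """Multi-channel surface EMG with event markers and optional angle trace.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        EMG in mV, channel order ``channel_labels``.
    markers : list of (float, str)
        ``(time_s, kind)`` with kind in ``{"start", "pain", "end"}``,
        strictly increasing in time, grouped in (start, pain, end) triples.
    angle : ndarray or None, shape (n_samples,)
        Joint angle in degrees, aligned sample-for-sample with ``samples``.
    """

    fs: float
    samples: np.ndarray
    markers: list[tuple[float, str]]
    angle: np.ndarray | None = None
    channel_labels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{self.samples.shape[0]} rows for {len(self.channel_labels)} channels"
            )
        times = [t for t, _ in self.markers]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(f"marker times not strictly increasing: {times}")
        for _, kind in self.markers:
            if kind not in MARKER_KINDS:
                raise ValidationError(f"unknown marker kind {kind!r}")
        for i, (_, kind) in enumerate(self.markers):
            if kind != MARKER_KINDS[i % 3]:
                raise ValidationError(
                    "markers must repeat (start, pain, end); "
                    f"position {i} has {kind!r}"
                )
        if self.angle is not None:
            self.angle = np.asarray(self.angle, dtype=float)
            if self.angle.shape != (self.samples.shape[1],):
                raise ValidationError(
                    f"angle length {self.angle.shape} does not match "
                    f"{self.samples.shape[1]} samples"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialSegment:
    """One mobility-training trial cut from a recording.

    The *flexion* phase runs from ``t_start`` to ``t_pain`` (painless
    label source) and the *hold* phase from ``t_pain`` to ``t_end`` (pain
    label source).  ``true_maxap`` is the joint angle at the pain mark
    when an angle trace is available.
    """

    trial_id: int
    fs: float
    signal: np.ndarray  # channels x time, covering [t_start, t_end]
    t_start: float
    t_pain: float
    t_end: float
    angle: np.ndarray | None = None
    channel_labels: tuple[str, ...] = CHANNELS
    true_maxap: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_pain < self.t_end):
            raise ValidationError(
                f"need t_start < t_pain < t_end, got "
                f"({self.t_start}, {self.t_pain}, {self.t_end})"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def phase_of(self, t: float) -> str:
        """Trial phase at absolute time ``t`` (seconds): flexion or hold."""
        if not (self.t_start <= t <= self.t_end):
            raise ValueError(f"t={t} outside trial [{self.t_start}, {self.t_end}]")
        return "flexion" if t < self.t_pain else "hold"

    def angle_at(self, t: float) -> float:
        """Joint angle at absolute time ``t``, linearly interpolated."""
        if self.angle is None:
            raise ValidationError(f"trial {self.trial_id} has no angle trace")
        rel = np.clip(t - self.t_start, 0.0, (self.n_samples - 1) / self.fs)
        idx = rel * self.fs
        return float(np.interp(idx, np.arange(self.n_samples), self.angle))


def read_recording(
    signal_path: str | Path,
    marker_path: str | Path,
    angle_path: str | Path | None = None,
    fs: float = 2000.0,
) -> EmgRecording:
    """Read a recording from delimited text files.

    The signal file has a header row naming channels and one row per
    sample; channel order is normalised to ``CHANNELS``.  The marker file
    has columns ``time_s,kind``; the optional angle file has one angle
    per sample row.
    """
    sig = pd.read_csv(signal_path, sep=None, engine="python")
    missing = [c for c in CHANNELS if c not in sig.columns]
    if missing:
        raise FormatError(f"signal file missing channel column(s): {missing}")
    extra = [c for c in sig.columns if c not in CHANNELS]
    if extra:
        raise FormatError(f"signal file has unexpected column(s): {extra}")
    samples = sig[list(CHANNELS)].to_numpy(dtype=float).T

    mk = pd.read_csv(marker_path, sep=None, engine="python")
    if not {"time_s", "kind"} <= set(mk.columns):
        raise FormatError("marker file must have columns time_s,kind")
    markers = [(float(t), str(k)) for t, k in zip(mk["time_s"], mk["kind"])]

    angle = None
    if angle_path is not None:
        angle = pd.read_csv(angle_path).iloc[:, 0].to_numpy(dtype=float)

    return EmgRecording(fs=fs, samples=samples, markers=markers, angle=angle)


def write_recording(rec: EmgRecording, out_dir: str | Path, stem: str = "recording") -> dict:
    """Write a recording back to the delimited-text layout ``read_recording`` reads.

    Returns a manifest dict with the file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_path = out / f"{stem}_signal.csv"
    pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels)).to_csv(
        sig_path, index=False, float_format="%.6f"
    )
    mk_path = out / f"{stem}_markers.csv"
    pd.DataFrame(rec.markers, columns=["time_s", "kind"]).to_csv(mk_path, index=False)
    manifest = {"signal": str(sig_path), "markers": str(mk_path), "fs": rec.fs}
    if rec.angle is not None:
        ang_path = out / f"{stem}_angle.csv"
        pd.DataFrame({"angle_deg": rec.angle}).to_csv(
            ang_path, index=False, float_format="%.4f"
        )
        manifest["angle"] = str(ang_path)
    return manifest


def _design_filters(fs: float, low_hz: float, high_hz: float, notch_hz: float):
    if fs <= 2 * high_hz:
        raise ValueError(
            f"fs={fs} Hz too low for a {high_hz} Hz band edge (need fs > {2 * high_hz})"
        )
    # 4th-order Butterworth band-pass + 2nd-order IIR notch (Q = 30),
    # both applied forward-backward for zero phase.
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    b_notch, a_notch = sps.iirnotch(notch_hz, Q=30.0, fs=fs)
    return sos, (b_notch, a_notch)


def bandpass_notch(
    rec: EmgRecording,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    notch_hz: float = 50.0,
) -> EmgRecording:
    """Zero-phase Butterworth band-pass (20-450 Hz) plus 50 Hz notch.

    Forward-backward (``filtfilt``) application keeps the output aligned
    with the event markers: there is no group delay to compensate.
    """
    sos, (b_n, a_n) = _design_filters(rec.fs, low_hz, high_hz, notch_hz)
    min_len = 3 * max(len(b_n), len(a_n), 9)  # filtfilt stabilising pad
    if rec.n_samples <= min_len:
        raise ValueError(
            f"signal of {rec.n_samples} samples too short to filter (need > {min_len})"
        )
    y = sps.sosfiltfilt(sos, rec.samples, axis=1)
    y = sps.filtfilt(b_n, a_n, y, axis=1)
    return replace(rec, samples=y)


def filter_response(
    freqs_hz: Sequence[float],
    fs: float = 2000.0,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    notch_hz: float = 50.0,
) -> np.ndarray:
    """Magnitude response of the zero-phase cascade at the given frequencies.

    Because the filters run forward-backward the effective magnitude is
    the squared single-pass magnitude of band-pass times notch.
    """
    sos, (b_n, a_n) = _design_filters(fs, low_hz, high_hz, notch_hz)
    w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / fs
    _, h_bp = sps.sosfreqz(sos, worN=w)
    _, h_n = sps.freqz(b_n, a_n, worN=w)
    return np.abs(h_bp * h_n) ** 2


def segment_trials(rec: EmgRecording) -> list[TrialSegment]:
    """Cut the recording into one :class:`TrialSegment` per marker triple.

    Samples outside any [start, end] interval are discarded.  Marker
    times snap to the nearest sample (ties round down).  When an angle
    trace is present, ``true_maxap`` is the angle at the pain mark.
    """
    if len(rec.markers) % 3 != 0:
        dangling = rec.markers[len(rec.markers) - len(rec.markers) % 3:]
        raise ValidationError(f"incomplete final marker triple: {dangling}")

    def snap(t: float) -> int:
        # nearest sample, ties (x.5) round down
        return int(np.ceil(t * rec.fs - 0.5))

    trials = []
    for k in range(len(rec.markers) // 3):
        (t0, _), (tp, _), (t1, _) = rec.markers[3 * k: 3 * k + 3]
        i0, i1 = snap(t0), snap(t1)
        if i0 < 0 or i1 >= rec.n_samples:
            raise ValidationError(
                f"trial {k} markers [{t0}, {t1}] extend outside the recording"
            )
        ang = rec.angle[i0: i1 + 1] if rec.angle is not None else None
        true_maxap = float(rec.angle[snap(tp)]) if rec.angle is not None else None
        trials.append(
            TrialSegment(
                trial_id=k,
                fs=rec.fs,
                signal=rec.samples[:, i0: i1 + 1],
                t_start=t0,
                t_pain=tp,
                t_end=t1,
                angle=ang,
                channel_labels=rec.channel_labels,
                true_maxap=true_maxap,
            )
        )
    return trials


def write_trials(trials: list[TrialSegment], out_dir: str | Path) -> Path:
    """Write one CSV per trial plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in trials:
        path = out / f"trial_{tr.trial_id:02d}.csv"
        df = pd.DataFrame(tr.signal.T, columns=list(tr.channel_labels))
        if tr.angle is not None:
            df["angle_deg"] = tr.angle
        df.to_csv(path, index=False, float_format="%.6f")
        entries.append(
            {
                "trial_id": tr.trial_id,
                "file": path.name,
                "fs": tr.fs,
                "t_start": tr.t_start,
                "t_pain": tr.t_pain,
                "t_end": tr.t_end,
                "true_maxap": tr.true_maxap,
            }
        )
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"trials": entries}, indent=2))
    return manifest


def read_trials(manifest_path: str | Path) -> list[TrialSegment]:
    """Read trials written by :func:`write_trials`."""
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    trials = []
    for e in meta["trials"]:
        df = pd.read_csv(manifest_path.parent / e["file"])
        angle = df.pop("angle_deg").to_numpy() if "angle_deg" in df.columns else None
        trials.append(
            TrialSegment(
                trial_id=e["trial_id"],
                fs=e["fs"],
                signal=df.to_numpy().T,
                t_start=e["t_start"],
                t_pain=e["t_pain"],
                t_end=e["t_end"],
                angle=angle,
                channel_labels=tuple(df.columns),
                true_maxap=e["true_maxap"],
            )
        )
    return trials
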