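"""Seeded generator of synthetic mobility-training trials.

Each trial emulates robot-assisted (or therapist-assisted) slow knee
flexion with pain-coupled surface EMG: the joint angle ramps linearly
from the start angle to the maximum angle position (maxAP) and then
holds; a latent pain level rises from 0 to 3 as the angle passes the
pain-onset angle; each muscle's EMG is band-limited Gaussian noise whose
amplitude envelope is baseline plus a pain-driven gain (extensors more
activated than flexors) and whose spectrum shifts downward as pain
rises.  Mains interference at 50 Hz can be added to exercise the notch
filter.

The generator reproduces the statistical structure the analysis
pipeline assumes — amplitude envelopes rising during flexion and
plateauing during hold, a downward spectral shift under pain — not the
biophysics of motor-unit recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import CHANNELS, EmgRecording, TrialSegment


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults follow the robot-assisted protocol: 8 trials per subject,
    slow flexion to the maxAP over 12 s, a 5 s hold, angle from 10° to
    70° with pain onset at 40°.  Extensor pain gains are three times the
    flexor gains.  ``spectral_shift`` is the fraction of carrier power
    moved from the high band to the low band at full pain.
    """

    fs: float = 2000.0
    n_trials: int = 8
    flexion_s: float = 12.0
    hold_s: float = 5.0
    start_angle: float = 10.0
    maxap: float = 70.0
    pain_onset_angle: float = 40.0
    #: per-channel (MRF, MVM, MBF-CL, MS) resting amplitude, mV RMS
    baseline_mV: tuple[float, ...] = (0.020, 0.018, 0.015, 0.014)
    #: per-channel amplitude added at full pain, mV RMS (extensors 3x flexors)
    pain_gain_mV: tuple[float, ...] = (0.060, 0.054, 0.020, 0.018)
    envelope_gamma: float = 1.0
    #: fraction of the pain ramp at which the EMG envelope saturates —
    #: unconscious contraction plateaus before the joint reaches the
    #: maxAP (reaction delay between muscle response and self-report)
    envelope_saturation: float = 0.85
    spectral_shift: float = 0.30
    low_band_hz: tuple[float, float] = (20.0, 150.0)
    high_band_hz: tuple[float, float] = (150.0, 450.0)
    base_low_fraction: float = 0.35
    mains_mV: float = 0.005
    angle_trace: bool = True

    def __post_init__(self) -> None:
        if self.flexion_s <= 0 or self.hold_s <= 0:
            raise ValueError("phase durations must be positive")
        if self.maxap <= self.start_angle:
            raise ValueError("maxap must exceed start_angle")
        if not (self.start_angle <= self.pain_onset_angle < self.maxap):
            raise ValueError("pain_onset_angle must lie in [start_angle, maxap)")
        if any(g < 0 for g in self.pain_gain_mV) or any(b <= 0 for b in self.baseline_mV):
            raise ValueError("gains must be >= 0 and baselines > 0")
        if not 0 <= self.spectral_shift <= 1 - self.base_low_fraction:
            raise ValueError("spectral_shift out of range")
        if not 0 < self.envelope_saturation <= 1:
            raise ValueError("envelope_saturation must be in (0, 1]")


def healthy_mode(cfg: SyntheticConfig) -> SyntheticConfig:
    """Healthy-control profile: pain gains cut to 10%, no spectral shift.

    Emulates subjects without joint stiffness, whose EMG shows no
    consistent flexion/hold difference: only the gain and shift fields
    change.
    """
    return replace(
        cfg,
        pain_gain_mV=tuple(0.1 * g for g in cfg.pain_gain_mV),
        spectral_shift=0.0,
    )


def null_mode(cfg: SyntheticConfig) -> SyntheticConfig:
    """Zero-effect profile: no pain-driven amplitude or spectral change."""
    return replace(
        cfg, pain_gain_mV=tuple(0.0 for _ in cfg.pain_gain_mV), spectral_shift=0.0
    )


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    pad = int(fs)  # discard the filter transient
    x = sps.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    return x / np.sqrt(np.mean(x**2))


def pain_level(angle: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Latent pain on the 0-3 rating scale as a function of joint angle."""
    frac = (np.asarray(angle) - cfg.pain_onset_angle) / (cfg.maxap - cfg.pain_onset_angle)
    return 3.0 * np.clip(frac, 0.0, 1.0)


def synth_trial(cfg: SyntheticConfig, trial_seed: int, trial_id: int = 0) -> TrialSegment:
    """One synthetic trial, fully determined by ``(cfg, trial_seed)``."""
    rng = np.random.default_rng(trial_seed)
    n_flex = int(round(cfg.flexion_s * cfg.fs))
    n_hold = int(round(cfg.hold_s * cfg.fs))
    n = n_flex + n_hold

    angle = np.concatenate(
        [
            np.linspace(cfg.start_angle, cfg.maxap, n_flex, endpoint=False),
            np.full(n_hold, cfg.maxap),
        ]
    )
    p = pain_level(angle, cfg) / 3.0  # normalised 0..1
    # muscular drive saturates before the pain report reaches threshold:
    # the envelope plateaus in late flexion, ahead of the maxAP
    drive = np.clip(p / cfg.envelope_saturation, 0.0, 1.0)
    t = np.arange(n) / cfg.fs

    sig = np.empty((len(CHANNELS), n))
    for ch in range(len(CHANNELS)):
        low = _band_noise(rng, n, cfg.low_band_hz, cfg.fs)
        high = _band_noise(rng, n, cfg.high_band_hz, cfg.fs)
        low_frac = cfg.base_low_fraction + cfg.spectral_shift * drive
        carrier = np.sqrt(low_frac) * low + np.sqrt(1.0 - low_frac) * high
        envelope = cfg.baseline_mV[ch] + cfg.pain_gain_mV[ch] * drive**cfg.envelope_gamma
        mains_phase = rng.uniform(0, 2 * np.pi)
        sig[ch] = envelope * carrier + cfg.mains_mV * np.sin(
            2 * np.pi * 50.0 * t + mains_phase
        )

    return TrialSegment(
        trial_id=trial_id,
        fs=cfg.fs,
        signal=sig,
        t_start=0.0,
        t_pain=cfg.flexion_s,
        t_end=(n - 1) / cfg.fs,
        angle=angle if cfg.angle_trace else None,
        true_maxap=cfg.maxap if cfg.angle_trace else None,
    )


def synth_recording(cfg: SyntheticConfig, seed: int, gap_s: float = 1.0) -> EmgRecording:
    """A full multi-trial recording with marker triples and inter-trial gaps.

    Between trials the channels carry baseline-level noise; the output
    passes :class:`~painflex.io.EmgRecording` validation and round-trips
    through ``segment_trials``.
    """
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(cfg.n_trials + 1)]
    rng = np.random.default_rng(trial_seeds[-1])

    n_gap = int(round(gap_s * cfg.fs))
    chunks, angle_chunks, markers = [], [], []
    t_cursor = 0.0

    def gap_chunk() -> np.ndarray:
        g = rng.standard_normal((len(CHANNELS), n_gap))
        return g * np.asarray(cfg.baseline_mV)[:, None]

    for k in range(cfg.n_trials):
        chunks.append(gap_chunk())
        angle_chunks.append(np.full(n_gap, cfg.start_angle))
        t_cursor += n_gap / cfg.fs
        tr = synth_trial(cfg, trial_seeds[k], trial_id=k)
        chunks.append(tr.signal)
        angle_chunks.append(
            tr.angle if tr.angle is not None else np.full(tr.n_samples, np.nan)
        )
        markers += [
            (t_cursor, "start"),
            (t_cursor + cfg.flexion_s, "pain"),
            (t_cursor + (tr.n_samples - 1) / cfg.fs, "end"),
        ]
        t_cursor += tr.n_samples / cfg.fs
    chunks.append(gap_chunk())
    angle_chunks.append(np.full(n_gap, cfg.start_angle))

    angle = np.concatenate(angle_chunks) if cfg.angle_trace else None
    return EmgRecording(
        fs=cfg.fs, samples=np.concatenate(chunks, axis=1), markers=markers, angle=angle
    )


@dataclass
class SyntheticSubject:
    """One simulated subject: their jittered config and trial list."""

    subject_id: int
    cfg: SyntheticConfig
    trials: list[TrialSegment]


def synth_cohort(
    cfg: SyntheticConfig,
    n_subjects: int,
    master_seed: int,
    experiment: str = "II",
    gain_jitter: float = 0.25,
    onset_jitter_deg: float = 5.0,
) -> list[SyntheticSubject]:
    """Per-subject trial sets with subject-level gain and onset jitter.

    ``experiment="II"`` gives the robot protocol (8 trials, angle
    trace); ``"I"`` the therapist protocol (5 trials, ~3 s hold, no
    angle trace).  Pain-onset jitter is per subject, not per trial,
    mirroring the robot's fixed preset maxAP.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if experiment == "I":
        cfg = replace(cfg, n_trials=5, hold_s=3.0, angle_trace=False)
    elif experiment != "II":
        raise ValueError(f"experiment must be 'I' or 'II', got {experiment!r}")

    ss = np.random.SeedSequence(master_seed)
    subjects = []
    for sid, subj_ss in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(subj_ss)
        factor = float(np.exp(rng.normal(0.0, gain_jitter)))
        onset = float(
            np.clip(
                cfg.pain_onset_angle + rng.normal(0.0, onset_jitter_deg),
                cfg.start_angle + 1.0,
                cfg.maxap - 5.0,
            )
        )
        subj_cfg = replace(
            cfg,
            pain_gain_mV=tuple(g * factor for g in cfg.pain_gain_mV),
            pain_onset_angle=onset,
        )
        trial_seeds = [
            int(s.generate_state(1)[0] % 2**31) for s in subj_ss.spawn(cfg.n_trials)
        ]
        trials = [
            synth_trial(subj_cfg, trial_seeds[k], trial_id=k)
            for k in range(cfg.n_trials)
        ]
        subjects.append(SyntheticSubject(subject_id=sid, cfg=subj_cfg, trials=trials))
    return subjects
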