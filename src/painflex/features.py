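"""Sliding-window EMG feature extraction and phase-based labelling.

Within each 250 ms window (125 ms step) twelve feature families are
computed per channel: four amplitude features (RMS, MAV, variance,
waveform length), two threshold counts (zero crossings, slope-sign
changes), two spectral moments (mean and median frequency of the raw
periodogram), three wavelet-packet families (RMS, variance and energy of
the 8 terminal sub-bands of a 3-level db4 decomposition) and sample
entropy — 33 values per channel, 132 over the four muscles.  Windows
whose end time falls in the flexion phase are labelled *painless*, those
ending in the hold phase *pain*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import pywt
from scipy.spatial.distance import cdist

from .io import CHANNELS, TrialSegment

PAINLESS, PAIN = "painless", "pain"


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing and feature parameters.

    ``eps_mV`` is the noise guard for the threshold counts; sample
    entropy uses embedding dimension ``sampen_m`` with tolerance
    ``sampen_r_coeff`` times the per-window standard deviation.
    """

    window_ms: float = 250.0
    step_ms: float = 125.0
    eps_mV: float = 0.005
    sampen_m: int = 2
    sampen_r_coeff: float = 0.2
    wpt_wavelet: str = "db4"
    wpt_level: int = 3

    def __post_init__(self) -> None:
        if not self.window_ms > self.step_ms > 0:
            raise ValueError("need window_ms > step_ms > 0")
        if self.eps_mV < 0 or self.sampen_m < 1 or self.wpt_level < 1:
            raise ValueError("invalid feature configuration")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))


@dataclass
class AnalysisWindow:
    """One sliding window: per-channel samples plus its phase label source."""

    x: np.ndarray  # channels x N, mV
    onset_s: float  # relative to trial start
    end_s: float
    phase: str  # flexion | hold
    trial_id: int = 0


def slide_windows(trial: TrialSegment, cfg: FeatureConfig = FeatureConfig()) -> list[AnalysisWindow]:
    """Windows at offsets 0, S, 2S, ... fully inside the trial.

    The window's phase is the trial phase at its *end* time, so a window
    straddling the pain mark counts as pain only once the mark has
    passed — the causal rule a pseudo-online system must use.
    """
    n = cfg.window_samples(trial.fs)
    s = cfg.step_samples(trial.fs)
    L = trial.n_samples
    if L < n:
        raise ValueError(
            f"trial {trial.trial_id} ({L} samples) shorter than one "
            f"{n}-sample window"
        )
    windows = []
    for off in range(0, L - n + 1, s):
        end_s = (off + n) / trial.fs
        phase = trial.phase_of(min(trial.t_start + end_s, trial.t_end))
        windows.append(
            AnalysisWindow(
                x=trial.signal[:, off: off + n],
                onset_s=off / trial.fs,
                end_s=end_s,
                phase=phase,
                trial_id=trial.trial_id,
            )
        )
    return windows


# ---------------------------------------------------------------- features

def time_domain_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """(RMS, MAV, VAR, WL) of one window.

    RMS = sqrt(mean x_i^2); MAV = mean |x_i|; VAR uses the unbiased
    (N-1) denominator; WL = sum |x_{i+1} - x_i|.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    rms = float(np.sqrt(np.mean(x**2)))
    mav = float(np.mean(np.abs(x)))
    var = float(np.var(x, ddof=1))
    wl = float(np.sum(np.abs(np.diff(x))))
    return rms, mav, var, wl


def threshold_counts(x: np.ndarray, eps_mV: float = 0.005, *, literal_eps: bool = False) -> tuple[int, int]:
    """(ZC, SSC): sign-change counts with a noise guard.

    ZC counts i with ``x_i * x_{i+1} < 0`` and ``|x_i - x_{i+1}| > eps``;
    SSC counts interior extrema with both neighbour differences
    exceeding eps in magnitude.  ``literal_eps=True`` drops the absolute
    value on the guard (signed differences), in which case the counts
    become order-dependent.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    d_fwd = x[:-1] - x[1:]  # x_i - x_{i+1}
    guard_fwd = d_fwd > eps_mV if literal_eps else np.abs(d_fwd) > eps_mV
    zc = int(np.sum((x[:-1] * x[1:] < 0) & guard_fwd))

    d_next = x[1:-1] - x[2:]   # x_i - x_{i+1}, interior i
    d_prev = x[1:-1] - x[:-2]  # x_i - x_{i-1}
    if literal_eps:
        g_next, g_prev = d_next > eps_mV, d_prev > eps_mV
    else:
        g_next, g_prev = np.abs(d_next) > eps_mV, np.abs(d_prev) > eps_mV
    ssc = int(np.sum((d_next * d_prev > 0) & g_next & g_prev))
    return zc, ssc


def periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided raw periodogram, bins f_j = j*fs/N for j = 1..N/2."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2
    j = np.arange(1, n // 2 + 1)
    return j * fs / n, spec[j]


def spectral_features(x: np.ndarray, fs: float) -> tuple[float, float]:
    """(MNF, MDF) from the raw periodogram.

    MNF is the power-weighted mean frequency; MDF the smallest bin where
    cumulative power reaches half the total.  An all-zero window has no
    defined spectrum and returns NaNs.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    f, p = periodogram(x, fs)
    total = p.sum()
    if total <= 0:
        return float("nan"), float("nan")
    mnf = float(np.sum(f * p) / total)
    mdf = float(f[np.searchsorted(np.cumsum(p), total / 2.0)])
    return mnf, mdf


def wpt_features(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """24 wavelet-packet values: RMS, VAR and energy of 8 sub-bands.

    3-level db4 decomposition with periodised boundaries so that the
    sub-band energies sum exactly to the window energy (Parseval for an
    orthogonal basis).  The window is zero-padded to the next multiple
    of ``2**level`` (500 -> 504 samples at 2000 Hz) so every
    decomposition level sees an even-length input, which keeps the
    periodised transform exactly orthogonal.  Terminal nodes are
    reported in ascending frequency order.
    """
    x = np.asarray(x, dtype=float)
    min_len = pywt.Wavelet(cfg.wpt_wavelet).dec_len * 2 ** (cfg.wpt_level - 1)
    if x.size < min_len:
        raise ValueError(f"window of {x.size} samples too short for WPT (need >= {min_len})")
    block = 2**cfg.wpt_level
    if x.size % block:
        x = np.concatenate([x, np.zeros(block - x.size % block)])
    wp = pywt.WaveletPacket(x, cfg.wpt_wavelet, mode="periodization", maxlevel=cfg.wpt_level)
    nodes = wp.get_level(cfg.wpt_level, order="freq")
    rms, var, energy = [], [], []
    for node in nodes:
        c = node.data
        rms.append(np.sqrt(np.mean(c**2)))
        var.append(np.var(c, ddof=1))
        energy.append(np.sum(c**2))
    return np.concatenate([rms, var, energy])


def sample_entropy(
    x: np.ndarray, m: int = 2, r_coeff: float = 0.2
) -> tuple[float, bool]:
    """Sample entropy with Chebyshev distance and self-matches excluded.

    ``r = r_coeff * std(x)`` (per window).  Returns ``(value, capped)``;
    when either template-match count is zero (including the constant
    window with r = 0) the maximum resolvable entropy
    ``-ln(2 / ((N-m-1)(N-m)))`` is returned with ``capped=True``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    r = r_coeff * float(np.std(x))
    cap = -np.log(2.0 / ((n - m - 1) * (n - m)))
    if r == 0.0:  # constant window: tolerance degenerates, entropy unresolvable
        return cap, True

    def mean_similarity(mm: int) -> float:
        # B^mm(r): ordered template pairs (i != j) within Chebyshev
        # tolerance r, over all N-mm+1 templates, normalised per
        # template by N-mm and averaged over templates.
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        k = emb.shape[0]  # N - mm + 1
        pairs = int(np.sum(d <= r)) - k  # Θ(r - d) counts d <= r; drop self-matches
        return pairs / ((k - 1) * k)

    b_m = mean_similarity(m)
    b_m1 = mean_similarity(m + 1)
    if b_m == 0.0 or b_m1 == 0.0:
        return cap, True
    return float(-np.log(b_m1 / b_m)), False


# ---------------------------------------------------------- feature table

_SCALARS = ["RMS", "MAV", "VAR", "WL", "ZC", "SSC", "MNF", "MDF"]


def feature_names(channels: Iterable[str] = CHANNELS, n_bands: int = 8) -> list[str]:
    """Column names in the contract order: 33 per channel."""
    names = []
    for ch in channels:
        names += [f"{ch}_{s}" for s in _SCALARS]
        for fam in ("WPTRMS", "WPTVAR", "WPTEnergy"):
            names += [f"{ch}_{fam}_{k}" for k in range(1, n_bands + 1)]
        names.append(f"{ch}_SampEn")
    return names


def window_features(win: AnalysisWindow, fs: float, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """The 33-per-channel feature vector of one window."""
    rows = []
    for ch in range(win.x.shape[0]):
        x = win.x[ch]
        rms, mav, var, wl = time_domain_features(x)
        zc, ssc = threshold_counts(x, cfg.eps_mV)
        mnf, mdf = spectral_features(x, fs)
        wpt = wpt_features(x, cfg)
        sampen, _ = sample_entropy(x, cfg.sampen_m, cfg.sampen_r_coeff)
        rows.append(np.concatenate([[rms, mav, var, wl, zc, ssc, mnf, mdf], wpt, [sampen]]))
    return np.concatenate(rows)


def build_feature_table(
    trials: list[TrialSegment], cfg: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """One labelled row per sliding window across all trials.

    Columns: the 132 ``channel_feature`` values (see
    :func:`feature_names`), plus ``trial_id``, ``onset_s``, ``end_s``
    and ``label`` (*painless* for flexion-phase windows, *pain* for
    hold-phase windows).
    """
    if not trials:
        raise ValueError("no trials given")
    names = feature_names(trials[0].channel_labels, 2 ** cfg.wpt_level)
    records, meta = [], []
    for tr in trials:
        for win in slide_windows(tr, cfg):
            try:
                records.append(window_features(win, tr.fs, cfg))
            except ValueError as exc:
                raise ValueError(
                    f"trial {tr.trial_id}, window at {win.onset_s:.3f}s: {exc}"
                ) from exc
            meta.append(
                (tr.trial_id, win.onset_s, win.end_s, PAIN if win.phase == "hold" else PAINLESS)
            )
    df = pd.DataFrame(np.asarray(records), columns=names)
    df[["trial_id", "onset_s", "end_s", "label"]] = pd.DataFrame(
        meta, columns=["trial_id", "onset_s", "end_s", "label"]
    )
    return df
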