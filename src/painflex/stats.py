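"""Across-subject feature statistics and paired comparisons.

For the therapist-assisted protocol the per-window features are first
normalised within each subject, averaged separately over painless
(flexion-phase) and pain (hold-phase) windows, and the per-subject
state means are compared with paired t-tests — one test per (muscle,
feature).  The same paired test compares per-subject classifier metrics
(SVM vs RF).  Significance stars: * p < 0.05, ** p < 0.01,
*** p < 0.001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .classification import META_COLUMNS
from .features import PAIN, PAINLESS


def stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test between matched per-subject values."""

    name: str
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool  # all differences zero: t undefined

    @property
    def stars(self) -> str:
        return stars(self.p)


def paired_t(a, b, name: str = "") -> PairedComparison:
    """Two-sided paired t-test, pairing by position (subject).

    t = mean(d) / (sd(d)/sqrt(n)) with the sample (n−1) standard
    deviation and df = n − 1.  Zero-variance differences are flagged
    degenerate (infinite t, p = 0 when the mean difference is nonzero;
    t = 0, p = 1 when all differences vanish).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedComparison(name, 0.0, n - 1, 1.0, 0.0, True)
        t = math.copysign(math.inf, d.mean())
        return PairedComparison(name, t, n - 1, 0.0, float(d.mean()), True)
    res = sst.ttest_rel(a, b)
    return PairedComparison(name, float(res.statistic), n - 1, float(res.pvalue), float(d.mean()), False)


def normalize_per_subject(
    features: pd.DataFrame, method: str = "zscore"
) -> pd.DataFrame:
    """Normalise each feature within each subject across all its windows.

    ``zscore`` (default) centres and scales to unit sd; ``minmax`` maps
    to [0, 1].  Zero-variance features are flagged with a warning and
    left unscaled.  Requires a ``subject_id`` column.
    """
    if method not in ("zscore", "minmax"):
        raise ValueError(f"unknown normalisation {method!r}")
    if "subject_id" not in features.columns:
        raise ValueError("feature table needs a subject_id column")
    cols = [c for c in features.columns if c not in META_COLUMNS]
    out = features.copy()
    for sid, idx in features.groupby("subject_id").groups.items():
        block = out.loc[idx, cols]
        if len(idx) < 2:
            raise ValueError(f"subject {sid} has fewer than 2 windows")
        if method == "zscore":
            spread = block.std(ddof=1)
            centre = block.mean()
        else:
            spread = block.max() - block.min()
            centre = block.min()
        flat = spread[spread == 0].index
        if len(flat):
            warnings.warn(f"subject {sid}: zero-variance feature(s) left unscaled: {list(flat)[:5]}")
            spread = spread.replace(0.0, 1.0)
            centre = centre.where(spread != 0, 0.0)
        out.loc[idx, cols] = (block - centre) / spread
    return out


def state_means(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-subject painless/pain means of each feature.

    Tidy output: one row per (subject_id, feature) with columns
    ``state_mean_painless`` and ``state_mean_pain``.  Subjects missing
    one of the two states are excluded with a warning.
    """
    cols = [c for c in normalized.columns if c not in META_COLUMNS]
    rows = []
    for sid, block in normalized.groupby("subject_id"):
        present = set(block["label"])
        if not {PAIN, PAINLESS} <= present:
            warnings.warn(f"subject {sid} lacks state(s) {({PAIN, PAINLESS} - present)}; excluded")
            continue
        painless = block.loc[block["label"] == PAINLESS, cols].mean()
        pain = block.loc[block["label"] == PAIN, cols].mean()
        for f in cols:
            rows.append(
                {
                    "subject_id": sid,
                    "feature": f,
                    "state_mean_painless": painless[f],
                    "state_mean_pain": pain[f],
                }
            )
    return pd.DataFrame(rows)


def compare_states(means: pd.DataFrame, holm: bool = True) -> pd.DataFrame:
    """Paired t-test pain vs painless per feature across subjects.

    One row per feature with t, df, two-sided p and significance stars
    (uncorrected, matching per-feature reporting); a Holm-adjusted
    p-value column is appended for users who want family-wise control.
    """
    rows = []
    for f, block in means.groupby("feature", sort=False):
        cmp = paired_t(
            block["state_mean_pain"].to_numpy(),
            block["state_mean_painless"].to_numpy(),
            name=f,
        )
        rows.append(
            {"feature": f, "t": cmp.t, "df": cmp.df, "p": cmp.p,
             "mean_diff": cmp.mean_diff, "stars": cmp.stars, "degenerate": cmp.degenerate}
        )
    df = pd.DataFrame(rows)
    if holm and len(df):
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[i])
            adj[i] = min(1.0, running)
        df["p_holm"] = adj
    return df
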