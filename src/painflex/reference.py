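"""Reference per-subject classification metrics for a seven-patient
robot-assisted training cohort.

These published per-subject accuracy/precision/recall/F1 values (percent)
are the worked-example inputs for the cohort-aggregation and paired-
comparison routines: recomputing the ``Mean ± std`` rows and the
SVM-vs-RF paired t statistics from them exercises the same code paths
used on model output.
"""

from __future__ import annotations

import pandas as pd

_COLS = ["accuracy", "precision", "recall", "f1"]

#: per-subject SVM metrics, percent
SVM_SUBJECT_METRICS = pd.DataFrame(
    [
        [92.18, 89.54, 95.57, 92.45],
        [86.59, 84.61, 93.09, 88.64],
        [86.09, 78.76, 95.33, 86.25],
        [80.32, 70.15, 99.15, 82.16],
        [93.77, 87.66, 94.95, 91.15],
        [86.07, 69.25, 94.24, 79.83],
        [90.28, 80.26, 88.46, 84.16],
    ],
    columns=_COLS,
    index=pd.RangeIndex(1, 8, name="subject"),
)

#: per-subject random-forest metrics, percent
RF_SUBJECT_METRICS = pd.DataFrame(
    [
        [91.43, 88.36, 95.47, 91.78],
        [89.58, 90.53, 90.98, 90.75],
        [87.40, 84.80, 88.30, 86.51],
        [80.96, 73.81, 90.46, 81.29],
        [94.97, 91.21, 94.20, 92.68],
        [87.99, 76.88, 84.34, 80.44],
        [91.38, 85.84, 84.36, 85.09],
    ],
    columns=_COLS,
    index=pd.RangeIndex(1, 8, name="subject"),
)


def aggregate_published(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``mean`` and ``std`` (sample, n−1) rows to a metric table."""
    out = table.copy()
    out.loc["mean"] = table.mean()
    out.loc["std"] = table.std(ddof=1)
    return out
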