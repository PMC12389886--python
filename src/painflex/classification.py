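"""Pain/painless classification under a trial-level double cross-validation.

The classifier separating *pain* (positive, +1) from *painless* (−1)
windows is either a cost-sensitive linear SVM — the soft-margin problem

    min  (1/2)·ωᵀω + R·C·Σ_{y=+1} ξ_i + C·Σ_{y=−1} ξ_j

where the cost factor R up-weights slack on the pain class — or a random
forest tuned over (number of trees N_T, minimum leaf size N_L).

Hyperparameters are chosen per subject with a double cross-validation:
the 8 trials are randomly partitioned into 4 sets of 2; each outer fold
holds one set out for testing and tunes on the remaining 3 via an inner
3-fold rotation scored by the T criterion

    T = 0.2·Acc_v + 0.2·Acc_o + 0.3·Pre_v + 0.3·Rec_v

(validation accuracy/precision/recall plus optimisation-set accuracy),
averaged over the 3 rotations.  All windows of a trial stay in the same
set — no window-level leakage — and feature scaling statistics are
computed on training folds only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from ._bayes import maximize_ei
from .features import PAIN, PAINLESS

META_COLUMNS = ("trial_id", "onset_s", "end_s", "label", "subject_id")


# ------------------------------------------------------------- estimators

class CostSensitiveSVM(ClassifierMixin, BaseEstimator):
    """Linear soft-margin SVM with asymmetric slack penalties.

    Slack on the positive (pain) class is penalised ``cost_ratio * C``
    while the negative class pays ``C``, so ``cost_ratio`` > 1 trades
    false negatives for false positives.  Labels are +1 (pain) and −1
    (painless).

    Parameters
    ----------
    C : float
        Margin/slack trade-off.
    cost_ratio : float
        The cost factor R multiplying the positive-class penalty.
    max_iter : int
        Hard cap on solver iterations; poorly conditioned points in a
        hyperparameter sweep (huge C on non-separable data) otherwise
        dominate the run time without changing which point is selected.
    """

    def __init__(self, C: float = 1.0, cost_ratio: float = 1.0, max_iter: int = 10_000):
        self.C = C
        self.cost_ratio = cost_ratio
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if not np.all(np.isin(classes, (-1, 1))) or classes.size != 2:
            raise ValueError(
                f"y must contain both labels -1 (painless) and +1 (pain), got {classes}"
            )
        self.svc_ = SVC(
            kernel="linear",
            C=self.C,
            class_weight={1: self.cost_ratio, -1: 1.0},
            cache_size=200,
            max_iter=self.max_iter,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ConvergenceWarning at the cap
            self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        self.coef_ = self.svc_.coef_
        self.intercept_ = self.svc_.intercept_
        return self

    def decision_function(self, X):
        """Signed score: positive means pain."""
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(X)


def make_random_forest(n_trees: int, min_leaf: int, seed: int) -> RandomForestClassifier:
    """Random forest with the two tuned hyperparameters fixed."""
    return RandomForestClassifier(
        n_estimators=int(n_trees),
        min_samples_leaf=int(min_leaf),
        random_state=int(seed),
        n_jobs=1,
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus its training-fold scaling statistics."""

    kind: str  # csvm | rf
    estimator: object
    params: dict
    scaler: StandardScaler | None = None
    feature_names: list[str] | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_expected = (
            len(self.feature_names)
            if self.feature_names is not None
            else getattr(self.estimator, "n_features_in_", X.shape[1])
        )
        if X.shape[1] != n_expected:
            raise ValueError(f"model expects {n_expected} features, got {X.shape[1]}")
        return self.scaler.transform(X) if self.scaler is not None else X

    def decision_scores(self, X) -> np.ndarray:
        """Signed per-window score; positive ⇒ pain."""
        X = self._prepare(X)
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(X))
        # forests: signed margin = P(pain) - P(painless)
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos] - proba[:, 1 - pos]

    def predict_labels(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.where(scores > 0, PAIN, PAINLESS)


# ------------------------------------------------------------ primitives

T_WEIGHTS = (0.2, 0.2, 0.3, 0.3)


def t_value(
    acc_v: float, acc_o: float, pre_v: float, rec_v: float,
    weights: Sequence[float] = T_WEIGHTS,
) -> float:
    """Hyperparameter-selection criterion: weighted sum of four rates."""
    vals = (acc_v, acc_o, pre_v, rec_v)
    if any(not 0.0 <= v <= 1.0 for v in vals):
        raise ValueError(f"all inputs must lie in [0, 1], got {vals}")
    return float(np.dot(weights, vals))


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float  # NaN when TP+FP == 0
    recall: float  # NaN when TP+FN == 0
    f1: float  # NaN when precision or recall undefined


def confusion_metrics(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionMetrics:
    """Accuracy/precision/recall/F1 with pain as the positive class.

    Precision (recall) is flagged NaN when no positive prediction
    (positive truth) exists; callers exclude flagged values from
    averages.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    valid = {PAIN, PAINLESS}
    labels = set(y_true) | set(y_pred)
    if not labels <= valid:
        raise ValueError(f"labels outside {{pain, painless}}: {labels - valid}")
    tp = int(np.sum((y_true == PAIN) & (y_pred == PAIN)))
    tn = int(np.sum((y_true == PAINLESS) & (y_pred == PAINLESS)))
    fp = int(np.sum((y_true == PAINLESS) & (y_pred == PAIN)))
    fn = int(np.sum((y_true == PAIN) & (y_pred == PAINLESS)))
    acc = (tp + tn) / len(y_true)
    pre = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    if math.isnan(pre) or math.isnan(rec) or pre + rec == 0:
        f1 = float("nan")
    else:
        f1 = 2 * pre * rec / (pre + rec)
    return ConfusionMetrics(tp, tn, fp, fn, acc, pre, rec, f1)


def make_outer_folds(trial_ids: Sequence[int], seed: int, n_folds: int = 4) -> list[list[int]]:
    """Seeded random partition of trials into ``n_folds`` equal sets."""
    ids = list(trial_ids)
    if len(ids) % n_folds:
        raise ValueError(f"{len(ids)} trials not divisible into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    size = len(ids) // n_folds
    return [sorted(int(t) for t in perm[k * size: (k + 1) * size]) for k in range(n_folds)]


# ------------------------------------------------------------------ spec

@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family plus its search space and CV layout.

    The reference CSVM grid is every integer exponent of 2 from −20 to
    20 for both R and C; :meth:`desk_scale` thins it for interactive
    runs.
    """

    kind: str = "csvm"  # csvm | rf
    c_exponents: tuple[int, ...] = tuple(range(-20, 21))
    r_exponents: tuple[int, ...] = tuple(range(-20, 21))
    t_weights: tuple[float, ...] = T_WEIGHTS
    outer_folds: int = 4
    inner_folds: int = 3
    rf_trees: tuple[int, int] = (10, 500)
    rf_min_leaf: tuple[int, int] = (1, 50)
    rf_iterations: int = 30
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("csvm", "rf"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not self.c_exponents or not self.r_exponents:
            raise ValueError("empty hyperparameter grid")
        if abs(sum(self.t_weights) - 1.0) > 1e-12:
            raise ValueError("T weights must sum to 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.rf_iterations < 1:
            raise ValueError("need at least one optimiser iteration")

    @classmethod
    def desk_scale(cls, kind: str = "csvm", **kw) -> "ClassifierSpec":
        """Coarse grid (2^−12 … 2^12, stride 4), a 12-evaluation RF
        budget and trees capped at 200 — for desk-scale runs; the full
        search space stays available via the default constructor."""
        kw.setdefault("c_exponents", tuple(range(-12, 13, 4)))
        kw.setdefault("r_exponents", tuple(range(-12, 13, 4)))
        kw.setdefault("rf_trees", (10, 200))
        kw.setdefault("rf_iterations", 12)
        return cls(kind=kind, **kw)


# ------------------------------------------------------- inner selection

def split_features(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(X, y, trial_ids, feature_names) from a feature table.

    ``y`` is +1 for pain, −1 for painless.
    """
    names = [c for c in df.columns if c not in META_COLUMNS]
    X = df[names].to_numpy(dtype=float)
    y = np.where(df["label"].to_numpy() == PAIN, 1, -1)
    return X, y, df["trial_id"].to_numpy(), names


def _inner_rotations(training_sets: list[list[int]]):
    """Yield (validation_set, optimisation_sets) rotating each set once."""
    for v in range(len(training_sets)):
        yield training_sets[v], [s for i, s in enumerate(training_sets) if i != v]


def _fold_t(
    model, scaler, X_opt, y_opt, X_val, y_val, weights
) -> tuple[float, bool]:
    """T value of one inner rotation; flags folds with undefined terms."""
    if scaler is not None:
        X_opt = scaler.transform(X_opt)
        X_val = scaler.transform(X_val)
    acc_o = float(np.mean(model.predict(X_opt) == y_opt))
    pred_v = model.predict(X_val)
    m = confusion_metrics(
        np.where(y_val == 1, PAIN, PAINLESS), np.where(pred_v == 1, PAIN, PAINLESS)
    )
    if math.isnan(m.precision) or math.isnan(m.recall):
        return float("nan"), True
    return t_value(m.accuracy, acc_o, m.precision, m.recall, weights), False


def _mean_inner_t(build_model, df, training_sets, spec) -> tuple[float, int]:
    """Mean T over the 3 inner rotations for one hyperparameter point.

    Rotations with undefined validation precision or recall (a
    single-class validation fold, or a model that never predicts the
    positive class) are dropped from the average; the count of dropped
    rotations is returned so callers can warn once per selection.
    NaN is returned when every rotation is degenerate.
    """
    X, y, tid, _ = split_features(df)
    ts, dropped = [], 0
    for val_set, opt_sets in _inner_rotations(training_sets):
        opt_ids = [t for s in opt_sets for t in s]
        tr_mask = np.isin(tid, opt_ids)
        va_mask = np.isin(tid, val_set)
        scaler = None
        X_tr = X[tr_mask]
        if spec.scale_features and spec.kind == "csvm":
            scaler = StandardScaler().fit(X_tr)
            X_tr = scaler.transform(X_tr)
        model = build_model()
        model.fit(X_tr, y[tr_mask])
        t, degenerate = _fold_t(
            model, scaler, X[tr_mask], y[tr_mask], X[va_mask], y[va_mask], spec.t_weights
        )
        if degenerate:
            dropped += 1
        else:
            ts.append(t)
    return (float(np.mean(ts)) if ts else float("nan")), dropped


def inner_select_csvm(
    df: pd.DataFrame, training_sets: list[list[int]], spec: ClassifierSpec
) -> tuple[float, float, float]:
    """Grid-search (R*, C*) maximising the mean inner-CV T value.

    Ties break toward the smallest C, then the smallest R (stronger
    regularisation, weaker asymmetry).  Returns ``(R*, C*, T*)``.
    """
    best = None
    n_dropped = 0
    for ce in spec.c_exponents:
        for re_ in spec.r_exponents:
            C, R = 2.0**ce, 2.0**re_
            t, dropped = _mean_inner_t(
                lambda: CostSensitiveSVM(C=C, cost_ratio=R), df, training_sets, spec
            )
            n_dropped += dropped
            if math.isnan(t):
                continue
            key = (t, -ce, -re_)  # max T, then smallest C, then smallest R
            if best is None or key > best[0]:
                best = (key, R, C, t)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} inner rotation(s) had undefined precision/recall "
            "and were dropped from the T average"
        )
    if best is None:
        raise ValueError("no hyperparameter point produced a defined T value")
    return best[1], best[2], best[3]


def select_rf(
    df: pd.DataFrame, training_sets: list[list[int]], spec: ClassifierSpec, seed: int
) -> tuple[int, int, float]:
    """Bayesian optimisation of (N_T*, N_L*) on the mean inner-CV T value."""

    def objective(n_trees: int, min_leaf: int) -> float:
        t, _ = _mean_inner_t(
            lambda: make_random_forest(n_trees, min_leaf, seed), df, training_sets, spec
        )
        return -1.0 if math.isnan(t) else t

    (nt, nl), best_t, _ = maximize_ei(
        objective,
        (spec.rf_trees, spec.rf_min_leaf),
        n_iterations=spec.rf_iterations,
        seed=seed,
    )
    return nt, nl, best_t


def train_model(df: pd.DataFrame, spec: ClassifierSpec, params: dict, seed: int) -> TrainedModel:
    """Fit the chosen classifier on all rows of ``df`` (training windows)."""
    X, y, _, names = split_features(df)
    scaler = None
    if spec.scale_features and spec.kind == "csvm":
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    if spec.kind == "csvm":
        est = CostSensitiveSVM(C=params["C"], cost_ratio=params["R"]).fit(X, y)
    else:
        est = make_random_forest(params["n_trees"], params["min_leaf"], seed).fit(X, y)
    return TrainedModel(kind=spec.kind, estimator=est, params=dict(params), scaler=scaler, feature_names=names)


def train_csvm(df: pd.DataFrame, R: float, C: float, scale: bool = True) -> TrainedModel:
    """Convenience wrapper: fit the cost-sensitive SVM on a feature table."""
    spec = ClassifierSpec(kind="csvm", scale_features=scale)
    return train_model(df, spec, {"C": C, "R": R}, seed=0)


# --------------------------------------------------------------- reports

@dataclass
class FoldResult:
    fold: int
    test_trials: list[int]
    params: dict
    metrics: ConfusionMetrics


@dataclass
class CvReport:
    """Per-fold outcomes of one subject's double cross-validation."""

    kind: str
    subject_id: int | str
    folds: list[FoldResult]

    def mean_metric(self, name: str) -> float:
        vals = [getattr(f.metrics, name) for f in self.folds]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "kind": self.kind,
            "accuracy": self.mean_metric("accuracy"),
            "precision": self.mean_metric("precision"),
            "recall": self.mean_metric("recall"),
            "f1": self.mean_metric("f1"),
        }


def run_outer_cv(
    df: pd.DataFrame,
    spec: ClassifierSpec,
    seed: int,
    subject_id: int | str = 0,
    return_models: bool = False,
):
    """Double cross-validation for one subject's labelled feature table.

    Each of the ``outer_folds`` folds holds one trial set out as the
    test set, tunes hyperparameters by the inner rotation over the
    remaining sets, refits on all training windows and evaluates on the
    held-out pair.
    """
    trial_ids = sorted(df["trial_id"].unique())
    sets = make_outer_folds(trial_ids, seed, spec.outer_folds)
    folds, models = [], []
    for k, test_set in enumerate(sets):
        training_sets = [s for i, s in enumerate(sets) if i != k]
        train_df = df[~df["trial_id"].isin(test_set)]
        test_df = df[df["trial_id"].isin(test_set)]
        try:
            if spec.kind == "csvm":
                R, C, t_star = inner_select_csvm(train_df, training_sets, spec)
                params = {"R": R, "C": C, "inner_T": t_star}
            else:
                nt, nl, t_star = select_rf(train_df, training_sets, spec, seed + k)
                params = {"n_trees": nt, "min_leaf": nl, "inner_T": t_star}
            model = train_model(train_df, spec, params, seed + k)
        except Exception as exc:
            raise RuntimeError(f"outer fold {k} (test trials {test_set}): {exc}") from exc
        X_te, y_te, _, _ = split_features(test_df)
        pred = model.predict_labels(X_te)
        m = confusion_metrics(np.where(y_te == 1, PAIN, PAINLESS), pred)
        folds.append(FoldResult(fold=k, test_trials=test_set, params=params, metrics=m))
        models.append(model)
    report = CvReport(kind=spec.kind, subject_id=subject_id, folds=folds)
    return (report, models) if return_models else report


def aggregate_subjects(reports: Sequence[CvReport]) -> pd.DataFrame:
    """Cohort table: one row per subject plus a ``Mean ± std`` row.

    The final row holds the across-subject mean and sample (n−1)
    standard deviation of each metric.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 subjects to aggregate")
    rows = [r.summary() for r in reports]
    df = pd.DataFrame(rows).set_index("subject_id")
    metrics = ["accuracy", "precision", "recall", "f1"]
    mean = df[metrics].mean()
    std = df[metrics].std(ddof=1)
    df.loc["mean"] = {**{m: mean[m] for m in metrics}, "kind": df["kind"].iloc[0]}
    df.loc["std"] = {**{m: std[m] for m in metrics}, "kind": df["kind"].iloc[0]}
    return df


def sequential_forward_selection(
    df: pd.DataFrame,
    spec: ClassifierSpec,
    seed: int,
    max_features: int | None = None,
    params: dict | None = None,
) -> pd.DataFrame:
    """Greedy forward feature selection on the inner-CV mean T value.

    At each step the feature whose addition maximises the mean inner T
    (at fixed hyperparameters ``params``, default C = R = 1 for the SVM)
    joins the subset.  The full-set baseline is evaluated on the same
    rotation and returned as the last row.
    """
    X, y, tid, names = split_features(df)
    if len(names) < 2:
        raise ValueError("need at least 2 features")
    trial_ids = sorted(df["trial_id"].unique())
    sets = make_outer_folds(trial_ids, seed, spec.inner_folds)
    params = params or ({"C": 1.0, "R": 1.0} if spec.kind == "csvm" else {"n_trees": 100, "min_leaf": 1})

    def builder():
        if spec.kind == "csvm":
            return CostSensitiveSVM(C=params["C"], cost_ratio=params["R"])
        return make_random_forest(params["n_trees"], params["min_leaf"], seed)

    def score(subset: list[str]) -> float:
        sub = df[subset + ["trial_id", "label"]]
        return _mean_inner_t(builder, sub, sets, spec)[0]

    chosen: list[str] = []
    rows = []
    limit = max_features or len(names)
    while len(chosen) < limit:
        scores = [(score(chosen + [f]), f) for f in names if f not in chosen]
        best_t, best_f = max(scores, key=lambda s: (s[0], s[1]))
        chosen.append(best_f)
        rows.append({"step": len(chosen), "added": best_f, "mean_T": best_t,
                     "subset": tuple(chosen)})
    rows.append({"step": -1, "added": "<full set>", "mean_T": score(list(names)),
                 "subset": tuple(names)})
    return pd.DataFrame(rows)
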