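"""End-to-end orchestration: simulate → preprocess → features → double CV
→ pseudo-online streams → maxAP bias report.

One master seed deterministically derives every module seed, so a run
is reproducible from ``(inputs, config)`` alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .classification import ClassifierSpec, CvReport, aggregate_subjects, run_outer_cv
from .features import FeatureConfig, build_feature_table
from .online import bias_summary, estimate_maxap, smooth_decisions, stream_from_features
from .simulate import SyntheticConfig, SyntheticSubject, synth_cohort
from .stats import paired_t

log = logging.getLogger("painflex")


@dataclass(frozen=True)
class RunConfig:
    """Everything a cohort run needs, under a single master seed."""

    synthetic: SyntheticConfig = SyntheticConfig()
    features: FeatureConfig = FeatureConfig()
    specs: tuple[ClassifierSpec, ...] = (
        ClassifierSpec.desk_scale("csvm"),
        ClassifierSpec.desk_scale("rf"),
    )
    n_subjects: int = 7
    smoothing_width: int = 5
    seed: int = 42
    filter_signals: bool = True


def filter_trial(trial: pio.TrialSegment, **kw) -> pio.TrialSegment:
    """Band-pass + notch a single trial's signal (zero phase)."""
    rec = pio.EmgRecording(
        fs=trial.fs,
        samples=trial.signal,
        markers=[(0.0, "start"), (trial.t_pain - trial.t_start, "pain"),
                 (trial.t_end - trial.t_start, "end")],
        channel_labels=trial.channel_labels,
    )
    filtered = pio.bandpass_notch(rec, **kw)
    return replace(trial, signal=filtered.samples)


def subject_features(
    subject: SyntheticSubject, cfg: RunConfig
) -> tuple[pd.DataFrame, list[pio.TrialSegment]]:
    """Preprocess one subject's trials and extract the labelled table."""
    trials = subject.trials
    if cfg.filter_signals:
        trials = [filter_trial(t) for t in trials]
    df = build_feature_table(trials, cfg.features)
    df["subject_id"] = subject.subject_id
    return df, trials


def run_experiment2(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full robot-protocol evaluation on a synthetic cohort.

    Returns a dict with the per-classifier cohort tables (subject rows
    plus mean/std), the per-classifier maxAP bias summaries, the
    SVM-vs-RF paired comparisons and the per-trial decision streams of
    the test folds.
    """
    ss = np.random.SeedSequence(cfg.seed)
    cohort_seed, cv_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    cohort = synth_cohort(cfg.synthetic, cfg.n_subjects, cohort_seed)

    reports: dict[str, list[CvReport]] = {s.kind: [] for s in cfg.specs}
    biases: dict[str, dict] = {}
    streams: dict[str, list[pd.DataFrame]] = {s.kind: [] for s in cfg.specs}
    estimates: dict[str, dict] = {s.kind: {} for s in cfg.specs}

    tables = {}
    features_by_subject = {}
    for subject in cohort:
        df, trials = subject_features(subject, cfg)
        features_by_subject[subject.subject_id] = df
        trial_by_id = {t.trial_id: t for t in trials}
        for spec in cfg.specs:
            report, models = run_outer_cv(
                df, spec, cv_seed + subject.subject_id,
                subject_id=subject.subject_id, return_models=True,
            )
            reports[spec.kind].append(report)
            for fold, model in zip(report.folds, models):
                log.info(
                    "subject %s %s fold %d: params=%s acc=%.3f",
                    subject.subject_id, spec.kind, fold.fold, fold.params,
                    fold.metrics.accuracy,
                )
                for tid in fold.test_trials:
                    stream = stream_from_features(model, df, tid)
                    stream = smooth_decisions(stream, cfg.smoothing_width)
                    streams[spec.kind].append(
                        stream.to_frame().assign(subject_id=subject.subject_id)
                    )
                    est = estimate_maxap(stream, trial_by_id[tid])
                    estimates[spec.kind].setdefault(subject.subject_id, []).append(est)

    for spec in cfg.specs:
        tables[spec.kind] = aggregate_subjects(reports[spec.kind])
        biases[spec.kind] = bias_summary(estimates[spec.kind])

    comparisons = None
    kinds = [s.kind for s in cfg.specs]
    if len(kinds) == 2:
        a, b = (tables[k].drop(index=["mean", "std"]) for k in kinds)
        rows = []
        for metric in ("accuracy", "precision", "recall", "f1"):
            cmp = paired_t(a[metric].to_numpy(), b[metric].to_numpy(), name=metric)
            rows.append({"metric": metric, "pair": f"{kinds[0]} vs {kinds[1]}",
                         "t": cmp.t, "df": cmp.df, "p": cmp.p, "stars": cmp.stars})
        comparisons = pd.DataFrame(rows)

    result = {
        "tables": tables,
        "bias": biases,
        "comparisons": comparisons,
        "streams": {k: pd.concat(v, ignore_index=True) for k, v in streams.items()},
        "estimates": estimates,
        "features_by_subject": features_by_subject,
        "seed": cfg.seed,
    }
    if out_dir is not None:
        _write_report(result, Path(out_dir))
    return result


def run_chance_control(
    features_by_subject: dict, spec: ClassifierSpec, seed: int
) -> dict:
    """Label-permutation control: accuracy should collapse to chance.

    Within each subject the majority class is subsampled to match the
    minority count (so chance is 0.5 rather than the class prior) and
    the window labels are then randomly permuted.  The double CV runs
    unchanged on the permuted tables; the across-subject mean accuracy
    is returned with the per-subject values.
    """
    rng = np.random.default_rng(seed)
    accs = {}
    for sid, df in features_by_subject.items():
        pain_idx = df.index[df["label"] == "pain"]
        painless_idx = df.index[df["label"] == "painless"]
        n = min(len(pain_idx), len(painless_idx))
        keep = np.concatenate([
            rng.choice(pain_idx, n, replace=False),
            rng.choice(painless_idx, n, replace=False),
        ])
        sub = df.loc[np.sort(keep)].copy()
        sub["label"] = rng.permutation(sub["label"].to_numpy())
        report = run_outer_cv(sub, spec, int(rng.integers(2**31)), subject_id=sid)
        accs[sid] = report.mean_metric("accuracy")
    return {
        "per_subject_accuracy": accs,
        "mean_accuracy": float(np.mean(list(accs.values()))),
    }


def run_type_one_calibration(
    n_cohorts: int = 200,
    n_subjects: int = 5,
    seed: int = 0,
    synthetic: SyntheticConfig | None = None,
) -> dict:
    """False-positive calibration of the state-comparison t-tests.

    Simulates zero-effect cohorts (no pain-driven amplitude or spectral
    change), runs the normalise → state-means → paired-t chain on each,
    and reports the fraction of (cohort, feature) tests significant at
    α = 0.05 — which should sit near 0.05.  Cohorts are kept small
    (short single trials at 1 kHz) so hundreds of replicates run in
    minutes; the test's validity depends only on subject count, not
    trial length.
    """
    from .simulate import null_mode, synth_cohort
    from .stats import compare_states, normalize_per_subject, state_means

    cfg = synthetic or SyntheticConfig(
        fs=1000.0, flexion_s=1.5, hold_s=1.0, n_trials=1
    )
    cfg = null_mode(cfg)
    ss = np.random.SeedSequence(seed)
    n_sig = n_total = 0
    fractions = []
    for cohort_ss in ss.spawn(n_cohorts):
        cohort_seed = int(cohort_ss.generate_state(1)[0] % 2**31)
        cohort = synth_cohort(cfg, n_subjects, cohort_seed)
        frames = []
        for subject in cohort:
            df = build_feature_table(subject.trials)
            df["subject_id"] = subject.subject_id
            frames.append(df)
        feats = pd.concat(frames, ignore_index=True)
        comp = compare_states(state_means(normalize_per_subject(feats)), holm=False)
        sig = int((comp["p"] < 0.05).sum())
        n_sig += sig
        n_total += len(comp)
        fractions.append(sig / len(comp))
    return {
        "fraction_significant": n_sig / n_total,
        "n_cohorts": n_cohorts,
        "n_tests": n_total,
        "per_cohort_fractions": fractions,
    }


def _write_report(result: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for kind, table in result["tables"].items():
        table.to_csv(out / f"metrics_{kind}.csv")
        result["streams"][kind].to_csv(out / f"streams_{kind}.csv", index=False)
    if result["comparisons"] is not None:
        result["comparisons"].to_csv(out / "paired_comparisons.csv", index=False)
    bias_obj = {
        kind: {k: v for k, v in b.items()} for kind, b in result["bias"].items()
    }
    (out / "bias_report.json").write_text(
        json.dumps({"seed": result["seed"], "bias": bias_obj}, indent=2, sort_keys=True)
    )
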