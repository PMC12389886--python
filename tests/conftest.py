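"""Shared fixtures: small, fast synthetic configurations.

The reduced sampling rate / durations keep the suite quick; full-scale
study conditions are exercised in the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from painflex import FeatureConfig, SyntheticConfig, synth_cohort, synth_trial
from painflex.pipeline import RunConfig, subject_features


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Short trials at 1 kHz: enough windows for CV, fast to generate."""
    return SyntheticConfig(fs=1000.0, flexion_s=4.0, hold_s=2.0)


@pytest.fixture(scope="session")
def small_trial(small_cfg):
    return synth_trial(small_cfg, trial_seed=7)


@pytest.fixture(scope="session")
def small_subject_features(small_cfg):
    """Labelled feature table of one 8-trial subject (small scale)."""
    subject = synth_cohort(small_cfg, 1, 123)[0]
    df, trials = subject_features(subject, RunConfig(synthetic=small_cfg))
    return df, trials


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
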