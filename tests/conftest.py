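"""Shared fixtures: synthetic records and cohorts with known ground truth.

Everything is generated programmatically at test time; session scope keeps
the larger cohorts from being rebuilt per test.
"""

import warnings

import numpy as np
import pytest

from ppg2bp.preprocess import preprocess_record
from ppg2bp.synthetic import (
    DEFAULT_NOISE,
    NoiseConfig,
    SyntheticBeatConfig,
    generate_cohort,
    generate_record,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticBeatConfig()


@pytest.fixture(scope="session")
def clean_record(default_config):
    """Noiseless 3-s record (two complete valley-bounded beats) plus truth."""
    return generate_record(default_config, NoiseConfig(), fs=1000.0, duration=3.0, seed=0)


@pytest.fixture(scope="session")
def noisy_record(default_config):
    return generate_record(default_config, DEFAULT_NOISE, fs=1000.0, duration=3.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """30-subject cohort with default noise: records, table, truths."""
    return generate_cohort(30, 3, seed=11)


@pytest.fixture(scope="session")
def cohort_features(small_cohort):
    """Feature matrix of the small cohort (preprocessed, extracted)."""
    from ppg2bp.features import build_feature_matrix

    records, table, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, failures = build_feature_matrix(
            [preprocess_record(r) for r in records], table
        )
    return matrix, failures


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
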