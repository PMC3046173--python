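"""Shared fixtures: synthetic records and the full recovery experiment."""

import warnings

import numpy as np
import pytest

from hrvrisk.io import FeatureVector, RRSeries, features_to_frame
from hrvrisk.pipeline import extract_features
from hrvrisk.preprocessing import rosner_filter
from hrvrisk.synthetic import CohortSpec, generate_cohort, generate_rr

RECOVERY_SEEDS = range(1, 11)


@pytest.fixture
def rr_normal() -> RRSeries:
    """One 5-minute normal-class NN series."""
    return generate_rr(seed=42)


@pytest.fixture
def random_rr_factory():
    """Factory for i.i.d. Gaussian NN series (seeded)."""

    def make(seed: int, n: int = 300, mean: float = 800.0, sd: float = 25.0) -> RRSeries:
        rng = np.random.default_rng(seed)
        return RRSeries(intervals=np.abs(rng.normal(mean, sd, n)) + 1.0)

    return make


def extract_cohort_table(seed: int):
    """Clean + extract the feature table of one default synthetic cohort."""
    records, labels = generate_cohort(CohortSpec(seed=seed))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rr in records:
            rr_clean, _ = rosner_filter(rr)
            rows.append(FeatureVector(rr.id, extract_features(rr_clean)))
    return features_to_frame(rows), np.asarray(labels)


@pytest.fixture(scope="session")
def recovery_tables():
    """Feature tables of the default cohort (45+45, risk_scaling=0.5)
    for seeds 1-10; shared across the parameter-recovery tests."""
    return {seed: extract_cohort_table(seed) for seed in RECOVERY_SEEDS}
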