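import numpy as np
import pandas as pd
import pytest

from stresspair import CohortConfig, FeatureMatrix, generate_cohort, subset_split
from stresspair.simulate import NO_STRESS, STRESS


def make_fm(values, labels=None, split=None, feature_names=None, sample_ids=None):
    """Build a FeatureMatrix from a plain array for compact test setup."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_names = feature_names or [f"f{k}" for k in range(p)]
    sample_ids = sample_ids or [f"s{k}" for k in range(n)]
    return FeatureMatrix(
        pd.DataFrame(values, index=sample_ids, columns=feature_names),
        labels=labels,
        split=split,
    )


def random_labeled_fm(rng, n=10, p=4):
    labels = [NO_STRESS] * (n // 2) + [STRESS] * (n - n // 2)
    return make_fm(rng.standard_normal((n, p)), labels=labels)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=20))


@pytest.fixture(scope="session")
def default_fm(default_cohort):
    return default_cohort.to_feature_matrix()


@pytest.fixture(scope="session")
def train_valid(default_fm):
    return subset_split(default_fm, "train"), subset_split(default_fm, "validation")
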