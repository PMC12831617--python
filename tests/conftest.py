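import numpy as np
import pytest

import panelomics as po


@pytest.fixture(scope="session")
def mini_cohort():
    """20 samples x 30 features, 3 planted effects at d=1.5."""
    return po.fixture_suite(seed=7)["mini"]


@pytest.fixture(scope="session")
def separable_cohort():
    """40 samples, one planted feature at d=4 (near-perfect separator)."""
    return po.fixture_suite(seed=7)["separable"]


@pytest.fixture(scope="session")
def null_cohort():
    """22 samples x 30 features, no informative features."""
    return po.fixture_suite(seed=7)["null"]


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-sized cohort: 40/49 samples, 100/82/60 features."""
    return po.generate_cohort(po.SyntheticSpec(seed=11))


@pytest.fixture()
def labels6():
    return po.PhenotypeLabels(list("abcdef"), [1, 1, 1, 0, 0, 0])


def standardized(table, labels):
    std, _ = po.impute_and_standardize(table)
    return std.values, labels.label, std.feature_ids


@pytest.fixture(scope="session")
def planted30_cohort():
    """89 samples, 30 features, 3 planted at d=2 (deep-ranker recovery size)."""
    spec = po.SyntheticSpec(
        layer_sizes=(10, 10, 10), n_informative=3, effect_size=2.0, seed=3
    )
    return po.generate_cohort(spec)
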