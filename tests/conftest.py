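import numpy as np
import pytest

from mopflow import (
    PlantedRule,
    binarize,
    featurize,
    fit_ensemble,
    generate_library,
)
from mopflow.synthetic import (
    blind_test_table,
    planted_columns,
    rule_match_vector,
    synthetic_training_table,
)


@pytest.fixture(scope="session")
def rule():
    return PlantedRule()


@pytest.fixture(scope="session")
def library(rule):
    return generate_library(40, rule, seed=7)


@pytest.fixture(scope="session")
def library_features(library):
    return featurize(library, radius=1)


@pytest.fixture(scope="session")
def labeled(library, library_features):
    return binarize(library, library_features, 50.0)


@pytest.fixture(scope="session")
def ensemble(labeled):
    return fit_ensemble(labeled, B=200, seed=3)


@pytest.fixture(scope="session")
def planted_cols(library, library_features, rule):
    cols = planted_columns(library_features, rule_match_vector(library, rule))
    assert cols, "generator must emit at least one rule-tracking column"
    return cols


@pytest.fixture(scope="session")
def training_table():
    return synthetic_training_table()


@pytest.fixture(scope="session")
def blind_test():
    return blind_test_table()
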