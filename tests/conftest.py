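"""Shared fixtures: a small seeded synthetic dataset and a trained ensemble.

Training fixtures are session-scoped so the grid searches run once for the
whole suite.  The reduced grids keep tests quick while still exercising the
exhaustive-search machinery.
"""

from __future__ import annotations

import pytest

import synapred as sp

#: small but non-trivial grids used wherever the test is not about grid content
FAST_GRIDS = {
    "kNN": {"n_neighbors": [3, 5], "weights": ["uniform", "distance"]},
    "SVM": {"C": [1.0, 10.0], "gamma": [0.1, 1.0]},
    "RF": {"n_estimators": [50], "max_depth": [None, 10]},
}


@pytest.fixture(scope="session")
def tiny_config() -> sp.SimulationConfig:
    return sp.SimulationConfig(
        n_genes=300, n_pos_labeled=20, n_neg_labeled=60, n_hidden_pos=15, seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config) -> sp.SyntheticDataset:
    return sp.generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_normalized(tiny_dataset, tiny_config):
    retained, _ = sp.filter_adult_only(tiny_dataset.matrix, tiny_config.adult_stage_indices)
    return sp.max_normalize(retained)


@pytest.fixture(scope="session")
def tiny_labeled(tiny_dataset, tiny_normalized) -> sp.LabeledGeneSet:
    present = frozenset(tiny_normalized.index)
    return sp.LabeledGeneSet(
        tiny_dataset.positives & present, tiny_dataset.negatives & present
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_labeled, tiny_normalized):
    """15 classifiers + their splits, trained once for the whole session."""
    classifiers, splits = sp.train_all(
        tiny_labeled, tiny_normalized, grids=FAST_GRIDS, cv_folds=4, seed=3
    )
    return classifiers, splits


@pytest.fixture(scope="session")
def tiny_table(tiny_trained, tiny_normalized, tiny_labeled):
    classifiers, _ = tiny_trained
    return sp.predict_all(
        classifiers, tiny_normalized,
        exclude=tiny_labeled.positives | tiny_labeled.negatives,
    )
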