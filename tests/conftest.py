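import numpy as np
import pytest

from tolrad.annotations_io import build_frequency_table
from tolrad.classifier import train
from tolrad.synthetic import PlantedCohortSpec, generate_cohort

PLANTED = ["PF77001", "PF77002", "PF77003", "PF77004"]


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted-signal cohort shared across module tests."""
    spec = PlantedCohortSpec(
        n_per_class=10,
        n_noise_domains=30,
        total_instances_range=(1500, 2500),
        seed=11,
    )
    sets, labels, ledger = generate_cohort(spec)
    return sets, labels, ledger


@pytest.fixture(scope="session")
def small_labels_vector(small_cohort):
    sets, labels, _ = small_cohort
    return np.array([labels[s.genome_id] for s in sets])


@pytest.fixture(scope="session")
def planted_table(small_cohort):
    sets, _, _ = small_cohort
    return build_frequency_table(sets, domains=PLANTED)


@pytest.fixture(scope="session")
def trained_model(planted_table, small_labels_vector):
    return train(planted_table, small_labels_vector, cv_folds=5, n_trees=200, seed=11)
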