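import numpy as np
import pandas as pd
import pytest

import phenolink as pl
from phenolink import io as plio


@pytest.fixture(scope="session")
def default_config():
    """The standard fixed-seed synthetic world used by the end-to-end tests."""
    return pl.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    return pl.generate_dataset(default_config)


@pytest.fixture(scope="session")
def imputed(dataset):
    """The standard matrix after mean imputation (complete, no NaN)."""
    return plio.impute_population_mean(dataset["matrix"], scope="per_condition")


@pytest.fixture(scope="session")
def union_labels(dataset, imputed):
    return pl.coannotation_labels(
        imputed.strain_ids, dataset["annotation_sets"], mode="union"
    )


@pytest.fixture
def small_config():
    """A fast configuration for pipeline-level tests."""
    return pl.SyntheticConfig(
        n_strains=60, n_stresses=15, reps_per_stress=2, n_modules=4,
        module_size_range=(3, 4), n_auxotrophs=6, n_minimal_conditions=4,
        seed=7,
    )


def make_matrix(values, strains=None, conditions=None):
    values = np.asarray(values, dtype=float)
    strains = strains or [f"g{i+1}" for i in range(values.shape[0])]
    conditions = conditions or [f"c{j+1}" for j in range(values.shape[1])]
    return pl.FitnessMatrix(pd.DataFrame(values, index=strains, columns=conditions))


@pytest.fixture
def matrix_factory():
    return make_matrix
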