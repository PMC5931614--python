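import numpy as np
import pytest

from emps import (LangevinConfig, generate_dataset, reference_circuits)


@pytest.fixture(scope="session")
def three_gene_truth():
    return reference_circuits()["three_gene"]


@pytest.fixture(scope="session")
def two_gene_truth():
    return reference_circuits()["two_gene"]


@pytest.fixture(scope="session")
def small_three_gene_data(three_gene_truth):
    """Small 3-gene dataset (4 train + 2 test cells) for fast tests."""
    cfg = LangevinConfig(n_train=4, n_test=2, seed=101)
    return generate_dataset(three_gene_truth, cfg)


@pytest.fixture(scope="session")
def full_three_gene_data(three_gene_truth):
    """Full-size dataset at the study conditions (10 + 10 cells, 50 points)."""
    cfg = LangevinConfig(seed=2024)
    return generate_dataset(three_gene_truth, cfg)
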