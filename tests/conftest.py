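import numpy as np
import pandas as pd
import pytest

from endoseq import EndotypeModel
from endoseq.endotype import EndotypeAssignment
from endoseq.io import CountMatrix
from endoseq.preprocess import VstMatrix
from endoseq.simulate import SimulationConfig, simulate

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic discovery cohort (13 A / 14 B / 3 other)."""
    return simulate(SimulationConfig(), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Full pipeline fit on the default cohort."""
    cm, samples, _, _ = default_cohort
    return EndotypeModel(cm, samples).fit()


@pytest.fixture(scope="session")
def validation_cohort(default_cohort):
    """Second cohort drawn from the same generative truth (new seed)."""
    _, _, _, truth = default_cohort
    return simulate(SimulationConfig(), seed=77, truth=truth)


def make_count_matrix(values, gene_ids=None, sample_ids=None) -> CountMatrix:
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return CountMatrix(gene_ids, sample_ids, values)


def make_vst(values, gene_ids=None, sample_ids=None) -> VstMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return VstMatrix(gene_ids, sample_ids, values)


def make_assignment(labels: dict | pd.Series) -> EndotypeAssignment:
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    return EndotypeAssignment(labels=labels.astype(str))


def two_group_assignment(sample_ids, n_a):
    labels = ["A"] * n_a + ["B"] * (len(sample_ids) - n_a)
    return make_assignment(pd.Series(labels, index=list(sample_ids)))
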