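import numpy as np
import pytest

from thermoclass.dataset import LabeledExample, assign_threshold_labels
from thermoclass.simulate import SimulationConfig, simulate_dataset
from thermoclass.thermo_labels import DEFAULT_THRESHOLDS


def examples_from(dataset, thresholds=DEFAULT_THRESHOLDS):
    """Join a synthetic dataset into labelled examples."""
    out = []
    for rec in dataset.records:
        ogt = dataset.annotations[rec.organism_key]
        out.append(
            LabeledExample(
                sequence_id=rec.id,
                embedding=dataset.embeddings[rec.id],
                labels=assign_threshold_labels(ogt, thresholds),
                growth_temperature=ogt,
            )
        )
    return out


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable synthetic data: low noise relative to the signal."""
    cfg = SimulationConfig(n_organisms=2500, dim=64, beta=3.0, sigma=0.1, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_examples(separable_dataset):
    return examples_from(separable_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
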