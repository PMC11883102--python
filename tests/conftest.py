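import numpy as np
import pytest

from mtamo.io_data import standardize
from mtamo.model import HyperParams, train
from mtamo.synthetic import SyntheticSpec, generate


def standardized(dataset):
    for label in dataset.labels:
        dataset.layers[label] = standardize(dataset.layers[label])
    return dataset


@pytest.fixture
def tiny_dataset():
    """Three layers, 8/6/7 genes, 12 samples; standardized."""
    spec = SyntheticSpec(
        n_samples=12,
        genes_per_layer={"mRNA": 8, "meth": 6, "SNV": 7},
        n_signal_genes=3,
        n_signal_modules=2,
        seed=42,
    )
    dataset, truth = generate(spec)
    return standardized(dataset), truth


@pytest.fixture(scope="session")
def small_trained():
    """A quickly trained model on a small signal-rich dataset (shared)."""
    spec = SyntheticSpec(
        n_samples=120,
        genes_per_layer={"mRNA": 60, "meth": 60, "SNV": 60},
        n_signal_genes=12,
        n_signal_modules=2,
        effect_size=1.0,
        noise_sd=0.5,
        cross_omics_correlation=0.6,
        seed=7,
    )
    dataset, truth = generate(spec)
    for label in dataset.labels:
        dataset.layers[label] = standardize(dataset.layers[label])
    hyper = HyperParams(N=4, D=4, epochs=60, seed=11)
    params, report = train(dataset, hyper)
    return params, report, dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
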