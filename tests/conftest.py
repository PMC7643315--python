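import numpy as np
import pytest

from deeplrp import MLPConfig, train
from deeplrp.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_data():
    """Small planted dataset: 300 samples x 60 probes, 6 terms of 10 genes,
    effect size 3 on one term per class."""
    spec = SyntheticSpec(n_samples=300, n_probes=60, n_terms=6,
                         genes_per_term=10, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_data):
    """A small net trained on the tiny planted dataset."""
    cfg = MLPConfig(layer_sizes=[60, 16, 8, 4, 2], p_drop=0.1, l1=1e-4,
                    lr=1e-3, batch_size=32, max_epochs=40,
                    early_stop_patience=8, seed=5)
    net, log = train(tiny_data.dataset, cfg)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
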