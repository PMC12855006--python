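import numpy as np
import pandas as pd
import pytest

from aekit.datamodel import AnnotationTable, ModalityBlock, config_from_dict
from aekit.synthetic_data import GeneratorSpec, make_multiomics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return config_from_dict({
        "architecture": "varix", "latent_dim": 2, "beta_final": 0.01,
        "epochs": 10, "batch_size": 16, "learning_rate": 1e-3, "seed": 0,
    })


@pytest.fixture
def tiny_blocks():
    ids_a = ["A", "B", "C"]
    ids_b = ["B", "C", "D"]
    block_a = ModalityBlock("x", "numeric", np.arange(6.0).reshape(3, 2),
                            ["f1", "f2"], ids_a)
    block_b = ModalityBlock("y", "numeric", np.arange(9.0).reshape(3, 3),
                            ["g1", "g2", "g3"], ids_b)
    table = pd.DataFrame({"label": ["u", "v", "w", "u"]},
                         index=["A", "B", "C", "D"])
    annotations = AnnotationTable(table=table, task_specs=[])
    return block_a, block_b, annotations


@pytest.fixture(scope="session")
def factor_dataset():
    spec = GeneratorSpec(n_samples=120, k_true=2,
                         feature_counts={"rna": 40, "prot": 24},
                         noise_sd=0.05, n_classes=2, class_separation=3.0,
                         seed=7)
    dataset, truth = make_multiomics(spec)
    return spec, dataset, truth
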