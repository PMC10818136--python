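import numpy as np
import pytest

from sagdti import ModelConfig, SyntheticSpec, generate_dataset
from sagdti.drug_encoder import DrugEmbeddingConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def drug_cfg():
    """A small drug-embedding configuration shared across tests."""
    return DrugEmbeddingConfig(max_len=20, hidden_dim=8, clip=3)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A miniature mixed-signal benchmark (fast to generate, reused widely)."""
    return generate_dataset(SyntheticSpec(n_drugs=30, n_targets=12, n_pairs=120, seed=11))


@pytest.fixture(scope="session")
def tiny_model_config():
    """Model sized for unit tests (seconds, not minutes)."""
    return ModelConfig(
        drug_max_len=36, hidden_dim=16, drug_heads=2, clip=4,
        protein_max_tokens=24, protein_heads=2, max_sites=2, max_atoms_per_site=12,
        encoder_depth=1, fnn_mult=2, n_filters=3, gat_hidden=8, gat_heads=2,
        gat_layers=2, head_filters=3, head_fnn=(16, 8),
    )


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
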