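import numpy as np
import pytest

import phyloeco as pe


@pytest.fixture(scope="session")
def default_registry():
    """Default 58-feature registry and its scale lookup."""
    return pe.default_feature_definitions()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One seeded default synthetic dataset: 3 archetypes x 20 species."""
    proteomes, truth, phenotypes = pe.simulate_dataset(None, 20, seed=1)
    return proteomes, truth, phenotypes


@pytest.fixture(scope="session")
def synthetic_features(synthetic_dataset, default_registry):
    proteomes, truth, phenotypes = synthetic_dataset
    defs, scales = default_registry
    matrix = pe.build_feature_matrix(proteomes, defs, scales)
    return matrix, truth, phenotypes


@pytest.fixture(scope="session")
def pipeline_result(synthetic_features):
    matrix, truth, phenotypes = synthetic_features
    result = pe.run_pipeline(feature_matrix=matrix, seed=1)
    return result, truth, phenotypes


def random_distance_matrix(n, seed, metric="random"):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 5))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    ids = tuple(f"t{i}" for i in range(n))
    return pe.DistanceMatrix(ids, d, metric)
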