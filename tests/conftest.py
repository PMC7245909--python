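import numpy as np
import pandas as pd
import pytest

from organmap import MetaboliteMatrix, SimulationConfig


def make_metabolite_matrix(values: np.ndarray, n_con: int, n_rpa: int,
                           feature_ids=None) -> MetaboliteMatrix:
    """Wrap a raw features x samples array into a labeled MetaboliteMatrix."""
    n_feat = values.shape[0]
    feature_ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = [f"s{i}" for i in range(n_con + n_rpa)]
    labels = ["CON"] * n_con + ["RPA"] * n_rpa
    return MetaboliteMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        group_labels=pd.Series(labels, index=sample_ids),
    )


@pytest.fixture(scope="session")
def separated_clusters() -> MetaboliteMatrix:
    """Two perfectly separated Gaussian clusters, 12 samples per group."""
    rng = np.random.default_rng(0)
    n = 12
    x = np.vstack([rng.normal(0, 1, (n, 30)), rng.normal(8, 1, (n, 30))]).T
    return make_metabolite_matrix(x, n, n)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)
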