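import numpy as np
import pandas as pd
import pytest

from cellqc.features import FeatureTable, NormalizedMatrix, extract_features
from cellqc.synthetic import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic dataset: 200 cells, 80/20 HIGH/LOW."""
    return simulate_dataset(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def sim_features(sim_default):
    matrix, stats, sets, labels = sim_default
    return extract_features(matrix, stats, sets), labels


def make_feature_table(X: np.ndarray, names=None, cells=None) -> FeatureTable:
    n_cells, n_feat = X.shape
    names = names or [f"f{i}" for i in range(n_feat)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    values = pd.DataFrame(X, index=cells, columns=names)
    return FeatureTable(
        values,
        pd.Series("technical", index=values.columns),
        pd.Series(False, index=values.columns),
    )


def make_normalized(values: np.ndarray, ercc_mask=None) -> NormalizedMatrix:
    n_genes, n_cells = values.shape
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"c{i}" for i in range(n_cells)],
    )
    mask = np.zeros(n_genes, bool) if ercc_mask is None else np.asarray(ercc_mask)
    return NormalizedMatrix(df, mask)
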