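import numpy as np
import pandas as pd
import pytest

from chemoscreen.core import (
    DrugResponseTable,
    ExpressionMatrix,
    ResponseMetric,
    ScreenDataset,
)


def make_dataset(
    expr_values,
    resp_values,
    dataset_id="DS",
    genes=None,
    samples=None,
    drugs=None,
    metric=ResponseMetric.AUC,
    lineage=None,
):
    """Build a ScreenDataset from raw arrays (samples x genes, samples x drugs)."""
    expr_values = np.asarray(expr_values, dtype=float)
    resp_values = np.asarray(resp_values, dtype=float)
    n_samples, n_genes = expr_values.shape
    n_drugs = resp_values.shape[1]
    genes = genes or [f"G{i}" for i in range(n_genes)]
    samples = samples or [f"CL{i}" for i in range(n_samples)]
    drugs = drugs or [f"D{i}" for i in range(n_drugs)]
    expr = ExpressionMatrix(
        dataset_id=dataset_id,
        data=pd.DataFrame(expr_values, index=samples, columns=genes),
    )
    resp = DrugResponseTable(
        dataset_id=dataset_id,
        metric=metric,
        data=pd.DataFrame(resp_values, index=samples, columns=drugs),
    )
    return ScreenDataset(expression=expr, response=resp, lineage=lineage)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def toy_dataset(rng):
    """20 genes x 4 drugs x 15 lines of independent noise."""
    return make_dataset(
        rng.normal(size=(15, 20)), rng.normal(size=(15, 4)), dataset_id="TOY"
    )
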