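import numpy as np
import pandas as pd
import pytest

from lfqstats.dataset import DataSet


def make_dataset(
    values,
    groups=None,
    sample_ids=None,
    protein_ids=None,
    covariates=None,
    contaminant=None,
):
    """Build a DataSet directly from a samples x proteins array."""
    values = np.asarray(values, dtype=float)
    n_s, n_p = values.shape
    sample_ids = sample_ids or [f"S{i+1}" for i in range(n_s)]
    protein_ids = protein_ids or [f"P{j+1}" for j in range(n_p)]
    matrix = pd.DataFrame(values, index=sample_ids, columns=protein_ids)
    matrix.index.name = "sample_id"
    meta = {"group": groups if groups is not None else ["A"] * n_s}
    if covariates:
        meta.update(covariates)
    metadata = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    cont = pd.Series(
        contaminant if contaminant is not None else [False] * n_p,
        index=protein_ids,
        name="contaminant",
    )
    return DataSet(
        matrix=matrix,
        metadata=metadata,
        raw=matrix.copy(),
        log=(),
        annotations=pd.DataFrame(index=matrix.columns),
        contaminant=cont,
    )


@pytest.fixture
def toy_dataset():
    """4 samples (2 groups) x 5 proteins, complete, log2-ish scale."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(20, 30, size=(4, 5))
    return make_dataset(vals, groups=["A", "A", "B", "B"])
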