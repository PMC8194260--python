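import numpy as np
import pandas as pd
import pytest

from megadeg.io import DatasetMeta, ExpressionDataset


@pytest.fixture
def make_dataset():
    """Factory building a small ExpressionDataset from per-gene value lists.

    ``values`` maps gene -> list of floats ordered control-first; the split
    is given by n_control.
    """

    def _make(values: dict, n_control: int, dataset_id: str = "D1", meta=None):
        n_total = len(next(iter(values.values())))
        cols = [f"c{i}" for i in range(n_control)] + [
            f"t{i}" for i in range(n_total - n_control)
        ]
        mat = pd.DataFrame.from_dict(values, orient="index", columns=cols).astype(float)
        mat.index.name = "gene_id"
        groups = {c: ("control" if c.startswith("c") else "case") for c in cols}
        if meta is None:
            meta = DatasetMeta(
                dataset_id=dataset_id,
                n_control=n_control,
                n_case=n_total - n_control,
                country="United States",
                study_age=5,
                organism="Homo sapiens",
                platform="GPL570",
                data_type="microarray expression profiling",
                comparison="AD vs healthy controls",
            )
        return ExpressionDataset(dataset_id, mat, groups, meta)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
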