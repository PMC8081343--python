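import numpy as np
import pandas as pd
import pytest

import kernelstack as ks
from kernelstack.datasets import map_feature_set
from kernelstack.forest import ForestParams, fit_forest


@pytest.fixture(scope="session")
def small_dataset():
    """40 samples, 6 sets (1 planted), 2 data types -- shared read-only fixture."""
    ds, coll, truth = ks.generate(
        n_samples=40, n_sets=6, set_size_range=(5, 8), n_causal=4, seed=11
    )
    return ds, coll, truth


@pytest.fixture(scope="session")
def small_forest(small_dataset):
    ds, coll, truth = small_dataset
    af = map_feature_set("planted_set", coll.sets["planted_set"], ds)
    return fit_forest(af, ds, ForestParams(n_trees=80, seed=5))


@pytest.fixture(scope="session")
def tiny_tables():
    """Two aligned 5-sample tables plus binary labels, for assembly tests."""
    ids = [f"P{i}" for i in range(5)]
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(
        rng.standard_normal((5, 3)), index=ids, columns=["MLH1", "TP53", "BRCA1"]
    )
    cnv = pd.DataFrame(
        rng.standard_normal((5, 2)), index=ids, columns=["MLH1", "TP53"]
    )
    labels = pd.Series([0, 1, 0, 1, 1], index=ids)
    return {"expr": expr, "cnv": cnv}, labels
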