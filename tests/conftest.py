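import numpy as np
import pandas as pd
import pytest

import concordx as cx


@pytest.fixture(scope="session")
def small_study() -> cx.PairedStudy:
    """A compact paired study reused by read-only tests."""
    cfg = cx.default_config(
        "hga_vs_agasac",
        n_genes=1500,
        n_endogenous=300,
        n_housekeeping=15,
        n_missing=4,
        seed=42,
    )
    return cx.simulate_paired_study(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_counts() -> cx.CountMatrix:
    frame = pd.DataFrame(
        {
            "s1": [10, 20, 30, 5, 0],
            "s2": [12, 18, 33, 4, 1],
            "s3": [9, 25, 28, 6, 2],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    return cx.CountMatrix(frame)
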