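import numpy as np
import pandas as pd
import pytest

from loadnet.containers import ExpressionMatrix
from loadnet.sim import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Reduced cohort used by most integration-style unit tests."""
    return SimConfig(
        n_genes=600,
        module_sizes=(80, 60, 50),
        n_variants=100,
        n_causal_eqtl=5,
        seed=2,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate_bundle(small_cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard synthetic cohort: 2,000 genes x 60 samples x 500 variants."""
    return simulate_bundle(SimConfig(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def expr_from_array(arr, transformed=False, prefix="G") -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"{prefix}{i:03d}" for i in range(arr.shape[0])],
            columns=[f"S{j:03d}" for j in range(arr.shape[1])],
        ),
        transformed=transformed,
    )
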