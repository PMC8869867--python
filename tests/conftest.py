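import numpy as np
import pandas as pd
import pytest

from proteaphagy import SynthCountConfig, generate_tube_counts
from proteaphagy.quant import SpectralCountMatrix, make_sample_metadata


@pytest.fixture
def small_matrix() -> SpectralCountMatrix:
    """3 proteins x (2 conditions x 2 replicates + 2 controls), raw counts."""
    samples = make_sample_metadata({"A": 2, "B": 2}, n_controls=2)
    data = pd.DataFrame(
        {
            "A_r1": [10, 3, 0],
            "A_r2": [12, 2, 1],
            "B_r1": [40, 4, 0],
            "B_r2": [44, 3, 2],
            "control_r1": [2, 2, 0],
            "control_r2": [3, 3, 0],
        },
        index=["P1", "P2", "P3"],
        dtype=float,
    )
    return SpectralCountMatrix(data=data, samples=samples, stage="raw")


@pytest.fixture
def default_counts():
    """One generated TUBE experiment under the default study conditions."""
    return generate_tube_counts(SynthCountConfig(seed=7))


def random_matrix(rng: np.random.Generator, n: int = 20, k: int = 4) -> SpectralCountMatrix:
    """Random log2-stage matrix over two conditions of k/2 replicates each."""
    assert k % 2 == 0
    samples = make_sample_metadata({"A": k // 2, "B": k // 2})
    data = pd.DataFrame(
        rng.uniform(0, 10, size=(n, k)),
        index=[f"P{i}" for i in range(n)],
        columns=list(samples.index),
    )
    return SpectralCountMatrix(data=data, samples=samples, stage="log2")
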