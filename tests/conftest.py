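import numpy as np
import pandas as pd
import pytest

from mfsyn.io import LOC_COLUMNS


def make_table(rng, n=100, fov_id="fov0", n_traces=20):
    """Random but valid localization table for plumbing tests."""
    tids = rng.integers(0, n_traces, n)
    return pd.DataFrame({
        "fov_id": fov_id,
        "tid": np.sort(tids).astype(np.int64),
        "t_s": np.arange(n) * 1e-3,
        "x_nm": rng.normal(0, 100, n),
        "y_nm": rng.normal(0, 100, n),
        "z_nm": rng.normal(0, 50, n),
        "efo_hz": rng.uniform(100_000, 300_000, n),
        "cfr": rng.uniform(0, 0.9, n),
        "dcr": rng.uniform(0, 1, n),
    })[LOC_COLUMNS]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
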