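import numpy as np
import pytest

import nirscal as nc


@pytest.fixture(scope="session")
def leaf_dataset():
    """Full-size leaf-preset dataset with a 294/75 split (session-wide)."""
    cfg = nc.leaf_config(seed=7)
    ds = nc.generate_dataset(cfg)
    return nc.split_calibration_validation(ds, 75 / 369, seed=8)


@pytest.fixture(scope="session")
def small_dataset():
    """Small leaf-like dataset for cheap end-to-end tests."""
    cfg = nc.leaf_config(n_samples=80, seed=3)
    return nc.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_spectra(rng, n=8, p=200, ids=None):
    wl = 400.0 + 0.5 * np.arange(p)
    ids = ids or [f"s{i}" for i in range(n)]
    return nc.SpectraSet(ids, wl, rng.normal(size=(n, p)))
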