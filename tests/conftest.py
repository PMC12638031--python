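import warnings

import numpy as np
import pytest

import spotmap
from spotmap.pipeline import RunConfig, run_map


@pytest.fixture(scope="session")
def small_sc():
    """K=3 reference with planted markers; 100 cells/type keeps the
    variance filter out of the chi-square noise regime."""
    sc, planted = spotmap.simulate_sc(K=3, G=300, cells_per_type=100,
                                      markers_per_type=20, seed=7)
    return sc, planted


@pytest.fixture(scope="session")
def small_st(small_sc):
    sc, _ = small_sc
    st, truth = spotmap.simulate_st(sc, n_spots=144, lam=3, seed=8)
    return st, truth


@pytest.fixture(scope="session")
def pipeline_run(small_sc, small_st):
    """One small end-to-end mapping shared by integration-level tests."""
    sc, _ = small_sc
    st, _ = small_st
    cfg = RunConfig(seed=9, markers_n_top=20, cellcount_n_max=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = run_map(sc, st, cfg)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
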