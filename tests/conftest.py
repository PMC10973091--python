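import numpy as np
import pytest

from grinvar import SimulationConfig, get_preset, load_assay_summary


@pytest.fixture(scope="session")
def summary():
    return load_assay_summary()


@pytest.fixture()
def wt2a():
    return get_preset("WT-GluN1/2A")


@pytest.fixture()
def wt2b():
    return get_preset("WT-GluN1/2B")


@pytest.fixture()
def wt2a_clean():
    """WT GluN1/2A preset with every noise source disabled."""
    return get_preset("WT-GluN1/2A", noise_cv=0.0, cr_noise_cv=0.0,
                      baseline_sd=0.0, tau_cell_cv=0.0, iv_noise_sd=0.0)


@pytest.fixture()
def sim():
    return SimulationConfig(seed=7, n_cells=4, sample_interval_ms=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
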