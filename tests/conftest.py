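import numpy as np
import pandas as pd
import pytest

from ucrpanel import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A desk-scale study: 60 UCRs (120 probes), reference sample sizes."""
    return SyntheticConfig(n_ucrs=60, n_de=10, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate(small_config)


@pytest.fixture()
def tiny_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(5)
    probes = ["uc.1+", "uc.1+A", "uc.2+"]
    samples = ["N01", "N02", "L01", "L02"]
    return pd.DataFrame(rng.normal(8, 1, size=(3, 4)),
                        index=pd.Index(probes, name="probe_id"),
                        columns=samples)
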