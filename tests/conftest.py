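import numpy as np
import pytest

from mtmat import SyntheticConfig, generate_synthetic, log_cpm


@pytest.fixture(scope="session")
def small_study():
    """Default-scale synthetic study: 50 subjects x 3 visits, 10 genera plus
    background flora, ~64% zeros."""
    return generate_synthetic(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_logcpm(small_study):
    table, _, _, _ = small_study
    return log_cpm(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
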