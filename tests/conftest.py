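import numpy as np
import pytest

import mrtdpred as mp


@pytest.fixture(scope="session")
def arv():
    return mp.load_arv_mrtd()


@pytest.fixture(scope="session")
def arv_train(arv):
    return mp.subset_frame(arv, "train")


@pytest.fixture(scope="session")
def arv_test(arv):
    return mp.subset_frame(arv, "test")


@pytest.fixture(scope="session")
def mlr():
    return mp.published_mlr()


@pytest.fixture(scope="session")
def net():
    return mp.published_network()


@pytest.fixture(scope="session")
def random_descriptor_matrix():
    """Seeded random descriptor rows spanning realistic ranges."""

    def make(n: int, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return np.column_stack(
            [
                rng.uniform(0.01, 14.0, n),   # oxid_hl, days
                rng.uniform(0.0, 1.0, n),     # p_bd
                rng.uniform(-5.0, 1.0, n),    # log_bio_hl
                rng.uniform(-3.0, 6.0, n),    # alogp
                rng.uniform(0.0001, 41.0, n),  # asol, g/L
                rng.uniform(120.0, 730.0, n),  # mw, Da
            ]
        )

    return make
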