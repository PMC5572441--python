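import warnings

import numpy as np
import pytest

from binam import DataParameters, generate_dataset, train


@pytest.fixture(autouse=True)
def _quiet_saturation_warning():
    # the small workloads used in tests trip the random-baseline guard by design
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*I_rand.*")
        warnings.filterwarnings("ignore", message=".*not meaningful.*")
        yield


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(DataParameters(m=16, n=16, c=4, d=4, N=20), seed=1)


@pytest.fixture(scope="session")
def small_memory(small_dataset):
    return train(small_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
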