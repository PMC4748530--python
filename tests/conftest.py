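import numpy as np
import pandas as pd
import pytest

import aromaflux as af


@pytest.fixture(scope="session")
def noiseless_scenario():
    return af.default_scenario(seed=11, noise=False)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_scenario):
    return af.simulate_fermentation(noiseless_scenario)


@pytest.fixture(scope="session")
def noisy_dataset():
    return af.simulate_fermentation(af.default_scenario(seed=23, noise=True))


@pytest.fixture(scope="session")
def partition_frame(noiseless_scenario):
    return pd.DataFrame(
        [
            {"compound": c, "F1": p.F1, "F2": p.F2, "F3": p.F3, "F4": p.F4}
            for c, p in noiseless_scenario.partition_params.items()
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
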