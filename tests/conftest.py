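import numpy as np
import pytest

import bnwhatif as bw


@pytest.fixture(scope="session")
def toy3_net():
    return bw.toy3()


@pytest.fixture(scope="session")
def survey11_net():
    return bw.survey11(0)


@pytest.fixture(scope="session")
def chart():
    return bw.GrowthChartTable.load_default()


@pytest.fixture(scope="session")
def naive4_with_noise():
    """naive-Bayes truth plus two independent noise columns, n=5000."""
    truth = bw.naive4(3)
    data = bw.ancestral_sample(truth, 5000, 17)
    rng = np.random.default_rng(99)
    data["N1"] = rng.choice(["u", "v", "w"], size=len(data))
    data["N2"] = rng.choice(["u", "v"], size=len(data))
    return truth, data


def random_net_and_row(seed, n_nodes=6):
    """A random small network plus one positive-probability joint sample."""
    net = bw.random_network(n_nodes, seed=seed)
    row = bw.ancestral_sample(net, 1, seed + 1).iloc[0]
    return net, row
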