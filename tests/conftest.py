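import numpy as np
import pytest
from hypothesis import settings

import symptomnet as sn
from symptomnet.glasso import PartialCorrelationNetwork

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_network():
    """The default eight-edge ground truth over the 14 nodes."""
    return sn.default_network()


@pytest.fixture(scope="session")
def metas():
    return sn.default_variables()


def make_network(weights, labels=None, binary=()):
    """Wrap a raw symmetric weight matrix as a PartialCorrelationNetwork."""
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    if labels is None:
        labels = tuple(f"v{i}" for i in range(p))
    sign = np.empty((p, p), dtype=object)
    sign[:] = ""
    for i in range(p):
        for j in range(i + 1, p):
            if weights[i, j] != 0.0:
                if labels[i] in binary or labels[j] in binary:
                    cls = "unsigned-categorical"
                else:
                    cls = "positive" if weights[i, j] > 0 else "negative"
                sign[i, j] = sign[j, i] = cls
    return PartialCorrelationNetwork(tuple(labels), weights, sign, 0.0, float("nan"))


@pytest.fixture(scope="session")
def chain3():
    """3-node chain ground truth: 0–1 at 0.4, 1–2 at 0.3, no 0–2 edge."""
    return sn.build_ground_truth(
        [("a", "b", 0.4), ("b", "c", 0.3)], ["a", "b", "c"]
    )


@pytest.fixture(scope="session")
def continuous_cohort_20k(planted_network, metas):
    """Large continuous-mode cohort used by recovery checks."""
    latent = sn.sample_latent(planted_network, 20_000, seed=20_220_624)
    return sn.realize_cohort(latent, metas, mode="continuous")
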