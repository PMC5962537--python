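import numpy as np
import pytest

from wristml import simulate as sim


@pytest.fixture(scope="session")
def profiles():
    return sim.default_profiles()


@pytest.fixture(scope="session")
def chain():
    return sim.default_chain()


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 1 h on the fast-mixing chain: quick end-to-end LOSO."""
    return sim.simulate_cohort(4, 1.0, chain=sim.demo_chain(), seed=11)


def gaussian_fixture(n_per_class, means, sd=1.0, n_features=8, seed=0):
    """Well-separated Gaussian classes as a (features, labels) pair.

    ``means`` maps class name -> scalar centre applied to every feature.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    for (cls, mu), n in zip(means.items(), n_per_class):
        X.append(mu + sd * rng.standard_normal((n, n_features)))
        y += [cls] * n
    return np.vstack(X), np.array(y, dtype=object)
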