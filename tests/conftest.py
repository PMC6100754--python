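import numpy as np
import pytest

import ketosynth as ks


@pytest.fixture(scope="session")
def table1():
    return ks.load_table1()


@pytest.fixture(scope="session")
def table2():
    return ks.load_table2()


@pytest.fixture(scope="session")
def paper_fits(table2):
    """Default-length fits of the four fully specified priors, shared
    across tests (each takes ~15 s; fitting once keeps the suite fast)."""
    fits = {}
    for k, name in enumerate(["SP1", "SP2", "FSP", "EP_MP2"]):
        fits[name] = ks.run_mcmc(
            table2, ks.make_prior(name), ks.MCMCConfig(seed=11 + k)
        )
    return fits


def random_arm(rng: np.random.Generator, n: int | None = None, censor=0.3):
    """A random censored survival arm with at least one event."""
    n = n or int(rng.integers(4, 40))
    t = np.round(rng.exponential(10.0, n), 3) + 1e-3
    e = (rng.random(n) > censor).astype(int)
    if e.sum() == 0:
        e[rng.integers(n)] = 1
    return ks.SurvivalArm.from_arrays("random", t, e)
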