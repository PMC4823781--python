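import numpy as np
import pytest

from nucdeform import EnergyModelConfig, load_default_table, packaged_benchmark


def enumerate_hard_rods(weights, footprint):
    """Brute-force start probabilities over all non-overlapping configurations."""
    n = len(weights)
    total = 0.0
    per_start = np.zeros(n)

    def configs(start):
        if start >= n:
            yield ()
            return
        for rest in configs(start + 1):
            yield rest
        for rest in configs(start + footprint):
            yield (start,) + rest

    for config in configs(0):
        w = np.prod([weights[i] for i in config]) if config else 1.0
        total += w
        for i in config:
            per_start[i] += w
    return per_start / total


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def geom(table):
    return table.geometry_arrays()


@pytest.fixture(scope="session")
def cfg129():
    return EnergyModelConfig()


@pytest.fixture(scope="session")
def benchmark():
    return packaged_benchmark()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_window(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def make_window(rng):
    def _make(length=129):
        return random_window(rng, length)
    return _make
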