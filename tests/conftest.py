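import numpy as np
import pytest

import netchrono as nc


@pytest.fixture(scope="session")
def ba_small():
    """BA network small enough for exact all-pairs work."""
    return nc.generate_ba(nc.GeneratorConfig("ba", 60, 2, seed=7))


@pytest.fixture(scope="session")
def ba_500():
    return nc.generate_ba(nc.GeneratorConfig("ba", 500, 2, seed=11))


@pytest.fixture(scope="session")
def sbm_two_block():
    """Planted two-community network with within-block bias, grown edge by
    edge so a ground-truth arrival order exists; block labels attached."""
    rng = np.random.default_rng(42)
    n = 60
    block = {i: ("A" if i < n // 2 else "B") for i in range(n)}
    edges = []
    seen = set()
    while len(edges) < 240:
        u = int(rng.integers(n))
        same = rng.random() < 0.9
        pool = [w for w in range(n) if w != u and (block[w] == block[u]) == same]
        v = int(rng.choice(pool))
        key = (min(u, v), max(u, v))
        if key in seen:
            continue
        seen.add(key)
        edges.append(key)
    net = nc.TemporalNetwork(edges, node_labels=block)
    return net


@pytest.fixture(scope="session")
def path4():
    return nc.TemporalNetwork([(0, 1), (1, 2), (2, 3)])


@pytest.fixture(scope="session")
def triangle():
    return nc.TemporalNetwork([(0, 1), (1, 2), (0, 2)])
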