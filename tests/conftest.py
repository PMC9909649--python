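import numpy as np
import pytest

from transfernet import (
    GeneratorConfig,
    Hospital,
    TransferNetwork,
    build_network,
    simulate,
)

SIM_SEED = 11


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic dataset shared across tests."""
    cfg = GeneratorConfig()
    registry, records, ledger = simulate(cfg, seed=SIM_SEED)
    return cfg, registry, records, ledger


@pytest.fixture(scope="session")
def default_net(default_sim):
    _, registry, records, _ = default_sim
    return build_network(records, registry)


def make_network(arcs, extra_nodes=(), registry=None):
    """Build a TransferNetwork from an arc-weight mapping plus optional
    isolate node ids."""
    ids = sorted({v for pair in arcs for v in pair} | set(extra_nodes))
    nodes = {
        v: (registry[v] if registry else Hospital(hospital_id=v)) for v in ids
    }
    return TransferNetwork(nodes=nodes, arcs=dict(arcs))


def random_digraph(seed, n_min=4, n_max=10, p=None):
    """A random directed network (no self-loops), weights all 1."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.15, 0.55)) if p is None else p
    ids = [f"v{i}" for i in range(n)]
    arcs = {
        (a, b): 1
        for a in ids
        for b in ids
        if a != b and rng.random() < p
    }
    return make_network(arcs, extra_nodes=ids)
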