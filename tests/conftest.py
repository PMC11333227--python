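import numpy as np
import pytest

from spikefix import (FixedSpec, HomeostasisParams, LIFParams, RunConfig,
                      STDPParams)


@pytest.fixture(scope="session")
def spec16() -> FixedSpec:
    return FixedSpec.from_mode("fixed16")


@pytest.fixture(scope="session")
def specf() -> FixedSpec:
    return FixedSpec.from_mode("float")


@pytest.fixture(scope="session")
def lif() -> LIFParams:
    return LIFParams()


@pytest.fixture(scope="session")
def stdp() -> STDPParams:
    return STDPParams()


@pytest.fixture(scope="session")
def hom() -> HomeostasisParams:
    return HomeostasisParams()


@pytest.fixture()
def run16() -> RunConfig:
    return RunConfig.from_dict({"precision": "fixed16"})


@pytest.fixture()
def runf() -> RunConfig:
    return RunConfig.from_dict({"precision": "float"})


def random_reference_setup(seed: int, n_relay: int = 3, n_exc: int = 4,
                           n_inh: int = 2, n_out: int = 1,
                           n_static: int = 10, n_plastic: int = 8):
    """Build matched (layers, netlist) and reference-simulator inputs for a
    random small network (used by the engine/oracle equivalence tests)."""
    from spikefix.network import Connection, LayerSpec, Netlist

    rng = np.random.default_rng(seed)
    n = n_relay + n_exc + n_inh + n_out
    relay_ids = list(range(n_relay))
    internal = list(range(n_relay, n))
    exc_ids = list(range(n_relay, n_relay + n_exc))
    layers = [
        LayerSpec("input_pixel", n_relay, 1),
        LayerSpec("excitatory", n_exc, 2),
        LayerSpec("inhibitory", n_inh, 3),
        LayerSpec("output", n_out, 2),
    ]
    conns, seen = [], set()
    # plastic: excitatory, from relays onto excitatory-layer neurons
    while sum(c.plastic for c in conns) < n_plastic:
        pre = int(rng.integers(0, n_relay))
        post = int(rng.choice(exc_ids))
        if (pre, post) in seen:
            continue
        seen.add((pre, post))
        conns.append(Connection(pre, post, float(rng.uniform(0, 1)),
                                plastic=True))
    while len(conns) < n_plastic + n_static:
        pre = int(rng.integers(0, n))
        post = int(rng.choice(internal))
        if (pre, post) in seen:
            continue
        seen.add((pre, post))
        sign = "inhibitory" if rng.random() < 0.3 else "excitatory"
        conns.append(Connection(pre, post, float(rng.uniform(0.5, 6.0)),
                                sign=sign))
    net = Netlist(n_neurons=n, connections=conns)
    net.validate()
    return layers, net, relay_ids, exc_ids
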