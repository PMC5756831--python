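import numpy as np
import pytest

from channelweb import FlowNetwork, PlantedWebSpec, generate_planted_web


def make_net(ids, categories, F, biomass=None, imports=None, exports=None, respiration=None):
    """Small hand-built network; unspecified boundary flows are zero."""
    S = len(ids)
    z = np.zeros(S)
    return FlowNetwork(
        node_ids=tuple(ids),
        names=tuple(ids),
        category=tuple(categories),
        biomass=np.ones(S) if biomass is None else np.asarray(biomass, float),
        imports=z if imports is None else np.asarray(imports, float),
        exports=z if exports is None else np.asarray(exports, float),
        respiration=z if respiration is None else np.asarray(respiration, float),
        F=np.asarray(F, float),
    )


@pytest.fixture
def two_disjoint_links():
    """a->b and c->d, unit fluxes, no other structure."""
    F = np.zeros((4, 4))
    F[0, 1] = 1.0
    F[2, 3] = 1.0
    return make_net(
        "abcd",
        ["producer", "consumer", "producer", "consumer"],
        F,
        imports=[1, 0, 1, 0],
        exports=[0, 1, 0, 1],
    )


def planted(k=3, m=8, L=3, eps=0.0, seed=0, **kw):
    return generate_planted_web(
        PlantedWebSpec(n_channels=k, per_channel=m, levels=L, coupling=eps, seed=seed, **kw)
    )


def random_web(seed, cycles=True):
    """Random small web for oracle comparisons: planted base plus, optionally,
    a few weak consumer-to-consumer back-edges that create cycles."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 4))
    m = int(rng.integers(4, 9))
    net, _ = planted(k=k, m=m, L=3, eps=float(rng.uniform(0, 0.4)), seed=seed)
    if cycles:
        F = net.F.copy()
        consumers = np.nonzero(~net.basal_mask)[0]
        for _ in range(3):
            i, j = rng.choice(consumers, size=2, replace=False)
            F[i, j] += float(rng.uniform(0.01, 0.1))
        net = net.with_flows(F=F)
    return net
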