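"""Synthetic planted-channel food webs with known ground-truth compartments.

Each generated web consists of ``k`` energy channels: one basal node per
channel (detritus and producer alternating) feeding a layered stack of
consumers. Within-channel fluxes are lognormal, emulating the strongly
uneven link-weight distributions of empirical quantitative webs. A coupling
parameter ``eps`` reroutes that fraction of every consumer's diet to nodes
of foreign channels, moving the web continuously from perfectly
block-diagonal (eps = 0) to heavily entangled (eps -> 0.5).

Webs are balanced by construction: consumer intakes are generated top-down
so every node's intake covers the demand of its own consumers (with a
trophic transfer efficiency drawn in [0.2, 0.5]), and the surplus is split
between respiration and export. Basal nodes are fed by imports equal to
their demand. The generator therefore doubles as the balanced-input oracle
for the balancing and validation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .modularity import Partition
from .network_io import FlowNetwork


@dataclass(frozen=True)
class PlantedWebSpec:
    """Parameters of a planted-channel web.

    Attributes
    ----------
    n_channels
        Number of energy channels k (>= 1), each seeded by one basal node.
    per_channel
        Nodes per channel m (basal node included); m >= levels.
    levels
        Trophic levels per channel L (level 0 is the basal node); L >= 2.
    coupling
        Fraction eps in [0, 1] of each consumer's diet rerouted to
        lower-level nodes of foreign channels (ignored when k = 1).
    flux_sigma
        Sigma of the lognormal flux/intake draws.
    top_predator_coupling
        When true, top-level predators spread half of their diet evenly
        across foreign channels (mobile-predator coupling motif) regardless
        of ``coupling``.
    seed
        RNG seed; generation is deterministic given the spec.
    """

    n_channels: int = 3
    per_channel: int = 8
    levels: int = 3
    coupling: float = 0.05
    flux_sigma: float = 0.5
    top_predator_coupling: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise InputError("n_channels must be >= 1")
        if self.levels < 2:
            raise InputError("levels must be >= 2")
        if self.per_channel < self.levels:
            raise InputError("per_channel must be >= levels")
        if not 0.0 <= self.coupling <= 1.0:
            raise InputError("coupling must lie in [0, 1]")


def generate_planted_web(spec: PlantedWebSpec) -> tuple[FlowNetwork, Partition]:
    """Generate a balanced planted-channel web and its ground-truth partition."""
    rng = np.random.default_rng(spec.seed)
    k, m, L = spec.n_channels, spec.per_channel, spec.levels
    S = k * m

    node_ids: list[str] = []
    category: list[str] = []
    channel = np.empty(S, dtype=int)
    level = np.empty(S, dtype=int)
    # consumers are dealt round-robin over levels 1..L-1 so none is empty
    for c in range(k):
        for v in range(m):
            i = c * m + v
            node_ids.append(f"c{c}n{v}")
            channel[i] = c
            if v == 0:
                category.append("detritus" if c % 2 == 0 else "producer")
                level[i] = 0
            else:
                category.append("consumer")
                level[i] = 1 + (v - 1) % (L - 1)

    def nodes_at(chan: int, lev: int) -> np.ndarray:
        return np.nonzero((channel == chan) & (level == lev))[0]

    def foreign_at(chan: int, lev: int) -> np.ndarray:
        return np.nonzero((channel != chan) & (level == lev))[0]

    F = np.zeros((S, S))
    intake = np.zeros(S)
    # top-down: a consumer's intake must cover its consumers' demand
    for lev in range(L - 1, 0, -1):
        for i in np.nonzero(level == lev)[0]:
            demand = F[i, :].sum()
            if demand > 0:
                efficiency = rng.uniform(0.2, 0.5)
                T = demand / efficiency
            else:
                T = rng.lognormal(mean=0.0, sigma=spec.flux_sigma)
            intake[i] = T
            eps = spec.coupling
            if spec.top_predator_coupling and lev == L - 1:
                eps = 0.5
            home = nodes_at(channel[i], lev - 1)
            foreign = foreign_at(channel[i], lev - 1)
            if k == 1 or foreign.size == 0:
                eps = 0.0
            n_home = min(home.size, int(rng.integers(1, 3)))
            prey_home = rng.choice(home, size=n_home, replace=False)
            w = rng.lognormal(mean=0.0, sigma=spec.flux_sigma, size=n_home)
            F[prey_home, i] += (1.0 - eps) * T * w / w.sum()
            if eps > 0:
                n_f = min(foreign.size, int(rng.integers(1, 3)))
                prey_f = rng.choice(foreign, size=n_f, replace=False)
                wf = rng.lognormal(mean=0.0, sigma=spec.flux_sigma, size=n_f)
                F[prey_f, i] += eps * T * wf / wf.sum()

    imports = np.zeros(S)
    exports = np.zeros(S)
    respiration = np.zeros(S)
    biomass = np.zeros(S)
    for i in range(S):
        demand = F[i, :].sum()
        if level[i] == 0:
            imports[i] = demand
            intake[i] = demand
        else:
            surplus = intake[i] - demand
            resp_share = rng.uniform(0.4, 0.8)
            respiration[i] = resp_share * surplus
            exports[i] = surplus - respiration[i]
    # biomass from throughflow and a turnover time of a few days
    turnover = rng.lognormal(mean=np.log(3.0), sigma=0.3, size=S)
    biomass = (imports + F.sum(axis=0)) * turnover

    net = FlowNetwork(
        node_ids=tuple(node_ids),
        names=tuple(node_ids),
        category=tuple(category),
        biomass=biomass,
        imports=imports,
        exports=exports,
        respiration=respiration,
        F=F,
        meta={
            "generator": "planted-channel",
            "n_channels": k,
            "per_channel": m,
            "levels": L,
            "coupling": spec.coupling,
            "seed": spec.seed,
        },
    )
    return net, Partition(channel.copy())
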