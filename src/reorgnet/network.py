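"""Randomized instantiation of the network connectivity.

Each neuron receives exactly ``round(c * N_pre)`` presynaptic partners
from every population that projects to it, drawn uniformly without
replacement (autapses excluded within self-recurrent classes).  Every
synapse carries the class weight ``summed_weight / (c * N_pre)`` and an
independent transmission delay drawn uniformly from the class delay
range, so the summed resting-peak conductance per neuron per class is
exactly the configured summed weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, NetworkConfig, validate_config


@dataclass
class ConnectionClass:
    """Realized synapses of one population-to-population class."""

    pre_pop: str
    post_pop: str
    kind: str
    weight: float          # nS per synapse
    indegree: int
    pre_index: np.ndarray  # (N_post, indegree) global presynaptic indices
    delay: np.ndarray      # (N_post, indegree) ms


@dataclass
class NetworkInstance:
    """One concrete random network realization."""

    config: NetworkConfig
    seed: int
    pop_order: tuple
    pop_slice: dict = field(default_factory=dict)  # label -> slice of global ids
    classes: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(self.config.populations[p].size for p in self.pop_order)

    def population_of(self, global_index: int) -> str:
        for label, sl in self.pop_slice.items():
            if sl.start <= global_index < sl.stop:
                return label
        raise IndexError(global_index)


def build_network(config: NetworkConfig, seed: int | None = None) -> NetworkInstance:
    """Draw one network realization; deterministic given ``seed``.

    Parameters
    ----------
    config
        Validated network configuration.
    seed
        Connectivity seed; defaults to ``config.seed``.
    """
    validate_config(config)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))

    pop_order = tuple(config.populations)
    offsets = {}
    start = 0
    inst = NetworkInstance(config=config, seed=int(seed), pop_order=pop_order)
    for label in pop_order:
        n = config.populations[label].size
        inst.pop_slice[label] = slice(start, start + n)
        offsets[label] = start
        start += n

    for i, conn in enumerate(config.connections):
        n_pre = config.populations[conn.pre_pop].size
        n_post = config.populations[conn.post_pop].size
        k = int(round(conn.connectivity_ratio * n_pre))
        if k <= 0:
            raise ConfigError(
                f"connections[{i}]: c*N = "
                f"{conn.connectivity_ratio * n_pre:g} rounds to zero in-degree")
        recurrent = conn.pre_pop == conn.post_pop
        if recurrent and k > n_pre - 1:
            raise ConfigError(
                f"connections[{i}]: in-degree {k} impossible without autapses")
        pre_index = np.empty((n_post, k), dtype=np.int64)
        for post in range(n_post):
            pool = np.arange(n_pre)
            if recurrent:
                pool = np.delete(pool, post)
            pre_index[post] = rng.choice(pool, size=k, replace=False)
        lo, hi = conn.delay_range
        delay = rng.uniform(lo, hi, size=(n_post, k))
        inst.classes.append(ConnectionClass(
            pre_pop=conn.pre_pop, post_pop=conn.post_pop, kind=conn.kind,
            weight=conn.summed_weight / k, indegree=k,
            pre_index=pre_index + offsets[conn.pre_pop], delay=delay,
        ))
    return inst
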