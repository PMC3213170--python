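"""Shared fixtures.

Expensive simulations (scaled trial batches, the full-size batch for the
dwell-time check, the mean-field attractor timeline) are session-scoped
so independent tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

import reorgnet as rn
from reorgnet import analysis, meanfield, stability


def make_config(n=50, variant="all_types", **kwargs):
    return rn.default_config(variant=variant, n_exc=n, n_inh=n, **kwargs)


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down network: 50 neurons per population."""
    return make_config(50)


@pytest.fixture(scope="session")
def tiny_network():
    """10-neuron network (2 per population) for exact oracle comparisons.

    The bias is raised above threshold so the noise-free network fires,
    exercising spikes, delays and plasticity deterministically.
    """
    cfg = make_config(2, noise_sigma=0.0)
    for p in cfg.populations.values():
        p.neuron.noise_sigma = 0.0
    for label in rn.EXC_POPS:
        cfg.populations[label].bias_conductance = 9.5
    cfg.populations[rn.INH_POP].bias_conductance = 5.5
    for conn in cfg.connections:
        conn.connectivity_ratio = 0.5     # in-degree 1 from each class
        conn.delay_range = (1.0, 4.0)
    cfg.protocol.trial_duration = 800.0
    cfg.protocol.goal_display_onset = 300.0
    return rn.validate_config(cfg)


@pytest.fixture(scope="session")
def scaled_batch(fast_config):
    """16 balanced scaled-down trials (independent connectivity draws)."""
    return analysis.run_batch(fast_config, 16, seed=3, vary_network=True)


@pytest.fixture(scope="session")
def meanfield_trajectory():
    cfg = rn.default_config()
    return meanfield.simulate_mean_field(cfg)


@pytest.fixture(scope="session")
def meanfield_basis(meanfield_trajectory):
    """PC basis over all four mean-field transition patterns (two goals
    crossed with the two symmetry-break targets), so the goal and action
    axes are the symmetric contrasts."""
    trajs = [meanfield_trajectory]
    for goal, target in (("G1", "A2"), ("G2", "A1"), ("G2", "A2")):
        cfg = rn.default_config()
        cfg.protocol.sensory_target = goal
        trajs.append(meanfield.simulate_mean_field(cfg, symmetry_break=target))
    return analysis.fit_pca(trajs)


@pytest.fixture(scope="session")
def attractor_timeline(meanfield_trajectory, meanfield_basis):
    return stability.track_attractors(meanfield_trajectory, stride=100.0,
                                      basis=meanfield_basis)


@pytest.fixture(scope="session")
def dwell_batch():
    """Eight full-size (200 neurons/population) trials with goal G1."""
    cfg = rn.default_config()
    return analysis.run_batch(cfg, 8, seed=1, goals=["G1"] * 8)
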