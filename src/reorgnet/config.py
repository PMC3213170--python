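"""Configuration schema for the reorganizable attractor network.

The network models a prefrontal circuit in which four excitatory
populations (A--D) and one shared pool of inhibitory interneurons (IN)
form overlapping cell assemblies.  Pairs A&B and C&D encode two goals;
pairs A&D and B&C encode two action directions.  Which pair behaves as a
cell assembly at a given moment is decided by short-term synaptic
plasticity: goal-assembly synapses depress with use while action-assembly
synapses facilitate, so sustained goal activity dismantles the goal
attractor and builds the action attractors.

Three canonical wirings (``variant``) are supported:

``all_types``
    depressing goal synapses, facilitating action synapses, constant
    self-recurrent / inhibitory synapses (the default network),
``depression_only``
    plasticity only on the goal synapses,
``facilitation_only``
    plasticity only on the action synapses.

All quantities use nS for conductances, mV for potentials, nF for
capacitance and ms for time.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import yaml

EXC_POPS = ("A", "B", "C", "D")
INH_POP = "IN"
ALL_POPS = EXC_POPS + (INH_POP,)

#: goal label -> populations receiving its sensory input
GOAL_ASSEMBLIES = {"G1": ("A", "B"), "G2": ("C", "D")}
#: action label -> populations forming the action-coding assembly
ACTION_ASSEMBLIES = {"A1": ("A", "D"), "A2": ("B", "C")}

#: assembly label -> ordered population pairs (pre, post) whose mutual
#: synapses define the assembly's internal efficacy
ASSEMBLY_EDGES = {
    "A&B": (("A", "B"), ("B", "A")),
    "C&D": (("C", "D"), ("D", "C")),
    "A&D": (("A", "D"), ("D", "A")),
    "B&C": (("B", "C"), ("C", "B")),
}

VARIANTS = ("all_types", "depression_only", "facilitation_only")
SYNAPSE_KINDS = ("facilitation", "depression", "constant", "inhibitory")


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant.

    The message always names the offending field path.
    """


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron constants.

    ``noise_sigma`` is the amplitude of the additive membrane noise in
    mV/sqrt(ms): each integration step adds an independent normal deviate
    with standard deviation ``noise_sigma * sqrt(dt)`` to the membrane
    potential (Euler--Maruyama convention).
    """

    membrane_capacitance: float  # nF
    leak_conductance: float      # nS
    leak_reversal: float         # mV
    threshold: float = -52.0     # mV
    reset: float = -60.0         # mV
    refractory: float = 2.0      # ms
    excitatory_reversal: float = -5.0   # mV
    inhibitory_reversal: float = -75.0  # mV
    noise_sigma: float = 0.14    # mV / sqrt(ms)

    def validate(self, path: str) -> None:
        if not self.reset < self.threshold:
            raise ConfigError(f"{path}.reset: must be below threshold")
        for name in ("membrane_capacitance", "leak_conductance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{path}.{name}: must be > 0")
        if self.refractory < 0:
            raise ConfigError(f"{path}.refractory: must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigError(f"{path}.noise_sigma: must be >= 0")


def excitatory_neuron_defaults(noise_sigma: float = 0.14) -> NeuronParams:
    return NeuronParams(
        membrane_capacitance=0.5, leak_conductance=25.0, leak_reversal=-70.0,
        refractory=2.0, noise_sigma=noise_sigma,
    )


def inhibitory_neuron_defaults(noise_sigma: float = 0.14) -> NeuronParams:
    return NeuronParams(
        membrane_capacitance=0.2, leak_conductance=20.0, leak_reversal=-65.0,
        refractory=1.0, noise_sigma=noise_sigma,
    )


@dataclass
class PlasticityParams:
    """Tsodyks--Markram short-term plasticity constants for one synapse kind.

    ``U_rest`` is the resting utilization (fraction of resources released
    per spike), ``tau_u`` the relaxation time of the utilization factor u
    back to ``U_rest`` and ``tau_x`` the recovery time of the available
    resources x back to 1.  Depression dominates when u relaxes quickly and
    x recovers slowly; facilitation dominates in the opposite regime.
    """

    U_rest: float
    tau_u: float  # ms
    tau_x: float  # ms

    def validate(self, path: str) -> None:
        if not 0 < self.U_rest <= 1:
            raise ConfigError(f"{path}.U_rest: must be in (0, 1]")
        if self.tau_u <= 0:
            raise ConfigError(f"{path}.tau_u: must be > 0")
        if self.tau_x <= 0:
            raise ConfigError(f"{path}.tau_x: must be > 0")


def default_plasticity() -> dict:
    # Depression: utilization relaxes fast (20 ms), resources recover
    # slowly (600 ms).  Facilitation: utilization stays elevated (600 ms),
    # resources recover fast (100 ms).  Both rest at U = 0.2.
    return {
        "depression": PlasticityParams(U_rest=0.2, tau_u=20.0, tau_x=600.0),
        "facilitation": PlasticityParams(U_rest=0.2, tau_u=600.0, tau_x=100.0),
    }


@dataclass
class ConnectionSpec:
    """One population-to-population synapse class.

    ``summed_weight`` is the total conductance a postsynaptic neuron would
    see if every one of its presynaptic partners had synaptic activity 1;
    each individual synapse carries ``summed_weight / (c * N_pre)``.
    """

    pre_pop: str
    post_pop: str
    kind: str
    summed_weight: float             # nS
    connectivity_ratio: float = 0.2
    delay_range: tuple = (1.0, 5.0)  # ms

    def validate(self, path: str, populations: Iterable[str]) -> None:
        if self.pre_pop not in populations:
            raise ConfigError(f"{path}.pre_pop: unknown population {self.pre_pop!r}")
        if self.post_pop not in populations:
            raise ConfigError(f"{path}.post_pop: unknown population {self.post_pop!r}")
        if self.kind not in SYNAPSE_KINDS:
            raise ConfigError(f"{path}.kind: unknown kind {self.kind!r}")
        if not 0 < self.connectivity_ratio <= 1:
            raise ConfigError(f"{path}.connectivity_ratio: must be in (0, 1]")
        if self.summed_weight < 0:
            raise ConfigError(f"{path}.summed_weight: must be >= 0")
        lo, hi = self.delay_range
        if not (0 < lo <= hi):
            raise ConfigError(f"{path}.delay_range: need 0 < lo <= hi")


@dataclass
class StimulusProtocol:
    """External-input protocol for one trial.

    The activation input ramps linearly from 0 to ``activation_amplitude``
    over ``activation_ramp`` ms starting at ``goal_display_onset`` and is
    then held for the rest of the trial on all four excitatory
    populations.  The sensory input is a rectangular pulse of
    ``sensory_amplitude`` for ``sensory_width`` ms onto the assembly of
    ``sensory_target`` (G1 -> A&B, G2 -> C&D).  An optional perturbation
    pulse targets one action assembly (A1 -> A&D, A2 -> B&C).
    """

    activation_amplitude: float = 0.35  # nS
    activation_ramp: float = 200.0      # ms
    sensory_amplitude: float = 0.2      # nS
    sensory_width: float = 200.0        # ms
    sensory_target: str = "G1"
    perturbation_amplitude: float = 0.0  # nS
    perturbation_onset: float = 0.0      # ms after goal_display_onset
    perturbation_width: float = 200.0    # ms
    perturbation_target: str = "A1"
    goal_display_onset: float = 500.0    # ms
    trial_duration: float = 4000.0       # ms

    def validate(self, path: str) -> None:
        for name in ("activation_amplitude", "sensory_amplitude",
                     "perturbation_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{path}.{name}: must be >= 0")
        for name in ("activation_ramp", "sensory_width", "perturbation_width",
                     "perturbation_onset", "goal_display_onset"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{path}.{name}: must be >= 0")
        if self.trial_duration <= 0:
            raise ConfigError(f"{path}.trial_duration: must be > 0")
        if self.goal_display_onset > self.trial_duration:
            raise ConfigError(f"{path}.goal_display_onset: beyond trial_duration")
        if self.sensory_target not in GOAL_ASSEMBLIES:
            raise ConfigError(f"{path}.sensory_target: must be G1 or G2")
        if self.perturbation_target not in ACTION_ASSEMBLIES:
            raise ConfigError(f"{path}.perturbation_target: must be A1 or A2")


@dataclass
class PopulationSpec:
    size: int
    neuron: NeuronParams
    bias_conductance: float  # nS

    def validate(self, path: str) -> None:
        if self.size <= 0:
            raise ConfigError(f"{path}.size: must be > 0")
        if self.bias_conductance < 0:
            raise ConfigError(f"{path}.bias_conductance: must be >= 0")
        self.neuron.validate(f"{path}.neuron")


# (goal, action, self, E->IN, IN->E) summed weights and excitatory kinds
# for the three canonical wirings.
_VARIANT_TABLES = {
    "all_types": {
        "goal": (3.2, "depression"),
        "action": (1.55, "facilitation"),
        "self": (1.7, "constant"),
        "e_to_in": (0.7, "constant"),
        "in_to_e": (5.0, "inhibitory"),
    },
    "depression_only": {
        "goal": (3.0, "depression"),
        "action": (0.5, "constant"),
        "self": (1.8, "constant"),
        "e_to_in": (0.7, "constant"),
        "in_to_e": (5.5, "inhibitory"),
    },
    "facilitation_only": {
        "goal": (0.8, "constant"),
        "action": (3.1, "facilitation"),
        "self": (1.9, "constant"),
        "e_to_in": (0.7, "constant"),
        "in_to_e": (7.5, "inhibitory"),
    },
}

_GOAL_EDGES = (("A", "B"), ("B", "A"), ("C", "D"), ("D", "C"))
_ACTION_EDGES = (("A", "D"), ("D", "A"), ("B", "C"), ("C", "B"))
_SELF_EDGES = (("A", "A"), ("B", "B"), ("C", "C"), ("D", "D"))


def variant_connections(variant: str, connectivity_ratio: float = 0.2,
                        delay_range: tuple = (1.0, 5.0)) -> list:
    """Connection table of one canonical wiring, as ConnectionSpec list."""
    if variant not in _VARIANT_TABLES:
        raise ConfigError(f"variant: unknown variant {variant!r}")
    tab = _VARIANT_TABLES[variant]
    conns = []

    def add(edges, role):
        w, kind = tab[role]
        for pre, post in edges:
            conns.append(ConnectionSpec(pre, post, kind, w,
                                        connectivity_ratio, delay_range))

    add(_GOAL_EDGES, "goal")
    add(_ACTION_EDGES, "action")
    add(_SELF_EDGES, "self")
    add([(p, INH_POP) for p in EXC_POPS], "e_to_in")
    add([(INH_POP, p) for p in EXC_POPS], "in_to_e")
    return conns


@dataclass
class NetworkConfig:
    """Full parameterization of one network and one trial protocol."""

    populations: dict = field(default_factory=dict)
    connections: list = field(default_factory=list)
    plasticity: dict = field(default_factory=default_plasticity)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    variant: str = "all_types"
    seed: int = 0
    dt: float = 0.1          # ms, integration step
    tau_s_exc: float = 100.0  # ms, NMDA-like excitatory synaptic decay
    tau_s_inh: float = 20.0   # ms, inhibitory synaptic decay

    def copy(self) -> "NetworkConfig":
        return copy.deepcopy(self)

    def population_order(self) -> tuple:
        return tuple(self.populations)

    def connection(self, pre: str, post: str) -> ConnectionSpec:
        for c in self.connections:
            if c.pre_pop == pre and c.post_pop == post:
                return c
        raise KeyError(f"no connection {pre}->{post}")


def default_config(variant: str = "all_types", n_exc: int = 200,
                   n_inh: int = 200, seed: int = 0,
                   noise_sigma: float = 0.14) -> NetworkConfig:
    """Canonical configuration for one of the three wirings.

    ``n_exc``/``n_inh`` scale the population sizes (200 each at full
    scale); all other parameters are the canonical defaults.
    """
    pops = {p: PopulationSpec(n_exc, excitatory_neuron_defaults(noise_sigma),
                              bias_conductance=8.35)
            for p in EXC_POPS}
    pops[INH_POP] = PopulationSpec(
        n_inh, inhibitory_neuron_defaults(noise_sigma), bias_conductance=4.0)
    cfg = NetworkConfig(
        populations=pops,
        connections=variant_connections(variant),
        variant=variant,
        seed=seed,
    )
    return validate_config(cfg)


def validate_config(config: NetworkConfig) -> NetworkConfig:
    """Check every configuration invariant; return the config unchanged.

    Raises :class:`ConfigError` naming the offending field path.
    """
    if config.variant not in VARIANTS:
        raise ConfigError(f"variant: unknown variant {config.variant!r}")
    missing = [p for p in ALL_POPS if p not in config.populations]
    if missing:
        raise ConfigError(f"populations: missing {missing}")
    for label, pop in config.populations.items():
        pop.validate(f"populations[{label}]")
    if config.dt <= 0:
        raise ConfigError("dt: must be > 0")
    for name in ("tau_s_exc", "tau_s_inh"):
        if getattr(config, name) <= 0:
            raise ConfigError(f"{name}: must be > 0")
    for kind in ("facilitation", "depression"):
        if kind not in config.plasticity:
            raise ConfigError(f"plasticity[{kind}]: missing")
        config.plasticity[kind].validate(f"plasticity[{kind}]")
    for i, conn in enumerate(config.connections):
        path = f"connections[{i}]"
        conn.validate(path, config.populations)
        lo, hi = conn.delay_range
        if lo < config.dt:
            raise ConfigError(f"{path}.delay_range: lower bound below dt")
        if hi > config.protocol.trial_duration:
            raise ConfigError(f"{path}.delay_range: exceeds trial duration")
        if conn.pre_pop == INH_POP and conn.kind != "inhibitory":
            raise ConfigError(f"{path}.kind: interneuron output must be inhibitory")
        if conn.pre_pop != INH_POP and conn.kind == "inhibitory":
            raise ConfigError(f"{path}.kind: excitatory source cannot be inhibitory")
    config.protocol.validate("protocol")
    return config


def meanfield_config(config: NetworkConfig) -> NetworkConfig:
    """Copy of ``config`` with the mean-field goal-synapse weight.

    In the deterministic mean-field model the goal-assembly weight of the
    ``all_types`` wiring is reduced from 3.2 to 1.9 nS: spiking-noise
    fluctuations let the spiking network escape the goal state earlier, and
    the weaker deterministic coupling restores a comparable transition
    time.  Other variants are returned unchanged.
    """
    cfg = config.copy()
    if cfg.variant == "all_types":
        for conn in cfg.connections:
            if (conn.pre_pop, conn.post_pop) in _GOAL_EDGES:
                conn.summed_weight = 1.9
    return cfg


# ---------------------------------------------------------------------------
# serialization

def config_to_dict(config: NetworkConfig) -> dict:
    d = dataclasses.asdict(config)
    for label, pop in d["populations"].items():
        pop["neuron"] = dict(pop["neuron"])
    for conn in d["connections"]:
        conn["delay_range"] = list(conn["delay_range"])
    return d


def config_from_dict(d: dict) -> NetworkConfig:
    pops = {
        label: PopulationSpec(
            size=int(p["size"]),
            neuron=NeuronParams(**p["neuron"]),
            bias_conductance=float(p["bias_conductance"]),
        )
        for label, p in d["populations"].items()
    }
    conns = [
        ConnectionSpec(
            pre_pop=c["pre_pop"], post_pop=c["post_pop"], kind=c["kind"],
            summed_weight=float(c["summed_weight"]),
            connectivity_ratio=float(c.get("connectivity_ratio", 0.2)),
            delay_range=tuple(c.get("delay_range", (1.0, 5.0))),
        )
        for c in d["connections"]
    ]
    plas = {k: PlasticityParams(**v) for k, v in d["plasticity"].items()}
    cfg = NetworkConfig(
        populations=pops, connections=conns, plasticity=plas,
        protocol=StimulusProtocol(**d["protocol"]),
        variant=d.get("variant", "all_types"), seed=int(d.get("seed", 0)),
        dt=float(d.get("dt", 0.1)),
        tau_s_exc=float(d.get("tau_s_exc", 100.0)),
        tau_s_inh=float(d.get("tau_s_inh", 20.0)),
    )
    return validate_config(cfg)


def save_config(config: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> NetworkConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
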