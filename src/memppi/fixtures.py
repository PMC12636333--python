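"""Deterministic fixture configurations and hand-built lattices.

The registry supplies the small seeded systems used across the test
suite; the builders at the bottom construct exact lattice scenes for the
contact- and pocket-detection golden tests.  Everything here is
generated programmatically — no stored data files.
"""

from __future__ import annotations

from .config import RunConfig
from .inclusions import InclusionSpec, add_inclusion
from .lattice import LatticeState
from .reactions import ReactionNetwork, ReactionRule


def static_network_species(radius: int = 2, n_activators: int = 4,
                           n_inactivators: int = 4, n_targets: int = 8) -> list:
    """The fixed-partitioning cascade: the target and the inactivator
    partition into the ordered phase, the activator into the disordered
    phase; states do not feed back on partitioning."""
    return [
        InclusionSpec(name="activator", radius=radius, count=n_activators,
                      role="activator",
                      partition_by_state={"inactive": -1, "active": -1}),
        InclusionSpec(name="inactivator", radius=radius, count=n_inactivators,
                      role="inactivator",
                      partition_by_state={"inactive": 1, "active": 1}),
        InclusionSpec(name="target", radius=radius, count=n_targets,
                      role="target",
                      partition_by_state={"inactive": 1, "active": 1}),
    ]


def switching_network_species(radius: int = 2, n_activators: int = 4,
                              n_inactivators: int = 4, n_targets: int = 8) -> list:
    """The partition-switching cascade: both enzymes prefer the ordered
    phase; the target prefers disorder when inactive and switches to
    order on activation (activators act as recruiters, inactivators as
    excluders)."""
    return [
        InclusionSpec(name="activator", radius=radius, count=n_activators,
                      role="activator",
                      partition_by_state={"inactive": 1, "active": 1}),
        InclusionSpec(name="inactivator", radius=radius, count=n_inactivators,
                      role="inactivator",
                      partition_by_state={"inactive": 1, "active": 1}),
        InclusionSpec(name="target", radius=radius, count=n_targets,
                      role="target",
                      partition_by_state={"inactive": -1, "active": 1}),
    ]


def standard_rules(rate: float = 0.1) -> list:
    return [
        ReactionRule("activator", "target", "inactive", "active", rate),
        ReactionRule("inactivator", "target", "active", "inactive", rate),
    ]


def static_network(radius: int = 2, rate: float = 0.1, **kw) -> ReactionNetwork:
    return ReactionNetwork(species=static_network_species(radius, **kw),
                           rules=standard_rules(rate))


def switching_network(radius: int = 2, rate: float = 0.1, **kw) -> ReactionNetwork:
    return ReactionNetwork(species=switching_network_species(radius, **kw),
                           rules=standard_rules(rate))


_REGISTRY = ("bare_ising_4x4", "static_network_small",
             "switching_network_small", "m_sweep_r3_small")


def generate_fixture(name: str, seed: int = 0) -> RunConfig:
    """Return a small deterministic RunConfig from the fixture registry."""
    if name == "bare_ising_4x4":
        return RunConfig(lattice_size=4, tau=1.0, magnetization=0.0,
                         sweeps=1000, snapshot_interval=500, seed=seed)
    if name == "static_network_small":
        return RunConfig(lattice_size=24, tau=1.1, magnetization=0.0,
                         species=static_network_species(
                             radius=1, n_activators=2, n_inactivators=2,
                             n_targets=4),
                         rules=standard_rules(0.1),
                         sweeps=500, snapshot_interval=100, seed=seed)
    if name == "switching_network_small":
        return RunConfig(lattice_size=24, tau=0.9, magnetization=0.0,
                         species=switching_network_species(
                             radius=1, n_activators=2, n_inactivators=2,
                             n_targets=4),
                         rules=standard_rules(0.1),
                         sweeps=500, snapshot_interval=100, seed=seed)
    if name == "m_sweep_r3_small":
        return RunConfig(lattice_size=40, tau=1.0, magnetization=-0.4,
                         species=static_network_species(
                             radius=3, n_activators=2, n_inactivators=2,
                             n_targets=4),
                         rules=standard_rules(0.1),
                         sweeps=500, snapshot_interval=100, seed=seed)
    raise KeyError(f"unknown fixture '{name}'; registry: {list(_REGISTRY)}")


# ---------------------------------------------------------------------------
# hand-built scenes for golden tests

def pocket_scene(with_inactivator: bool = False) -> LatticeState:
    """A 16x16 bright lattice holding one constructed dark cluster that
    contains two active targets and one activator (r=0 components); with
    ``with_inactivator`` an inactivator sits inside as well, so the
    cluster must not qualify as a pocket."""
    state = LatticeState(16, tau=0.9)
    state.spin[:, :] = -1
    state.spin[4:9, 4:9] = 1  # 25-site dark block
    species = [
        InclusionSpec(name="activator", radius=0, count=0, role="activator",
                      partition_by_state={"inactive": 1, "active": 1}),
        InclusionSpec(name="inactivator", radius=0, count=0, role="inactivator",
                      partition_by_state={"inactive": 1, "active": 1}),
        InclusionSpec(name="target", radius=0, count=0, role="target",
                      partition_by_state={"inactive": -1, "active": 1}),
    ]
    state.species = list(species)
    add_inclusion(state, species[2], (5, 5), "active")
    add_inclusion(state, species[2], (7, 7), "active")
    add_inclusion(state, species[0], (6, 6), "active")
    if with_inactivator:
        add_inclusion(state, species[1], (8, 8), "active")
    return state
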