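"""Contact-triggered reaction networks among inclusions.

A rule "actor + target(before) -> actor + target(after)" fires with a
fixed per-contact, per-sweep probability whenever a boundary site of an
actor-species inclusion is 4-adjacent to a boundary site of a
target-species inclusion in the required before-state.  Firing changes
only the target's internal activity state and, when the target species
partitions differently in its two states, its boundary spin value
(partition switching).  Because the switch does not depend on the
surrounding lipid configuration, these dynamics violate detailed balance.

Each rule carries a diagrammatic sign pair: the activity sign (+ for an
activating pathway, - for an inactivating one) and the contact-trend sign
(+ when actor and pre-state target partition into opposite phases, so
their contact rate grows with rescaled temperature; - when they partition
alike).  See :func:`memppi.analysis.predict_sign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .inclusions import (STATE_INDEX, STATE_NAMES, InclusionSpec,
                         state_tables, _radii_array)
from .lattice import EnergyModel, LatticeState


@dataclass
class ReactionRule:
    actor_species: str
    target_species: str
    target_state_before: str
    target_state_after: str
    rate_per_contact_sweep: float

    def __post_init__(self) -> None:
        for s in (self.target_state_before, self.target_state_after):
            if s not in STATE_NAMES:
                raise ValueError(f"unknown activity state '{s}'")
        if self.target_state_before == self.target_state_after:
            raise ValueError("a rule must change the target's state")
        if not 0.0 <= self.rate_per_contact_sweep <= 1.0:
            raise ValueError("rate_per_contact_sweep must lie in [0, 1]")


@dataclass
class ReactionNetwork:
    species: list = field(default_factory=list)   # list[InclusionSpec]
    rules: list = field(default_factory=list)     # list[ReactionRule]
    #: optional stored (activity_sign, contact_trend_sign) per rule; when
    #: provided it must match the derived signs (validated here).
    pathway_signs: list | None = None

    def __post_init__(self) -> None:
        names = {s.name for s in self.species}
        if len(names) != len(self.species):
            raise ValueError("duplicate species names in network")
        for r in self.rules:
            for ref in (r.actor_species, r.target_species):
                if ref not in names:
                    raise ValueError(
                        f"rule references undeclared species '{ref}'")
        derived = self.derive_pathway_signs()
        if self.pathway_signs is None:
            self.pathway_signs = derived
        else:
            stored = [tuple(p) for p in self.pathway_signs]
            if stored != derived:
                raise ValueError(
                    f"stored pathway_signs {stored} disagree with the signs "
                    f"derived from partitioning, {derived}")

    def spec(self, name: str) -> InclusionSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def derive_pathway_signs(self) -> list:
        """(activity_sign, contact_trend_sign) per rule.

        activity: +1 if the rule activates the target, -1 if it inactivates.
        contact trend: -1 when the actor (in its reaction-competent state)
        and the pre-state target partition alike — their contact rate falls
        as tau grows; +1 when they partition oppositely.
        """
        signs = []
        for r in self.rules:
            act = +1 if r.target_state_after == "active" else -1
            actor = self.spec(r.actor_species)
            target = self.spec(r.target_species)
            b_actor = actor.boundary_value(actor.initial_state)
            b_target = target.boundary_value(r.target_state_before)
            trend = -1 if b_actor == b_target else +1
            signs.append((act, trend))
        return signs

    def switches_partition(self, rule: ReactionRule) -> bool:
        t = self.spec(rule.target_species)
        return (t.boundary_value(rule.target_state_before)
                != t.boundary_value(rule.target_state_after))

    # kernel-ready arrays ---------------------------------------------------

    def to_arrays(self, species_order: list) -> dict:
        """Pack rules as index arrays relative to species_order."""
        index = {s.name: i for i, s in enumerate(species_order)}
        n = len(self.rules)
        return {
            "rule_actor": np.array([index[r.actor_species] for r in self.rules],
                                   dtype=np.int64).reshape(n),
            "rule_target": np.array([index[r.target_species] for r in self.rules],
                                    dtype=np.int64).reshape(n),
            "rule_before": np.array([STATE_INDEX[r.target_state_before]
                                     for r in self.rules], dtype=np.int64).reshape(n),
            "rule_after": np.array([STATE_INDEX[r.target_state_after]
                                    for r in self.rules], dtype=np.int64).reshape(n),
            "rule_rate": np.array([r.rate_per_contact_sweep for r in self.rules],
                                  dtype=np.float64).reshape(n),
        }


# ---------------------------------------------------------------------------
# per-sweep operations (Python API; the simulation driver uses the fused
# numba kernel, cross-checked against these in the test suite)

def detect_contacts(state: LatticeState) -> list:
    """Unordered inclusion pairs whose boundary sites are 4-adjacent."""
    n = state.n_inclusions
    if n < 2:
        return []
    t = state_tables(state)
    cmat = np.zeros((n, n), dtype=np.uint8)
    _kernels.fill_contacts(state.owner, state.bnd,
                           state.inc_x, state.inc_y, _radii_array(state),
                           t["fp_dx"], t["fp_dy"], t["fp_isb"], t["fp_start"],
                           cmat)
    a, b = np.nonzero(cmat)
    return [(int(i), int(j)) for i, j in zip(a, b)]


def apply_partition_switch(state: LatticeState, inclusion_id: int,
                           model: EnergyModel) -> float:
    """Reset an inclusion's boundary value to match its current activity
    state, immediately and unconditionally; returns the energy change."""
    spec = state.species[state.inc_species[inclusion_id]]
    new_b = spec.boundary_value(STATE_NAMES[state.inc_state[inclusion_id]])
    t = state_tables(state)
    return float(_kernels.switch_partition_kernel(
        state.spin, state.owner, state.bnd,
        state.inc_x, state.inc_y, _radii_array(state), state.inc_b,
        inclusion_id, np.int8(new_b),
        t["fp_dx"], t["fp_dy"], t["fp_isb"], t["fp_start"], model.J_int))


def apply_reactions(state: LatticeState, network: ReactionNetwork,
                    model: EnergyModel, sweep_index: int = 0,
                    contacts: list | None = None) -> tuple:
    """One sweep's reaction phase on the current contacts.

    Each matching (actor, target, rule) contact gets a single Bernoulli
    trial; candidates fire in random order and a target changes state at
    most once per sweep.  Returns (event list, dE); events are
    (sweep_index, target_id, rule_index) tuples.
    """
    if contacts is None:
        contacts = detect_contacts(state)
    name_of = [s.name for s in state.species]
    cands = []
    for a, b in contacts:
        for ri, rule in enumerate(network.rules):
            for actor, target in ((a, b), (b, a)):
                if (name_of[state.inc_species[actor]] == rule.actor_species
                        and name_of[state.inc_species[target]] == rule.target_species):
                    cands.append((actor, target, ri))
    state.rng.shuffle(cands)
    changed = set()
    events = []
    dE = 0.0
    for actor, target, ri in cands:
        rule = network.rules[ri]
        if target in changed:
            continue
        if STATE_NAMES[state.inc_state[target]] != rule.target_state_before:
            continue
        rate = rule.rate_per_contact_sweep
        if rate <= 0.0:
            continue
        if rate < 1.0 and state.rng.random() >= rate:
            continue
        state.inc_state[target] = STATE_INDEX[rule.target_state_after]
        changed.add(target)
        dE += apply_partition_switch(state, target, model)
        events.append((sweep_index, target, ri))
    return events, dE
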