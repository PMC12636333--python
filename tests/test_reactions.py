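"""Contact detection, reaction firing, partition switching."""

import numpy as np
import pytest

from memppi import (EnergyModel, InclusionSpec, ReactionNetwork, ReactionRule,
                    add_inclusion, build_lattice, total_energy)
from memppi.inclusions import STATE_NAMES
from memppi.reactions import (apply_partition_switch, apply_reactions,
                              detect_contacts)


def point_spec(name, role="", b=(1, 1)):
    return InclusionSpec(name=name, radius=0, count=0, role=role,
                         partition_by_state={"inactive": b[0], "active": b[1]})


class TestDetectContacts:
    def test_manhattan_distance_one_touches(self, model):
        state = build_lattice(8, 0.0, seed=1)
        s = point_spec("p")
        add_inclusion(state, s, (2, 2))
        add_inclusion(state, s, (2, 3))
        assert detect_contacts(state) == [(0, 1)]

    def test_manhattan_distance_two_does_not(self, model):
        state = build_lattice(8, 0.0, seed=1)
        s = point_spec("p")
        add_inclusion(state, s, (2, 2))
        add_inclusion(state, s, (2, 4))
        assert detect_contacts(state) == []

    def test_r1_disks_three_apart_touch(self, model):
        """Two plus-shapes with centres 3 apart along an axis: the facing
        arms sit at distance 1, so their boundary sites are adjacent."""
        state = build_lattice(12, 0.0, seed=1)
        s = InclusionSpec(name="d", radius=1, count=0)
        add_inclusion(state, s, (5, 2))
        add_inclusion(state, s, (5, 5))
        assert detect_contacts(state) == [(0, 1)]
        # 4 apart: gap of two lipid sites, no contact
        state2 = build_lattice(12, 0.0, seed=1)
        add_inclusion(state2, s, (5, 2))
        add_inclusion(state2, s, (5, 6))
        assert detect_contacts(state2) == []

    def test_periodic_wrap_contact(self, model):
        state = build_lattice(8, 0.0, seed=1)
        s = point_spec("p")
        add_inclusion(state, s, (0, 0))
        add_inclusion(state, s, (7, 0))  # adjacent across the seam
        assert detect_contacts(state) == [(0, 1)]


def two_species_network(rate=1.0, switch=False):
    target_b = (-1, 1) if switch else (1, 1)
    species = [point_spec("activator", role="activator", b=(-1, -1)),
               point_spec("inactivator", role="inactivator", b=(1, 1)),
               point_spec("target", role="target", b=target_b)]
    rules = [ReactionRule("activator", "target", "inactive", "active", rate),
             ReactionRule("inactivator", "target", "active", "inactive", rate)]
    return species, ReactionNetwork(species=species, rules=rules)


class TestApplyReactions:
    def _state_with(self, species, placements):
        state = build_lattice(10, 0.0, seed=2)
        for spec, center, st in placements:
            add_inclusion(state, spec, center, st)
        return state

    def test_activation_at_rate_one(self, model):
        species, net = two_species_network(rate=1.0)
        state = self._state_with(species, [
            (species[0], (3, 3), "active"),
            (species[2], (3, 4), "inactive")])
        events, dE = apply_reactions(state, net, model, sweep_index=5)
        assert STATE_NAMES[state.inc_state[1]] == "active"
        assert events == [(5, 1, 0)]

    def test_inactivation_at_rate_one(self, model):
        species, net = two_species_network(rate=1.0)
        state = self._state_with(species, [
            (species[1], (3, 3), "active"),
            (species[2], (3, 4), "active")])
        apply_reactions(state, net, model)
        assert STATE_NAMES[state.inc_state[1]] == "inactive"

    def test_no_matching_rule_no_change(self, model):
        species, net = two_species_network(rate=1.0)
        state = self._state_with(species, [
            (species[0], (3, 3), "active"),
            (species[2], (3, 4), "active")])  # already active
        events, dE = apply_reactions(state, net, model)
        assert events == [] and dE == 0.0
        assert STATE_NAMES[state.inc_state[1]] == "active"

    def test_rate_zero_draws_no_randomness(self, model):
        """With all rates 0 the reaction phase must not consume RNG, so
        the configurational chain replays bit-identically without rules."""
        species, net = two_species_network(rate=0.0)
        state = self._state_with(species, [
            (species[0], (3, 3), "active"),
            (species[2], (3, 4), "inactive")])
        state.rng = np.random.default_rng(42)
        before = state.rng.bit_generator.state["state"]["state"]
        events, _ = apply_reactions(state, net, model)
        assert events == []

    def test_at_most_one_flip_per_target_per_sweep(self, model):
        """A target touching an activator and an inactivator flips at most
        once per sweep even at rate 1 (first success locks the target)."""
        species, net = two_species_network(rate=1.0)
        for seed in range(8):
            state = self._state_with(species, [
                (species[0], (3, 3), "active"),
                (species[2], (3, 4), "inactive"),
                (species[1], (3, 5), "active")])
            state.rng = np.random.default_rng(seed)
            events, _ = apply_reactions(state, net, model)
            assert len(events) <= 1  # never activate-then-deactivate


class TestPartitionSwitch:
    def test_switch_updates_boundary_and_energy(self, model):
        species, net = two_species_network(rate=1.0, switch=True)
        state = build_lattice(10, 0.6, seed=4)  # biased solvent: dE != 0
        add_inclusion(state, species[2], (5, 5), "inactive")
        assert state.inc_b[0] == -1
        E0 = total_energy(state, model)
        state.inc_state[0] = 1  # a flip just occurred
        dE = apply_partition_switch(state, 0, model)
        assert state.inc_b[0] == 1
        assert state.spin[5, 5] == 1  # boundary spin rewritten on lattice
        assert E0 + dE == pytest.approx(total_energy(state, model))
        # inverse switch restores
        state.inc_state[0] = 0
        dE2 = apply_partition_switch(state, 0, model)
        assert state.inc_b[0] == -1
        assert dE2 == pytest.approx(-dE)

    def test_static_partitioning_switch_is_noop(self, model):
        species, net = two_species_network(rate=1.0, switch=False)
        state = build_lattice(10, 0.0, seed=4)
        add_inclusion(state, species[2], (5, 5), "inactive")
        state.inc_state[0] = 1
        dE = apply_partition_switch(state, 0, model)
        assert dE == 0.0 and state.inc_b[0] == 1

    def test_reactions_never_touch_composition_or_positions(self, model):
        species, net = two_species_network(rate=1.0, switch=True)
        state = build_lattice(12, 0.0, seed=6)
        add_inclusion(state, species[0], (3, 3), "active")
        add_inclusion(state, species[2], (3, 4), "inactive")
        total = state.lipid_spin_sum()
        pos = (state.inc_x.copy(), state.inc_y.copy())
        apply_reactions(state, net, model)
        assert state.lipid_spin_sum() == total
        assert np.array_equal(state.inc_x, pos[0])
        assert np.array_equal(state.inc_y, pos[1])


class TestNetworkValidation:
    def test_undeclared_species_rejected(self):
        species = [point_spec("a")]
        with pytest.raises(ValueError, match="ghost"):
            ReactionNetwork(species=species, rules=[
                ReactionRule("a", "ghost", "inactive", "active", 0.1)])

    def test_stored_signs_must_match_derived(self):
        species, _ = two_species_network()
        rules = [ReactionRule("activator", "target", "inactive", "active", 0.1)]
        net = ReactionNetwork(species=species, rules=rules)
        assert net.pathway_signs == [(1, 1)]  # opposite partitioning: + contact
        with pytest.raises(ValueError, match="disagree"):
            ReactionNetwork(species=species, rules=rules,
                            pathway_signs=[(1, -1)])

    def test_rule_must_change_state(self):
        with pytest.raises(ValueError):
            ReactionRule("a", "t", "active", "active", 0.1)

    def test_kernel_and_python_contacts_agree(self, model):
        """The fused kernel's contact matrix must equal the API's pairs on
        random crowded states."""
        from memppi import _kernels
        from memppi.inclusions import (place_inclusions, state_tables,
                                       _radii_array)
        state = build_lattice(20, 0.0, seed=13)
        spec = InclusionSpec(name="d", radius=1, count=12)
        place_inclusions(state, [spec], seed=3)
        pairs = detect_contacts(state)
        # independent brute force over boundary-site adjacency
        L = state.L
        bsites = {}
        for i in range(state.n_inclusions):
            from memppi.inclusions import rasterize_disk
            offsets, isb = rasterize_disk(1)
            for (dx, dy), b in zip(offsets.tolist(), isb.tolist()):
                if b:
                    bsites.setdefault(i, []).append(
                        ((state.inc_x[i] + dx) % L, (state.inc_y[i] + dy) % L))
        expect = set()
        for i in bsites:
            for j in bsites:
                if i >= j:
                    continue
                for x1, y1 in bsites[i]:
                    for x2, y2 in bsites[j]:
                        if min(abs(x1 - x2), L - abs(x1 - x2)) + \
                           min(abs(y1 - y2), L - abs(y1 - y2)) == 1:
                            expect.add((i, j))
        assert set(pairs) == expect
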