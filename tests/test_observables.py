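"""Activity, correlation functions, dark-cluster and pocket detection."""

import numpy as np
import pandas as pd
import pytest

from memppi import (InclusionSpec, activity_fraction, add_inclusion,
                    build_lattice, detect_pockets, radial_cross_correlation,
                    replay_activity, run_simulation)
from memppi.fixtures import generate_fixture, pocket_scene
from memppi.observables import (Snapshot, Trajectory, detect_dark_clusters,
                                flag_pocketed, _label_periodic)


class TestActivityFraction:
    @pytest.mark.parametrize("states,expect", [
        ([0] * 10, 0.0),
        ([1] * 6, 1.0),
        ([1, 1, 1] + [0] * 9, 0.25),
    ])
    def test_values(self, states, expect):
        state = build_lattice(24, 0.0, seed=1)
        spec = InclusionSpec(name="t", radius=0, count=0, role="target",
                             partition_by_state={"inactive": 1, "active": 1})
        for k, s in enumerate(states):
            add_inclusion(state, spec, (k // 12, 2 * (k % 12)),
                          "active" if s else "inactive")
        assert activity_fraction(state) == pytest.approx(expect)

    def test_no_targets_rejected(self):
        state = build_lattice(8, 0.0, seed=1)
        with pytest.raises(ValueError):
            activity_fraction(state)


def synthetic_trajectory(positions, species_list, L=16, n_species=2):
    """Trajectory of bare snapshots at given center arrays (testing aid)."""
    snaps = []
    for t, (xs, ys, sp) in enumerate(positions):
        snaps.append(Snapshot(
            sweep=t, spin=np.zeros((L, L), dtype=np.int8),
            inc_x=np.asarray(xs), inc_y=np.asarray(ys),
            inc_species=np.asarray(sp),
            inc_state=np.ones(len(xs), dtype=np.int64),
            inc_b=np.ones(len(xs), dtype=np.int8)))
    return Trajectory(
        sweeps=np.arange(len(snaps)), activity=np.zeros(len(snaps)),
        energy=np.zeros(len(snaps)), snapshots=snaps,
        events=pd.DataFrame(columns=["sweep", "inclusion", "rule", "new_state"]),
        species=species_list, initial_inc_state=np.ones(2, dtype=np.int64),
        initial_inc_species=np.arange(2), achieved_m=0.0, tau=1.0, seed=0)


SPECIES2 = [InclusionSpec(name="a", radius=0, count=1),
            InclusionSpec(name="b", radius=0, count=1)]


class TestRadialCrossCorrelation:
    def test_ideal_gas_normalization(self):
        """Uniform random placements must give g ~ 1 in every populated bin."""
        rng = np.random.default_rng(0)
        L = 16
        frames = []
        for _ in range(400):
            xs = rng.integers(L, size=8)
            ys = rng.integers(L, size=8)
            frames.append((xs, ys, np.array([0, 0, 0, 0, 1, 1, 1, 1])))
        traj = synthetic_trajectory(frames, SPECIES2, L=L)
        g = radial_cross_correlation(traj, "a", "b", bin_width=1.0)
        pop = g[g["expected"] > 100]
        assert np.all(np.abs(pop["g"] - 1.0) < 0.15)
        # totals agree up to sampling noise (same truncation both sides)
        assert g["count"].sum() == pytest.approx(g["expected"].sum(), rel=0.05)

    def test_single_frozen_pair_single_bin(self):
        L = 16
        frames = [(np.array([2, 2]), np.array([2, 7]), np.array([0, 1]))] * 5
        traj = synthetic_trajectory(frames, SPECIES2, L=L)
        g = radial_cross_correlation(traj, "a", "b", bin_width=1.0)
        hot = g[g["count"] > 0]
        assert len(hot) == 1
        assert hot.iloc[0]["r_lo"] <= 5.0 < hot.iloc[0]["r_hi"]

    def test_minimum_image_distances(self):
        L = 16
        frames = [(np.array([0, 15]), np.array([0, 15]), np.array([0, 1]))]
        traj = synthetic_trajectory(frames, SPECIES2, L=L)
        g = radial_cross_correlation(traj, "a", "b", bin_width=1.0)
        hot = g[g["count"] > 0]
        assert hot.iloc[0]["r_lo"] <= np.sqrt(2) < hot.iloc[0]["r_hi"]

    def test_unknown_species_rejected(self):
        traj = synthetic_trajectory([(np.array([1]), np.array([1]),
                                      np.array([0]))], SPECIES2)
        with pytest.raises(ValueError):
            radial_cross_correlation(traj, "a", "zzz")


class TestPeriodicLabeling:
    def test_wraps_across_both_seams(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, :] = True
        mask[-1, :] = True
        labels = _label_periodic(mask)
        assert len(np.unique(labels[mask])) == 1
        mask2 = np.zeros((8, 8), dtype=bool)
        mask2[:, 0] = True
        mask2[:, -1] = True
        labels2 = _label_periodic(mask2)
        assert len(np.unique(labels2[mask2])) == 1


class TestPockets:
    def test_bright_lattice_no_pockets(self):
        state = build_lattice(16, -1.0, seed=1)  # all disordered
        state.species = pocket_scene().species
        assert detect_pockets(state, min_size=5) == []

    def test_constructed_pocket_detected(self):
        state = pocket_scene()
        found = detect_pockets(state, min_size=10)
        assert len(found) == 1
        rec = found[0]
        assert rec.census[("target", "active")] == 2
        assert rec.census[("activator", "active")] == 1
        assert ("inactivator", "active") not in rec.census
        assert rec.size >= 25

    def test_inactivator_inside_disqualifies(self):
        state = pocket_scene(with_inactivator=True)
        assert detect_pockets(state, min_size=10) == []
        # but the dark cluster itself is still found, with a full census
        clusters = detect_dark_clusters(state, min_size=10)
        assert len(clusters) == 1
        assert sum(clusters[0].census.values()) == len(clusters[0].occupants) == 4

    def test_min_size_filters(self):
        state = pocket_scene()
        assert detect_pockets(state, min_size=200) == []

    def test_census_counts_all_occupants(self):
        state = pocket_scene(with_inactivator=True)
        clusters = detect_dark_clusters(state, min_size=10)
        names = [(n, s) for (n, s) in clusters[0].census]
        assert ("inactivator", "active") in names


class TestFlagPocketed:
    def test_outlier_with_persistence_flagged(self):
        act = [0.1, 0.12, 0.11, 0.09, 0.1, 0.95]
        per = [0, 0, 1, 0, 0, 8]
        flags = flag_pocketed(act, per, iqr_mult=1.5, min_persist=3)
        assert flags.tolist() == [False] * 5 + [True]

    def test_high_activity_without_persistent_pocket_not_flagged(self):
        act = [0.1, 0.12, 0.11, 0.09, 0.1, 0.95]
        per = [0, 0, 0, 0, 0, 1]
        assert not flag_pocketed(act, per, min_persist=3).any()


class TestEventReplay:
    def test_replay_matches_recorded_activity(self):
        cfg = generate_fixture("static_network_small", seed=9)
        traj = run_simulation(cfg)
        assert np.allclose(replay_activity(traj), traj.activity)

    def test_replay_matches_for_switching_network(self):
        cfg = generate_fixture("switching_network_small", seed=4)
        traj = run_simulation(cfg)
        assert np.allclose(replay_activity(traj), traj.activity)
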