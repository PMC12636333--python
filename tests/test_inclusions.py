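"""Inclusion geometry, placement and diffusive moves."""

import numpy as np
import pytest
from scipy import stats

from memppi import (EnergyModel, InclusionSpec, add_inclusion, build_lattice,
                    total_energy)
from memppi.inclusions import (PackingError, detect_overlaps, edge_maps,
                               inclusion_move_attempt, place_inclusions,
                               rasterize_disk, scheduler_step)
from memppi.lattice import LIPID, LatticeState


def brute_force_disk(r):
    return sorted((dx, dy) for dx in range(-r - 1, r + 2)
                  for dy in range(-r - 1, r + 2) if dx * dx + dy * dy <= r * r)


class TestRasterize:
    def test_r0_single_site_own_boundary(self):
        offsets, isb = rasterize_disk(0)
        assert offsets.tolist() == [[0, 0]]
        assert isb.tolist() == [1]

    def test_r1_plus_shape(self):
        offsets, isb = rasterize_disk(1)
        assert sorted(map(tuple, offsets.tolist())) == [
            (-1, 0), (0, -1), (0, 0), (0, 1), (1, 0)]
        # the four arms have exterior neighbours; the centre is enclosed
        # by the arms, touches no lipid, and is therefore interior
        assert dict(zip(map(tuple, offsets.tolist()), isb.tolist())) == {
            (-1, 0): 1, (0, -1): 1, (0, 0): 0, (0, 1): 1, (1, 0): 1}

    @pytest.mark.parametrize("r", [2, 3, 4])
    def test_matches_brute_force_enumeration(self, r):
        offsets, isb = rasterize_disk(r)
        pts = brute_force_disk(r)
        assert sorted(map(tuple, offsets.tolist())) == pts
        # boundary = has a 4-neighbour outside the footprint
        pset = set(pts)
        for (dx, dy), b in zip(offsets.tolist(), isb.tolist()):
            outside = any((dx + ex, dy + ey) not in pset
                          for ex, ey in ((1, 0), (-1, 0), (0, 1), (0, -1)))
            assert bool(b) == outside

    def test_r3_footprint_size(self):
        offsets, isb = rasterize_disk(3)
        assert len(offsets) == 29

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            rasterize_disk(-1)

    @pytest.mark.parametrize("r", [0, 1, 2, 3])
    def test_edge_maps_consistent(self, r):
        """Lead/trail sets partition the symmetric difference of the moved
        footprint, with equal sizes (the relocation map is a bijection)."""
        offsets, _ = rasterize_disk(r)
        fp = set(map(tuple, offsets.tolist()))
        leads, trails = edge_maps(r)
        for d, (ddx, ddy) in enumerate(((1, 0), (-1, 0), (0, 1), (0, -1))):
            dest = {(x + ddx, y + ddy) for x, y in fp}
            assert set(map(tuple, leads[d].tolist())) == dest - fp
            assert set(map(tuple, trails[d].tolist())) == fp - dest


class TestPlacement:
    def test_empty_spec_list_noop(self):
        state = build_lattice(8, 0.0, seed=1)
        spins = state.spin.copy()
        place_inclusions(state, [], seed=0)
        assert np.array_equal(state.spin, spins)
        assert state.n_inclusions == 0

    def test_two_point_inclusions_distinct_sites(self):
        state = build_lattice(4, 0.0, seed=1)
        spec = InclusionSpec(name="p", radius=0, count=2)
        place_inclusions(state, [spec], seed=5)
        assert state.n_inclusions == 2
        assert (state.inc_x[0], state.inc_y[0]) != (state.inc_x[1], state.inc_y[1])
        assert detect_overlaps(state) == []

    def test_many_disks_disjoint_footprints(self):
        state = build_lattice(100, 0.0, seed=2)
        spec = InclusionSpec(name="d", radius=3, count=30)
        place_inclusions(state, [spec], seed=7)
        assert state.n_inclusions == 30
        assert detect_overlaps(state) == []  # exhaustive pairwise oracle
        # occupancy accounting: every footprint site owned, disjoint
        assert int((state.owner >= 0).sum()) == 30 * 29

    def test_overcrowded_raises_packing_error(self):
        state = build_lattice(8, 0.0, seed=3)
        spec = InclusionSpec(name="d", radius=2, count=6)  # 6*13 > 64
        with pytest.raises(PackingError):
            place_inclusions(state, [spec], seed=1)

    def test_seeded_placement_reproducible(self):
        a = build_lattice(20, 0.0, seed=4)
        b = build_lattice(20, 0.0, seed=4)
        spec = InclusionSpec(name="d", radius=1, count=5)
        place_inclusions(a, [spec], seed=11)
        place_inclusions(b, [spec], seed=11)
        assert np.array_equal(a.inc_x, b.inc_x)
        assert np.array_equal(a.inc_y, b.inc_y)


class TestMoves:
    def test_overlap_rejected_state_unchanged(self, model):
        state = build_lattice(8, 0.0, seed=1)
        spec = InclusionSpec(name="p", radius=1, count=0)
        add_inclusion(state, spec, (2, 2))
        add_inclusion(state, spec, (2, 5))  # 3 apart: move along +y collides
        spin = state.spin.copy()
        owner = state.owner.copy()
        accepted, dE = inclusion_move_attempt(state, 0, model, direction=2)
        assert not accepted and dE == 0.0
        assert np.array_equal(state.spin, spin)
        assert np.array_equal(state.owner, owner)

    def test_uniform_solvent_always_accepts(self, model):
        state = build_lattice(8, 1.0, seed=1)  # all lipids +1
        spec = InclusionSpec(name="p", radius=1, count=0,
                             partition_by_state={"inactive": -1, "active": -1})
        add_inclusion(state, spec, (3, 3))
        for d in range(4):
            accepted, dE = inclusion_move_attempt(state, 0, model, direction=d)
            assert accepted and dE == pytest.approx(0.0)

    def test_move_conserves_lipid_spin_sum_and_energy_books(self, model):
        state = build_lattice(12, 0.0, seed=8, tau=1.1)
        spec = InclusionSpec(name="p", radius=2, count=0,
                             partition_by_state={"inactive": 1, "active": 1})
        add_inclusion(state, spec, (4, 4))
        add_inclusion(state, spec, (9, 9))
        total = state.lipid_spin_sum()
        E = total_energy(state, model)
        for k in range(300):
            _, dE = inclusion_move_attempt(state, k % 2, model)
            E += dE
        assert state.lipid_spin_sum() == total
        assert E == pytest.approx(total_energy(state, model))
        assert detect_overlaps(state) == []

    @pytest.mark.parametrize("r,d", [(0, 0), (1, 2), (2, 0), (3, 3)])
    def test_move_then_reverse_is_involution(self, r, d):
        """The edge relocation map composed with its reverse restores the
        configuration exactly (the proposal is symmetric)."""
        from memppi import _kernels
        from memppi.inclusions import state_tables, _radii_array

        state = build_lattice(12, 0.0, seed=3)
        spec = InclusionSpec(name="p", radius=r, count=0)
        add_inclusion(state, spec, (5, 5))
        t = state_tables(state)
        spin0, owner0, bnd0 = (state.spin.copy(), state.owner.copy(),
                               state.bnd.copy())
        args = (t["fp_dx"], t["fp_dy"], t["fp_isb"], t["fp_start"],
                t["ld_dx"], t["ld_dy"], t["tr_dx"], t["tr_dy"], t["ed_start"])
        _kernels._apply_disk_move(state.spin, state.owner, state.bnd, 0,
                                  state.inc_b[0], 5, 5, r, d, *args)
        assert not np.array_equal(state.owner, owner0)
        dx, dy = ((1, 0), (-1, 0), (0, 1), (0, -1))[d]
        _kernels._apply_disk_move(state.spin, state.owner, state.bnd, 0,
                                  state.inc_b[0], 5 + dx, 5 + dy, r, d ^ 1,
                                  *args)
        assert np.array_equal(state.spin, spin0)
        assert np.array_equal(state.owner, owner0)
        assert np.array_equal(state.bnd, bnd0)

    def test_equilibrium_matches_joint_exact_enumeration(self, model,
                                                         probe_spec):
        """Production moves on a 4x4 lattice with an anchor inclusion and a
        single -1 lipid: the probe's long-run site occupancy must match the
        position marginal of the exact joint Boltzmann law (chi-square)."""
        L = 4

        def make(p, q):
            st = LatticeState(L, tau=1.0)
            st.spin[:, :] = 1
            add_inclusion(st, probe_spec, (0, 0), "active")      # anchor
            add_inclusion(st, probe_spec, (p // L, p % L), "active")  # probe
            st.spin[q // L, q % L] = -1
            return st

        weights = np.zeros(L * L)
        for p in range(1, L * L):
            for q in range(L * L):
                if q in (0, p):
                    continue
                E = total_energy(make(p, q), model)
                weights[p] += np.exp(-E / make(p, q).temperature)
        marg = weights / weights.sum()

        st = make(5, 10)
        st.rng = np.random.default_rng(99)
        thin = 25  # decorrelate: chi-square needs near-independent samples
        n = 8_000
        visits = np.zeros(L * L, dtype=np.int64)
        for _ in range(n):
            for _ in range(thin):
                inclusion_move_attempt(st, 1, model)
            visits[st.inc_x[1] * L + st.inc_y[1]] += 1
        sel = marg > 0
        chi2 = ((visits[sel] - marg[sel] * n) ** 2 / (marg[sel] * n)).sum()
        p_val = stats.chi2.sf(chi2, int(sel.sum()) - 1)
        assert p_val > 0.01


class TestScheduler:
    def test_c0_keeps_inclusions_immobile(self, model):
        state = build_lattice(10, 0.0, seed=6)
        spec = InclusionSpec(name="p", radius=1, count=2)
        place_inclusions(state, [spec], seed=2)
        x0, y0 = state.inc_x.copy(), state.inc_y.copy()
        scheduler_step(state, model, C=0, nsweeps=20)
        assert np.array_equal(state.inc_x, x0)
        assert np.array_equal(state.inc_y, y0)

    def test_fixed_seed_bit_identical_trajectory(self, model):
        def run():
            state = build_lattice(12, 0.0, seed=21, tau=1.05)
            spec = InclusionSpec(name="p", radius=1, count=3)
            place_inclusions(state, [spec], seed=2)
            state.rng = np.random.default_rng(77)
            scheduler_step(state, model, C=2, nsweeps=50)
            return state

        a, b = run(), run()
        assert np.array_equal(a.spin, b.spin)
        assert np.array_equal(a.inc_x, b.inc_x)
        assert np.array_equal(a.inc_y, b.inc_y)
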