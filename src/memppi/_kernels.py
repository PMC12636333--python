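"""Numba-compiled inner loops for the lattice Monte Carlo dynamics.

All kernels operate on flat numpy arrays packed by :mod:`memppi._context`.
Site classes are encoded as: ``owner == -1`` lipid, ``owner == i`` site of
inclusion ``i`` with ``bnd`` distinguishing boundary ring from interior.
The spin array holds the Ising spin at lipid sites, the boundary value at
inclusion-boundary sites and 0 at interior sites (interior spins carry no
coupling), so every pair energy is ``-c * s_a * s_b`` with a coefficient
that depends only on the two site classes.

Randomness: every kernel entry point reseeds numba's internal RNG from an
explicit integer seed so that call sequences are reproducible regardless of
process history.
"""

import numpy as np
from numba import njit

# direction table; d ^ 1 is the opposite direction
# d=0:+x, 1:-x, 2:+y, 3:-y


@njit(cache=True, inline="always")
def _dir(d):
    if d == 0:
        return 1, 0
    elif d == 1:
        return -1, 0
    elif d == 2:
        return 0, 1
    else:
        return 0, -1


@njit(cache=True, inline="always")
def _pair_e(spin, owner, bnd, x1, y1, x2, y2, J, Jint):
    """Energy of the bond (x1,y1)-(x2,y2); 0 unless lipid-lipid or lipid-boundary."""
    o1 = owner[x1, y1]
    o2 = owner[x2, y2]
    if o1 == -1:
        if o2 == -1:
            c = J
        elif bnd[x2, y2]:
            c = Jint
        else:
            return 0.0
    elif o2 == -1:
        if bnd[x1, y1]:
            c = Jint
        else:
            return 0.0
    else:
        return 0.0
    return -c * spin[x1, y1] * spin[x2, y2]


@njit(cache=True)
def total_energy_kernel(spin, owner, bnd, J, Jint):
    L = spin.shape[0]
    E = 0.0
    for x in range(L):
        xp = (x + 1) % L
        for y in range(L):
            yp = (y + 1) % L
            E += _pair_e(spin, owner, bnd, x, y, xp, y, J, Jint)
            E += _pair_e(spin, owner, bnd, x, y, x, yp, J, Jint)
    return E


@njit(cache=True)
def _box_energy(spin, owner, bnd, cx, cy, half, J, Jint):
    """Sum of bond energies with left/bottom endpoint in a (2*half+1)^2 box.

    The same box evaluated before/after a local update yields the exact dE
    as long as every modified site lies within Chebyshev distance ``half - 1``
    of (cx, cy).  When the box would wrap onto itself the whole lattice is
    summed instead (each bond once).
    """
    L = spin.shape[0]
    side = 2 * half + 1
    if side >= L:
        x0 = 0
        nx = L
    else:
        x0 = cx - half
        nx = side
    if side >= L:
        y0 = 0
        ny = L
    else:
        y0 = cy - half
        ny = side
    E = 0.0
    if J == Jint:
        # single coupling: every pair is -J*s1*s2 except inclusion-inclusion
        # (interior spins are stored as 0, so those terms vanish anyway)
        for a in range(nx):
            x = (x0 + a) % L
            xp = (x + 1) % L
            for b in range(ny):
                y = (y0 + b) % L
                yp = (y + 1) % L
                o1 = owner[x, y]
                s1 = spin[x, y]
                if not (o1 >= 0 and owner[xp, y] >= 0):
                    E -= J * s1 * spin[xp, y]
                if not (o1 >= 0 and owner[x, yp] >= 0):
                    E -= J * s1 * spin[x, yp]
        return E
    for a in range(nx):
        x = (x0 + a) % L
        xp = (x + 1) % L
        for b in range(ny):
            y = (y0 + b) % L
            yp = (y + 1) % L
            E += _pair_e(spin, owner, bnd, x, y, xp, y, J, Jint)
            E += _pair_e(spin, owner, bnd, x, y, x, yp, J, Jint)
    return E


@njit(cache=True, inline="always")
def _nbr_sum_excl(spin, owner, bnd, x, y, ex, ey, J, Jint, L):
    """Sum of coupling*spin over 4-neighbours of (x,y), excluding site (ex,ey)."""
    S = 0.0
    nx = x + 1 if x + 1 < L else 0
    if not (nx == ex and y == ey):
        o = owner[nx, y]
        if o == -1:
            S += J * spin[nx, y]
        elif bnd[nx, y]:
            S += Jint * spin[nx, y]
    nx = x - 1 if x > 0 else L - 1
    if not (nx == ex and y == ey):
        o = owner[nx, y]
        if o == -1:
            S += J * spin[nx, y]
        elif bnd[nx, y]:
            S += Jint * spin[nx, y]
    ny = y + 1 if y + 1 < L else 0
    if not (x == ex and ny == ey):
        o = owner[x, ny]
        if o == -1:
            S += J * spin[x, ny]
        elif bnd[x, ny]:
            S += Jint * spin[x, ny]
    ny = y - 1 if y > 0 else L - 1
    if not (x == ex and ny == ey):
        o = owner[x, ny]
        if o == -1:
            S += J * spin[x, ny]
        elif bnd[x, ny]:
            S += Jint * spin[x, ny]
    return S


@njit(cache=True, inline="always")
def _nbr_spin_sum_excl(spin, x, y, ex, ey, L):
    """Plain neighbour spin sum (exclusion as above); valid when J == J_int,
    since interior sites store spin 0 and boundary sites store b."""
    S = 0
    nx = x + 1 if x + 1 < L else 0
    if not (nx == ex and y == ey):
        S += spin[nx, y]
    nx = x - 1 if x > 0 else L - 1
    if not (nx == ex and y == ey):
        S += spin[nx, y]
    ny = y + 1 if y + 1 < L else 0
    if not (x == ex and ny == ey):
        S += spin[x, ny]
    ny = y - 1 if y > 0 else L - 1
    if not (x == ex and ny == ey):
        S += spin[x, ny]
    return S


@njit(cache=True)
def _kawasaki_pass(spin, owner, bnd, J, Jint, T, nlipid, acc_table, acc_off):
    """One sweep: nlipid exchange attempts from uniformly random lipid sites.

    acc_table, when non-empty, holds precomputed Metropolis factors for
    the discrete energy changes dE = k - acc_off of integer couplings;
    an empty table falls back to computing exp(-dE/T).
    Returns the accumulated energy change of accepted swaps.
    """
    L = spin.shape[0]
    LL4 = L * L * 4
    have_table = acc_table.shape[0] > 0
    same_coup = J == Jint
    # all-integer fast path: unit couplings with an acceptance table
    int_path = same_coup and J == 1.0 and have_table
    dE_acc = 0.0
    for _ in range(nlipid):
        # one uniform draw encodes (site, direction); redraw until the
        # site is a lipid (direction stays uniform and independent)
        while True:
            w = int(np.random.random() * LL4)
            idx = w >> 2
            x = idx // L
            y = idx % L
            if owner[x, y] == -1:
                break
        d = w & 3
        if d == 0:
            nx = x + 1 if x + 1 < L else 0
            ny = y
        elif d == 1:
            nx = x - 1 if x > 0 else L - 1
            ny = y
        elif d == 2:
            nx = x
            ny = y + 1 if y + 1 < L else 0
        else:
            nx = x
            ny = y - 1 if y > 0 else L - 1
        if owner[nx, ny] != -1:
            continue  # null move: neighbour is not a lipid
        sa = spin[x, y]
        sb = spin[nx, ny]
        if sa == sb:
            continue  # dE = 0, exchange is a no-op
        if int_path:
            di = (sa - sb) * (_nbr_spin_sum_excl(spin, x, y, nx, ny, L)
                              - _nbr_spin_sum_excl(spin, nx, ny, x, y, L))
            if di <= 0 or np.random.random() < acc_table[di + acc_off]:
                spin[x, y] = sb
                spin[nx, ny] = sa
                dE_acc += di
            continue
        if same_coup:
            Sa = J * _nbr_spin_sum_excl(spin, x, y, nx, ny, L)
            Sb = J * _nbr_spin_sum_excl(spin, nx, ny, x, y, L)
        else:
            Sa = _nbr_sum_excl(spin, owner, bnd, x, y, nx, ny, J, Jint, L)
            Sb = _nbr_sum_excl(spin, owner, bnd, nx, ny, x, y, J, Jint, L)
        dE = (sa - sb) * (Sa - Sb)
        if dE <= 0.0:
            accept = True
        else:
            if have_table:
                p = acc_table[int(dE) + acc_off]
            else:
                p = np.exp(-dE / T)
            accept = np.random.random() < p
        if accept:
            spin[x, y] = sb
            spin[nx, ny] = sa
            dE_acc += dE
    return dE_acc


@njit(cache=True)
def kawasaki_kernel(spin, owner, bnd, J, Jint, T, nsweeps, nlipid, seed,
                    acc_table, acc_off):
    np.random.seed(seed)
    dE = 0.0
    for _ in range(nsweeps):
        dE += _kawasaki_pass(spin, owner, bnd, J, Jint, T, nlipid,
                             acc_table, acc_off)
    return dE


@njit(cache=True)
def global_exchange_kernel(spin, owner, bnd, J, Jint, T, nsweeps, nlipid,
                           seed, acc_table, acc_off):
    """Nonlocal spin-exchange sweeps (equilibration aid, not model dynamics).

    Swaps two uniformly random lipid sites with Metropolis acceptance.
    Shares the Kawasaki chain's stationary distribution on the fixed-
    magnetization class but avoids its diffusive critical slowing-down.
    """
    np.random.seed(seed)
    L = spin.shape[0]
    LL = L * L
    have_table = acc_table.shape[0] > 0
    dE_acc = 0.0
    for _ in range(nsweeps):
        for _a in range(nlipid):
            while True:
                idx = int(np.random.random() * LL)
                x1 = idx // L
                y1 = idx % L
                if owner[x1, y1] == -1:
                    break
            while True:
                idx = int(np.random.random() * LL)
                x2 = idx // L
                y2 = idx % L
                if owner[x2, y2] == -1:
                    break
            sa = spin[x1, y1]
            sb = spin[x2, y2]
            if sa == sb:
                continue
            Sa = _nbr_sum_excl(spin, owner, bnd, x1, y1, x2, y2, J, Jint, L)
            Sb = _nbr_sum_excl(spin, owner, bnd, x2, y2, x1, y1, J, Jint, L)
            dE = (sa - sb) * (Sa - Sb)
            if dE <= 0.0:
                accept = True
            else:
                if have_table:
                    p = acc_table[int(dE) + acc_off]
                else:
                    p = np.exp(-dE / T)
                accept = np.random.random() < p
            if accept:
                spin[x1, y1] = sb
                spin[x2, y2] = sa
                dE_acc += dE
    return dE_acc


@njit(cache=True)
def kawasaki_code_counts(spin, owner, bnd, J, Jint, T, nlipid, nsweeps, seed,
                         counts, acc_table, acc_off):
    """Kawasaki sweeps on a tiny lattice, histogramming the spin bit-code per sweep.

    Site (x, y) contributes bit x*L+y when its spin is +1.  Requires L*L <= 20.
    """
    np.random.seed(seed)
    L = spin.shape[0]
    dE = 0.0
    for _ in range(nsweeps):
        dE += _kawasaki_pass(spin, owner, bnd, J, Jint, T, nlipid,
                             acc_table, acc_off)
        code = 0
        idx = 0
        for x in range(L):
            for y in range(L):
                if spin[x, y] > 0:
                    code |= 1 << idx
                idx += 1
        counts[code] += 1
    return dE


@njit(cache=True)
def _apply_disk_move(spin, owner, bnd, iid, b, cx, cy, r, d,
                     fp_dx, fp_dy, fp_isb, fp_start,
                     ld_dx, ld_dy, tr_dx, tr_dy, ed_start):
    """Translate inclusion iid (footprint centred at cx,cy) one site along d.

    Lipid spins on the leading edge are relocated to the trailing edge in
    sorted-offset order; the mapping is its own inverse under the reverse
    move, making the proposal symmetric.
    """
    L = spin.shape[0]
    ddx, ddy = _dir(d)
    e0 = ed_start[r * 4 + d]
    e1 = ed_start[r * 4 + d + 1]
    m = e1 - e0
    vals = np.empty(m, np.int8)
    for k in range(m):
        x = (cx + ld_dx[e0 + k] + L) % L
        y = (cy + ld_dy[e0 + k] + L) % L
        vals[k] = spin[x, y]
    for k in range(m):
        x = (cx + tr_dx[e0 + k] + L) % L
        y = (cy + tr_dy[e0 + k] + L) % L
        owner[x, y] = -1
        bnd[x, y] = 0
        spin[x, y] = vals[k]
    ncx = (cx + ddx + L) % L
    ncy = (cy + ddy + L) % L
    f0 = fp_start[r]
    f1 = fp_start[r + 1]
    for k in range(f0, f1):
        x = (ncx + fp_dx[k] + L) % L
        y = (ncy + fp_dy[k] + L) % L
        owner[x, y] = iid
        isb = fp_isb[k]
        bnd[x, y] = isb
        spin[x, y] = b if isb else 0


@njit(cache=True)
def try_disk_move(spin, owner, bnd, inc_x, inc_y, inc_r, inc_b, i, d, u,
                  fp_dx, fp_dy, fp_isb, fp_start,
                  ld_dx, ld_dy, tr_dx, tr_dy, ed_start,
                  J, Jint, T):
    """One Metropolis translation attempt for inclusion i along direction d.

    u is a uniform(0,1) variate for the acceptance decision.
    Returns (accepted, dE); a hard-core overlap rejects outright with dE=0.
    """
    L = spin.shape[0]
    cx = inc_x[i]
    cy = inc_y[i]
    r = inc_r[i]
    # hard-core check: every newly covered site must be lipid
    e0 = ed_start[r * 4 + d]
    e1 = ed_start[r * 4 + d + 1]
    for k in range(e0, e1):
        x = (cx + ld_dx[k] + L) % L
        y = (cy + ld_dy[k] + L) % L
        if owner[x, y] != -1:
            return False, 0.0
    half = r + 2
    Eb = _box_energy(spin, owner, bnd, cx, cy, half, J, Jint)
    _apply_disk_move(spin, owner, bnd, i, inc_b[i], cx, cy, r, d,
                     fp_dx, fp_dy, fp_isb, fp_start,
                     ld_dx, ld_dy, tr_dx, tr_dy, ed_start)
    Ea = _box_energy(spin, owner, bnd, cx, cy, half, J, Jint)
    dE = Ea - Eb
    ddx, ddy = _dir(d)
    if dE <= 0.0 or u < np.exp(-dE / T):
        inc_x[i] = (cx + ddx + L) % L
        inc_y[i] = (cy + ddy + L) % L
        return True, dE
    # revert via the reverse move from the new centre (exact inverse mapping)
    _apply_disk_move(spin, owner, bnd, i, inc_b[i],
                     (cx + ddx + L) % L, (cy + ddy + L) % L, r, d ^ 1,
                     fp_dx, fp_dy, fp_isb, fp_start,
                     ld_dx, ld_dy, tr_dx, tr_dy, ed_start)
    return False, 0.0


@njit(cache=True)
def fill_contacts(owner, bnd, inc_x, inc_y, inc_r,
                  fp_dx, fp_dy, fp_isb, fp_start, cmat):
    """Mark cmat[a,b]=1 (a<b) when boundary sites of a and b are 4-adjacent."""
    n = inc_x.shape[0]
    L = owner.shape[0]
    for i in range(n):
        for j in range(n):
            cmat[i, j] = 0
    for i in range(n):
        r = inc_r[i]
        f0 = fp_start[r]
        f1 = fp_start[r + 1]
        for k in range(f0, f1):
            if not fp_isb[k]:
                continue
            x = (inc_x[i] + fp_dx[k] + L) % L
            y = (inc_y[i] + fp_dy[k] + L) % L
            for d in range(4):
                ddx, ddy = _dir(d)
                nx = (x + ddx + L) % L
                ny = (y + ddy + L) % L
                o = owner[nx, ny]
                if o >= 0 and o != i and bnd[nx, ny]:
                    a = min(i, o)
                    b = max(i, o)
                    cmat[a, b] = 1


@njit(cache=True)
def switch_partition_kernel(spin, owner, bnd, inc_x, inc_y, inc_r, inc_b,
                            i, new_b, fp_dx, fp_dy, fp_isb, fp_start, Jint):
    """Set inclusion i's boundary value to new_b; return the energy change.

    Only (boundary site, adjacent lipid) couplings change.
    """
    L = spin.shape[0]
    old_b = inc_b[i]
    if new_b == old_b:
        return 0.0
    r = inc_r[i]
    f0 = fp_start[r]
    f1 = fp_start[r + 1]
    ssum = 0.0
    for k in range(f0, f1):
        if not fp_isb[k]:
            continue
        x = (inc_x[i] + fp_dx[k] + L) % L
        y = (inc_y[i] + fp_dy[k] + L) % L
        spin[x, y] = new_b
        for d in range(4):
            ddx, ddy = _dir(d)
            nx = (x + ddx + L) % L
            ny = (y + ddy + L) % L
            if owner[nx, ny] == -1:
                ssum += spin[nx, ny]
    inc_b[i] = new_b
    return -Jint * (new_b - old_b) * ssum


@njit(cache=True)
def advance(spin, owner, bnd,
            inc_x, inc_y, inc_r, inc_species, inc_state, inc_b,
            spec_b_by_state, spec_is_target,
            rule_actor, rule_target, rule_before, rule_after, rule_rate,
            fp_dx, fp_dy, fp_isb, fp_start,
            ld_dx, ld_dy, tr_dx, tr_dy, ed_start,
            J, Jint, T, C, nsweeps, nlipid, E0, seed,
            act_out, energy_out,
            ev_sweep, ev_inc, ev_rule, acc_table, acc_off):
    """Run nsweeps full scheduler steps: Kawasaki pass, C translation
    attempts per inclusion (randomised order), contact detection, reactions.

    Records per-sweep active-target fraction and running total energy;
    reaction events go into the ev_* arrays (capped at their length).
    Returns (running energy, number of events logged).
    """
    np.random.seed(seed)
    n_inc = inc_x.shape[0]
    n_rules = rule_actor.shape[0]
    n_targets = 0
    for i in range(n_inc):
        if spec_is_target[inc_species[i]]:
            n_targets += 1
    E = E0
    ev_cap = ev_sweep.shape[0]
    n_ev = 0
    order = np.empty(n_inc, np.int64)
    cmat = np.zeros((max(n_inc, 1), max(n_inc, 1)), np.uint8)
    changed = np.zeros(max(n_inc, 1), np.uint8)
    cand_cap = max(n_inc * n_inc * max(n_rules, 1), 1)
    cand_actor = np.empty(cand_cap, np.int64)
    cand_target = np.empty(cand_cap, np.int64)
    cand_rule = np.empty(cand_cap, np.int64)
    for sw in range(nsweeps):
        if nlipid > 0:
            E += _kawasaki_pass(spin, owner, bnd, J, Jint, T, nlipid,
                                acc_table, acc_off)
        # inclusion translation phase, randomised order
        if n_inc > 0 and C > 0:
            for i in range(n_inc):
                order[i] = i
            for j in range(n_inc - 1, 0, -1):
                k = np.random.randint(0, j + 1)
                tmp = order[j]
                order[j] = order[k]
                order[k] = tmp
            for oi in range(n_inc):
                i = order[oi]
                for _ in range(C):
                    d = np.random.randint(0, 4)
                    u = np.random.random()
                    acc, dE = try_disk_move(
                        spin, owner, bnd, inc_x, inc_y, inc_r, inc_b, i, d, u,
                        fp_dx, fp_dy, fp_isb, fp_start,
                        ld_dx, ld_dy, tr_dx, tr_dy, ed_start, J, Jint, T)
                    if acc:
                        E += dE
        # reaction phase
        if n_inc > 0 and n_rules > 0:
            fill_contacts(owner, bnd, inc_x, inc_y, inc_r,
                          fp_dx, fp_dy, fp_isb, fp_start, cmat)
            nc = 0
            for a in range(n_inc - 1):
                for t in range(a + 1, n_inc):
                    if not cmat[a, t]:
                        continue
                    for ri in range(n_rules):
                        # orientation a=actor, t=target
                        if (inc_species[a] == rule_actor[ri]
                                and inc_species[t] == rule_target[ri]):
                            cand_actor[nc] = a
                            cand_target[nc] = t
                            cand_rule[nc] = ri
                            nc += 1
                        # orientation t=actor, a=target
                        if (inc_species[t] == rule_actor[ri]
                                and inc_species[a] == rule_target[ri]):
                            cand_actor[nc] = t
                            cand_target[nc] = a
                            cand_rule[nc] = ri
                            nc += 1
            for i in range(n_inc):
                changed[i] = 0
            # random firing order resolves conflicts; first success wins
            for j in range(nc - 1, 0, -1):
                k = np.random.randint(0, j + 1)
                tmp = cand_actor[j]
                cand_actor[j] = cand_actor[k]
                cand_actor[k] = tmp
                tmp = cand_target[j]
                cand_target[j] = cand_target[k]
                cand_target[k] = tmp
                tmp = cand_rule[j]
                cand_rule[j] = cand_rule[k]
                cand_rule[k] = tmp
            for ci in range(nc):
                t = cand_target[ci]
                ri = cand_rule[ci]
                if changed[t]:
                    continue
                if inc_state[t] != rule_before[ri]:
                    continue
                rate = rule_rate[ri]
                if rate <= 0.0:
                    continue  # no RNG draw: rate-0 networks replay exactly
                if rate < 1.0 and np.random.random() >= rate:
                    continue
                inc_state[t] = rule_after[ri]
                changed[t] = 1
                new_b = spec_b_by_state[inc_species[t], inc_state[t]]
                E += switch_partition_kernel(
                    spin, owner, bnd, inc_x, inc_y, inc_r, inc_b,
                    t, new_b, fp_dx, fp_dy, fp_isb, fp_start, Jint)
                if n_ev < ev_cap:
                    ev_sweep[n_ev] = sw
                    ev_inc[n_ev] = t
                    ev_rule[n_ev] = ri
                    n_ev += 1
        # observables
        if n_targets > 0:
            na = 0
            for i in range(n_inc):
                if spec_is_target[inc_species[i]] and inc_state[i] == 1:
                    na += 1
            act_out[sw] = na / n_targets
        else:
            act_out[sw] = np.nan
        energy_out[sw] = E
    return E, n_ev
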