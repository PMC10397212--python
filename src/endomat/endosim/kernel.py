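"""Numba kernel for the fixed-dt randomised-sweep surface simulation.

State layout (one entry per lattice node):

* ``rab_occ``  -- Rab5-site occupant: 0 free, 1 APPL1, 2 NT-EEA1, 3 CT-EEA1
* ``rab_lip``  -- lipid node claimed by the APPL1/CT-EEA1 on this Rab5
  site (-1 when none; NT-EEA1 claims no lipid)
* ``lip_species`` -- 0 PI(3,4)P2, 1 PI(3)P (conversion is irreversible)
* ``lip_occ``  -- lipid-site occupant: 0 free, 1 APPL1, 2 INPP4A, 3 CT-EEA1
* ``last_detach`` -- (4, n) last detach time per species per node, for the
  cluster-detach feedback

Each step visits the nodes in a fresh random order and performs attach /
detach / convert-and-jump attempts with per-step probabilities
``rate * dt * (1 + feedback)``.  Collisions inject N-terminal EEA1 onto
free Rab5 sites, spread uniformly over the influx window.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# species indices
APPL1, NT, CT, INPP = 0, 1, 2, 3
# occupant codes on the Rab5 layer: species + 1
FREE = 0


@njit(cache=True)
def _count_rab_neighbors(rab_occ, nbr, ptr, i, code):
    n = 0
    for k in range(ptr[i], ptr[i + 1]):
        if rab_occ[nbr[k]] == code:
            n += 1
    return n


@njit(cache=True)
def _count_lip_inpp_neighbors(lip_occ, nbr, ptr, i):
    n = 0
    for k in range(ptr[i], ptr[i + 1]):
        if lip_occ[nbr[k]] == 2:
            n += 1
    return n


@njit(cache=True)
def _count_recent(last_detach, nbr, ptr, i, sp, t, t_r):
    n = 0
    for k in range(ptr[i], ptr[i + 1]):
        if t - last_detach[sp, nbr[k]] <= t_r:
            n += 1
    return n


@njit(cache=True)
def _pick_adjacent_lipid(lip_occ, lip_species, nbr, ptr, i, species_code):
    """Random free lipid site of the wanted species adjacent to node i
    (the node itself or a lattice neighbour); -1 if none."""
    found = np.empty(ptr[i + 1] - ptr[i] + 1, dtype=np.int32)
    m = 0
    if lip_occ[i] == 0 and lip_species[i] == species_code:
        found[m] = i
        m += 1
    for k in range(ptr[i], ptr[i + 1]):
        j = nbr[k]
        if lip_occ[j] == 0 and lip_species[j] == species_code:
            found[m] = j
            m += 1
    if m == 0:
        return -1
    return found[np.random.randint(0, m)]


@njit(cache=True)
def _detach_rab(rab_occ, rab_lip, lip_occ, last_detach, i, t):
    sp = rab_occ[i] - 1
    rab_occ[i] = 0
    if rab_lip[i] >= 0:
        lip_occ[rab_lip[i]] = 0
        rab_lip[i] = -1
    last_detach[sp, i] = t


@njit(cache=True)
def run_kernel(n, nbr, ptr, nbr2, ptr2,
               rates, alpha, beta, t_r, clustering,
               p_convert, p_jump,
               coll_times, influx_m, influx_w,
               theta, dt, t_max, burn_in, record_every,
               seed):
    """One full simulation run; returns the recorded count traces.

    Returns (times, counts[nrec, 6], conversion_time, n_influx_applied)
    where counts columns are APPL1, INPP4A, NT, CT, PI34P2, PI3P and
    conversion_time is -1.0 when censored at t_max.
    """
    np.random.seed(seed)
    kon = rates[:4]
    koff = rates[4:]
    a = alpha if clustering else 0.0
    b = beta if clustering else 0.0

    rab_occ = np.zeros(n, dtype=np.int8)
    rab_lip = np.full(n, -1, dtype=np.int32)
    lip_species = np.zeros(n, dtype=np.int8)
    lip_occ = np.zeros(n, dtype=np.int8)
    last_detach = np.full((4, n), -1e18)

    # --- burn-in: APPL1-only kinetics on an all-PI(3,4)P2 surface ---
    n_burn = int(burn_in / dt)
    perm = np.arange(n)
    for step in range(n_burn):
        t = -burn_in + step * dt
        np.random.shuffle(perm)
        for idx in range(n):
            i = perm[idx]
            if rab_occ[i] == 0:
                nsame = _count_rab_neighbors(rab_occ, nbr, ptr, i, 1)
                p = kon[APPL1] * dt * (1.0 + a * nsame)
                if np.random.random() < p:
                    lj = _pick_adjacent_lipid(lip_occ, lip_species, nbr, ptr,
                                              i, 0)
                    if lj >= 0:
                        rab_occ[i] = 1
                        rab_lip[i] = lj
                        lip_occ[lj] = 1
            elif rab_occ[i] == 1:
                nrec = _count_recent(last_detach, nbr, ptr, i, APPL1, t, t_r)
                p = koff[APPL1] * dt * (1.0 + b * nrec)
                if np.random.random() < p:
                    _detach_rab(rab_occ, rab_lip, lip_occ, last_detach, i, t)

    # --- main run ---
    n_steps = int(t_max / dt)
    nrec = n_steps // record_every + 3
    rec_t = np.empty(nrec)
    rec_c = np.zeros((nrec, 6), dtype=np.int32)
    irec = 0
    conversion_time = -1.0
    n_coll = len(coll_times)
    coll_added = np.zeros(n_coll, dtype=np.int32)
    theta_count = theta * n
    n_pi3p = 0
    applied = 0

    for step in range(n_steps + 1):
        t = step * dt
        crossed = n_pi3p >= theta_count
        if step % record_every == 0 or crossed or step == n_steps:
            c_appl1 = 0
            c_nt = 0
            c_ct = 0
            c_inpp = 0
            for i in range(n):
                if rab_occ[i] == 1:
                    c_appl1 += 1
                elif rab_occ[i] == 2:
                    c_nt += 1
                elif rab_occ[i] == 3:
                    c_ct += 1
                if lip_occ[i] == 2:
                    c_inpp += 1
            rec_t[irec] = t
            rec_c[irec, 0] = c_appl1
            rec_c[irec, 1] = c_inpp
            rec_c[irec, 2] = c_nt
            rec_c[irec, 3] = c_ct
            rec_c[irec, 4] = n - n_pi3p
            rec_c[irec, 5] = n_pi3p
            irec += 1
        if crossed:
            conversion_time = t
            break
        if step == n_steps:
            break

        # collision influx: keep cumulative adds on the window's ramp
        for ci in range(n_coll):
            tc = coll_times[ci]
            if tc <= t < tc + influx_w and coll_added[ci] < influx_m:
                target = int(influx_m * min(1.0, (t - tc + dt) / influx_w)
                             + 0.5)
                want = target - coll_added[ci]
                for _ in range(want):
                    # uniform choice among free Rab5 sites
                    nfree = 0
                    for i in range(n):
                        if rab_occ[i] == 0:
                            nfree += 1
                    if nfree == 0:
                        break
                    pick = np.random.randint(0, nfree)
                    cnt = 0
                    for i in range(n):
                        if rab_occ[i] == 0:
                            if cnt == pick:
                                rab_occ[i] = 2  # NT-EEA1, no lipid claim
                                coll_added[ci] += 1
                                break
                            cnt += 1

        np.random.shuffle(perm)
        for idx in range(n):
            i = perm[idx]
            # ---- Rab5 layer ----
            occ = rab_occ[i]
            if occ == 0:
                u = np.random.random()
                p_a = kon[APPL1] * dt * (1.0 + a * _count_rab_neighbors(
                    rab_occ, nbr, ptr, i, 1))
                p_n = kon[NT] * dt * (1.0 + a * _count_rab_neighbors(
                    rab_occ, nbr, ptr, i, 2))
                p_c = kon[CT] * dt * (1.0 + a * _count_rab_neighbors(
                    rab_occ, nbr, ptr, i, 3))
                if u < p_a:
                    # APPL1 needs a free adjacent PI(3,4)P2 as well
                    lj = _pick_adjacent_lipid(lip_occ, lip_species, nbr, ptr,
                                              i, 0)
                    if lj >= 0:
                        rab_occ[i] = 1
                        rab_lip[i] = lj
                        lip_occ[lj] = 1
                elif u < p_a + p_n:
                    rab_occ[i] = 2
                elif u < p_a + p_n + p_c:
                    # CT-EEA1 needs a free adjacent PI(3)P
                    lj = _pick_adjacent_lipid(lip_occ, lip_species, nbr, ptr,
                                              i, 1)
                    if lj >= 0:
                        rab_occ[i] = 3
                        rab_lip[i] = lj
                        lip_occ[lj] = 3
            else:
                sp = occ - 1
                nrec_d = _count_recent(last_detach, nbr, ptr, i, sp, t, t_r)
                p = koff[sp] * dt * (1.0 + b * nrec_d)
                if np.random.random() < p:
                    _detach_rab(rab_occ, rab_lip, lip_occ, last_detach, i, t)

            # ---- lipid layer (INPP4A) ----
            locc = lip_occ[i]
            if locc == 2:
                nrec_d = _count_recent(last_detach, nbr, ptr, i, INPP, t, t_r)
                p = koff[INPP] * dt * (1.0 + b * nrec_d)
                if np.random.random() < p:
                    lip_occ[i] = 0
                    last_detach[INPP, i] = t
                elif np.random.random() < p_convert:
                    lip_species[i] = 1  # irreversible PI(3,4)P2 -> PI(3)P
                    n_pi3p += 1
                    lip_occ[i] = 0
                    moved = False
                    if np.random.random() < p_jump:
                        # jump to a free PI(3,4)P2 within graph distance 2
                        nfree = 0
                        for k in range(ptr2[i], ptr2[i + 1]):
                            j = nbr2[k]
                            if lip_occ[j] == 0 and lip_species[j] == 0:
                                nfree += 1
                        if nfree > 0:
                            pick = np.random.randint(0, nfree)
                            cnt = 0
                            for k in range(ptr2[i], ptr2[i + 1]):
                                j = nbr2[k]
                                if lip_occ[j] == 0 and lip_species[j] == 0:
                                    if cnt == pick:
                                        lip_occ[j] = 2
                                        moved = True
                                        break
                                    cnt += 1
                    if not moved:
                        last_detach[INPP, i] = t
            elif locc == 0 and lip_species[i] == 0:
                nsame = _count_lip_inpp_neighbors(lip_occ, nbr, ptr, i)
                p = kon[INPP] * dt * (1.0 + a * nsame)
                if np.random.random() < p:
                    lip_occ[i] = 2

    for ci in range(n_coll):
        if conversion_time < 0 or coll_times[ci] <= conversion_time:
            applied += 1

    return rec_t[:irec], rec_c[:irec], conversion_time, applied
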