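"""Compiled inner loops (numba).

Everything here is deterministic given the seed argument; the kernels use
numba's own np.random state, which is independent of the caller's
numpy Generator, so each kernel call is seeded explicitly with a child seed
drawn by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=False)
def tracer_kmc(total_rate, cum_rate, neighbor, disp, start, rec_times, seed):
    """Continuous-time random walk of independent tracers on a lattice.

    Parameters
    ----------
    total_rate : (U,) total exit rate per volume, s^-1
    cum_rate : (U, 6) cumulative per-direction exit rates (last column equals
        ``total_rate``)
    neighbor : (U, 6) neighbor volume ids, -1 for a closed face
    disp : (U, 6, 3) physical displacement (um) of each jump direction; lets
        the same kernel serve periodic boxes (wrap) and bounded cells
    start : (n,) start volume per walker
    rec_times : (T,) strictly increasing recording times, s

    Returns
    -------
    pos : (T, n, 3) unwrapped walker displacement from its start, um
    vol : (T, n) volume occupied at each recording time
    """
    np.random.seed(seed)
    n = start.shape[0]
    T = rec_times.shape[0]
    pos = np.zeros((T, n, 3))
    vol = np.zeros((T, n), dtype=np.int64)
    for w in range(n):
        v = start[w]
        t = 0.0
        x = np.zeros(3)
        rec = 0
        while rec < T:
            a0 = total_rate[v]
            if a0 <= 0.0:
                tau = INF
            else:
                tau = -np.log(np.random.random()) / a0
            t_next = t + tau
            while rec < T and rec_times[rec] < t_next:
                pos[rec, w, 0] = x[0]
                pos[rec, w, 1] = x[1]
                pos[rec, w, 2] = x[2]
                vol[rec, w] = v
                rec += 1
            if rec >= T:
                break
            t = t_next
            r = np.random.random() * a0
            d = 0
            while d < 5 and r >= cum_rate[v, d]:
                d += 1
            nb = neighbor[v, d]
            if nb >= 0:
                x[0] += disp[v, d, 0]
                x[1] += disp[v, d, 1]
                x[2] += disp[v, d, 2]
                v = nb
    return pos, vol


@njit(cache=False)
def brownian_box(start, diff, dt, n_steps, rec_every, box, blocked, l, seed):
    """Brownian walkers in a periodic box with impenetrable voxels.

    Steps into a blocked voxel are rejected (the walker keeps its position
    for that step).  Returns unwrapped positions for MSD estimation.

    start : (n, 3) wrapped start positions in [0, box)
    blocked : (nx, ny, nz) uint8, 1 = inaccessible voxel
    """
    np.random.seed(seed)
    n = start.shape[0]
    nx, ny, nz = blocked.shape
    T = n_steps // rec_every
    out = np.zeros((T, n, 3))
    wrapped = start.copy()
    unwrapped = np.zeros((n, 3))
    sd = np.sqrt(2.0 * diff * dt)
    rec = 0
    for s in range(1, n_steps + 1):
        for w in range(n):
            dx = sd * np.random.normal()
            dy = sd * np.random.normal()
            dz = sd * np.random.normal()
            px = wrapped[w, 0] + dx
            py = wrapped[w, 1] + dy
            pz = wrapped[w, 2] + dz
            qx = px % box[0]
            qy = py % box[1]
            qz = pz % box[2]
            i = int(qx / l)
            j = int(qy / l)
            k = int(qz / l)
            if i >= nx:
                i = nx - 1
            if j >= ny:
                j = ny - 1
            if k >= nz:
                k = nz - 1
            if blocked[i, j, k] == 0:
                wrapped[w, 0] = qx
                wrapped[w, 1] = qy
                wrapped[w, 2] = qz
                unwrapped[w, 0] += dx
                unwrapped[w, 1] += dy
                unwrapped[w, 2] += dz
        if s % rec_every == 0 and rec < T:
            for w in range(n):
                out[rec, w, 0] = unwrapped[w, 0]
                out[rec, w, 1] = unwrapped[w, 1]
                out[rec, w, 2] = unwrapped[w, 2]
            rec += 1
    return out


# -- population (Gillespie) engine -------------------------------------------
#
# Per-volume slot layout of stored absolute event times:
#   [0, M)            first-order, aggregated per species (min-time tracking)
#   [M, 2M)           diffusion jump, per species
#   [2M, 2M+R2)       bimolecular channels
#   [2M+R2, 2M+R2+Rs) surface-transfer channels
#
# Jump and reaction slots are rescheduled by propensity stretching when the
# state changes; first-order slots track the minimum next-reaction time of
# the molecules present and are updated by the carry/min rules instead.

ADV_HORIZON = 0      # horizon reached
ADV_JUMP_BRIDGE = 1  # jump targets a particle-mode (volume, species)
ADV_FO_BRIDGE = 2    # first-order product must be created as a particle
ADV_R2_BRIDGE = 3    # bimolecular product must be created as a particle
ADV_MAX_EVENTS = 4


@njit(cache=False)
def seed_numba(seed):
    np.random.seed(seed)


@njit(cache=False)
def exp_draw(a):
    if a <= 0.0:
        return INF
    return -np.log(np.random.random()) / a


@njit(cache=False)
def _heap_less(vmin_t, a, b):
    if vmin_t[a] != vmin_t[b]:
        return vmin_t[a] < vmin_t[b]
    return a < b


@njit(cache=False)
def _heap_sift_up(heap, hpos, vmin_t, i):
    while i > 0:
        p = (i - 1) // 2
        if _heap_less(vmin_t, heap[i], heap[p]):
            heap[i], heap[p] = heap[p], heap[i]
            hpos[heap[i]] = i
            hpos[heap[p]] = p
            i = p
        else:
            break


@njit(cache=False)
def _heap_sift_down(heap, hpos, vmin_t, i):
    n = heap.shape[0]
    while True:
        lft = 2 * i + 1
        rgt = lft + 1
        best = i
        if lft < n and _heap_less(vmin_t, heap[lft], heap[best]):
            best = lft
        if rgt < n and _heap_less(vmin_t, heap[rgt], heap[best]):
            best = rgt
        if best == i:
            break
        heap[i], heap[best] = heap[best], heap[i]
        hpos[heap[i]] = i
        hpos[heap[best]] = best
        i = best


@njit(cache=False)
def heap_update(heap, hpos, vmin_t, v):
    i = hpos[v]
    _heap_sift_up(heap, hpos, vmin_t, i)
    _heap_sift_down(heap, hpos, vmin_t, hpos[v])


@njit(cache=False)
def heap_build(heap, hpos, vmin_t):
    n = heap.shape[0]
    for v in range(n):
        heap[v] = v
        hpos[v] = v
    for i in range(n // 2 - 1, -1, -1):
        _heap_sift_down(heap, hpos, vmin_t, i)


@njit(cache=False)
def update_volume_min(times, vmin_t, vmin_s, heap, hpos, v):
    S = times.shape[1]
    tmin = INF
    smin = -1
    for s in range(S):
        if times[v, s] < tmin:
            tmin = times[v, s]
            smin = s
    vmin_t[v] = tmin
    vmin_s[v] = smin
    heap_update(heap, hpos, vmin_t, v)


@njit(cache=False)
def reschedule_slot(times, prop, v, slot, a_new, t, fired):
    """Eq-3 style update of one stored time after a propensity change."""
    a_old = prop[v, slot]
    if fired or a_old <= 0.0 or times[v, slot] == INF:
        times[v, slot] = t + exp_draw(a_new)
    elif a_new <= 0.0:
        times[v, slot] = INF
    elif a_new != a_old:
        times[v, slot] = t + (a_old / a_new) * (times[v, slot] - t)
    prop[v, slot] = a_new


@njit(cache=False)
def rescale_volume(counts, times, prop, v, t, fired_slot,
                   k1, dvec, gsum, vfree, r2_a, r2_b, r2_kvol, rs_sp, rs_rate):
    """Recompute jump/bimolecular/surface propensities of v and reschedule."""
    M = counts.shape[1]
    R2 = r2_a.shape[0]
    Rs = rs_rate.shape[1]
    for i in range(M):
        a_new = counts[v, i] * dvec[i] * gsum[v]
        reschedule_slot(times, prop, v, M + i, a_new, t, fired_slot == M + i)
    for r in range(R2):
        a = r2_a[r]
        b = r2_b[r]
        if vfree[v] <= 0.0:
            pairs = 0.0
        elif a == b:
            n = counts[v, a]
            pairs = 0.5 * n * (n - 1)
        else:
            pairs = counts[v, a] * counts[v, b]
        a_new = r2_kvol[r] * pairs / vfree[v] if vfree[v] > 0.0 else 0.0
        reschedule_slot(times, prop, v, 2 * M + r, a_new, t, fired_slot == 2 * M + r)
    for q in range(Rs):
        slot = 2 * M + R2 + q
        a_new = counts[v, rs_sp[q]] * rs_rate[v, q]
        reschedule_slot(times, prop, v, slot, a_new, t, fired_slot == slot)


@njit(cache=False)
def fo_remove_one(counts, times, v, i, t, k1):
    """First-order bookkeeping after one random molecule of i left/reacted v.

    Returns the departing molecule's own first-order time, for transfer into
    a destination volume or particle.  Conditioned on the stored minimum m,
    a uniformly chosen molecule holds m itself with probability 1/N while
    every other molecule's time is m + Exp(k1) by memorylessness, so all
    redraws are anchored at m, never at the current time.
    counts[v, i] must still hold the pre-removal N.
    """
    n = counts[v, i]
    if k1[i] <= 0.0 or n <= 0:
        return INF
    m = times[v, i]
    if np.random.random() * n < 1.0:
        # the departing molecule held the stored minimum: the remaining
        # N-1 molecules are each m + Exp(k1), their minimum m + Exp((N-1) k1)
        times[v, i] = m + exp_draw((n - 1) * k1[i])
        return m
    return m + exp_draw(k1[i])


@njit(cache=False)
def fo_fire_min(counts, times, v, i, t, k1):
    """The stored minimum fired: redraw from the remaining N-1 aggregate."""
    n = counts[v, i]  # pre-removal count
    times[v, i] = t + exp_draw((n - 1) * k1[i])


@njit(cache=False)
def fo_add_one(times, v, i, t, k1):
    """A molecule of species i appeared in v at t: min-merge a fresh time."""
    if k1[i] > 0.0:
        cand = t + exp_draw(k1[i])
        if cand < times[v, i]:
            times[v, i] = cand


@njit(cache=False)
def gillespie_advance(t_h, max_events,
                      counts, times, prop, vmin_t, vmin_s, heap, hpos,
                      neighbor, cumg, vfree, mode,
                      k1, dvec,
                      fo_off, fo_rate, fo_delta,
                      r2_a, r2_b, r2_kvol, r2_delta,
                      rs_sp, rs_prod, rs_surface, rs_rate, pools,
                      counters):
    """Event-driven population dynamics until the horizon or a bridge event.

    Pops the earliest stored event over all subvolumes, executes it, rescales
    the affected stored times and reorders the schedule.  Returns
    ``(code, volume, slot, aux)``:

    - ``ADV_HORIZON``: all pending events lie beyond ``t_h``;
    - ``ADV_JUMP_BRIDGE``: the pending jump (``aux`` = direction) targets a
      volume where the species is particle-mode; nothing was executed;
    - ``ADV_FO_BRIDGE`` / ``ADV_R2_BRIDGE``: the pending reaction (``aux`` =
      drawn first-order channel / bimolecular channel) creates a product in
      a particle-mode slot; nothing was executed;
    - ``ADV_MAX_EVENTS``: event budget exhausted.

    ``counters`` accumulates executed events as [first-order, jump,
    bimolecular, surface-transfer].
    """
    M = counts.shape[1]
    R2 = r2_a.shape[0]
    events = 0
    while True:
        if events >= max_events:
            return ADV_MAX_EVENTS, -1, -1, -1
        v = heap[0]
        t = vmin_t[v]
        if t > t_h:
            return ADV_HORIZON, -1, -1, -1
        slot = vmin_s[v]
        gsum_v = cumg[v, 5]

        if slot < M:
            # first-order event of species i: resolve the channel now
            i = slot
            r = np.random.random() * k1[i]
            c = fo_off[i]
            acc = fo_rate[c]
            while acc < r and c + 1 < fo_off[i + 1]:
                c += 1
                acc += fo_rate[c]
            for s2 in range(M):
                add = fo_delta[c, s2] + (1 if s2 == i else 0)
                if add > 0 and mode[v, s2] == 0:
                    return ADV_FO_BRIDGE, v, slot, c
            fo_fire_min(counts, times, v, i, t, k1)
            for s2 in range(M):
                add = fo_delta[c, s2] + (1 if s2 == i else 0)
                counts[v, s2] += fo_delta[c, s2]
                for _ in range(add):
                    fo_add_one(times, v, s2, t, k1)
            rescale_volume(counts, times, prop, v, t, slot,
                           k1, dvec, cumg[:, 5], vfree, r2_a, r2_b, r2_kvol, rs_sp, rs_rate)
            update_volume_min(times, vmin_t, vmin_s, heap, hpos, v)
            counters[0] += 1

        elif slot < 2 * M:
            # diffusion jump of species i; destination drawn by face factors
            i = slot - M
            r = np.random.random() * gsum_v
            d = 0
            while d < 5 and r >= cumg[v, d]:
                d += 1
            nb = neighbor[v, d]
            if nb < 0 or counts[v, i] <= 0:
                # closed face (numerical tie) or stale slot: just redraw
                rescale_volume(counts, times, prop, v, t, slot,
                               k1, dvec, cumg[:, 5], vfree, r2_a, r2_b, r2_kvol, rs_sp, rs_rate)
                update_volume_min(times, vmin_t, vmin_s, heap, hpos, v)
                continue
            if mode[nb, i] == 0:
                return ADV_JUMP_BRIDGE, v, slot, d
            jumper_time = fo_remove_one(counts, times, v, i, t, k1)
            counts[v, i] -= 1
            counts[nb, i] += 1
            if jumper_time < times[nb, i]:
                times[nb, i] = jumper_time
            rescale_volume(counts, times, prop, v, t, slot,
                           k1, dvec, cumg[:, 5], vfree, r2_a, r2_b, r2_kvol, rs_sp, rs_rate)
            update_volume_min(times, vmin_t, vmin_s, heap, hpos, v)
            rescale_volume(counts, times, prop, nb, t, -1,
                           k1, dvec, cumg[:, 5], vfree, r2_a, r2_b, r2_kvol, rs_sp, rs_rate)
            update_volume_min(times, vmin_t, vmin_s, heap, hpos, nb)
            counters[1] += 1

        elif slot < 2 * M + R2:
            # bimolecular channel
            c = slot - 2 * M
            a = r2_a[c]
            b = r2_b[c]
            for s2 in range(M):
                add = r2_delta[c, s2] + (1 if s2 == a else 0) + (1 if s2 == b else 0)
                if add > 0 and mode[v, s2] == 0:
                    return ADV_R2_BRIDGE, v, slot, c
            fo_remove_one(counts, times, v, a, t, k1)
            counts[v, a] -= 1
            fo_remove_one(counts, times, v, b, t, k1)
            counts[v, b] -= 1
            for s2 in range(M):
                # reactants were decremented above; what remains is the
                # product copies: delta + the reactant corrections
                add = r2_delta[c, s2] + (1 if s2 == a else 0) + (1 if s2 == b else 0)
                counts[v, s2] += add
                for _ in range(add):
                    fo_add_one(times, v, s2, t, k1)
            rescale_volume(counts, times, prop, v, t, slot,
                           k1, dvec, cumg[:, 5], vfree, r2_a, r2_b, r2_kvol, rs_sp, rs_rate)
            update_volume_min(times, vmin_t, vmin_s, heap, hpos, v)
            counters[2] += 1

        else:
            # surface transfer: molecule absorbed into the nucleus/membrane pool
            q = slot - 2 * M - R2
            i = rs_sp[q]
            fo_remove_one(counts, times, v, i, t, k1)
            counts[v, i] -= 1
            pools[rs_surface[q], rs_prod[q]] += 1
            rescale_volume(counts, times, prop, v, t, slot,
                           k1, dvec, cumg[:, 5], vfree, r2_a, r2_b, r2_kvol, rs_sp, rs_rate)
            update_volume_min(times, vmin_t, vmin_s, heap, hpos, v)
            counters[3] += 1

        events += 1


# -- particle engine ----------------------------------------------------------

STEP_MOVED = 0        # normal move (or rejected: stays in place)
STEP_IMPORTED = 1     # absorbed through the nuclear envelope
STEP_TO_POPULATION = 2  # walked into a volume where its species is population-mode
STEP_ADSORBED = 3     # bound to the plasma membrane
STEP_CORRUPT = -1     # particle found in an illegal position


@njit(cache=False)
def step_particles_cell(pos, species, alive, normals, uniforms,
                        sd_step, r_cell_eff, r_nuc,
                        p_import, p_adsorb, p_handover,
                        x0, l, vol_id, mode,
                        codes, target_vol, spherical, periodic, box):
    """One Brownian step with boundary rejection for all live particles.

    Proposed moves ending outside the cell, inside the nucleus (failed
    import), or in an inaccessible voxel are rejected: the particle keeps
    its position for this step.  Surface crossings are converted into
    absorption attempts with the per-species probabilities ``p_import`` /
    ``p_adsorb``; one uniform per particle decides the attempt.

    codes/target_vol are output arrays (n,), target_vol = destination volume
    for STEP_TO_POPULATION particles.
    """
    n = pos.shape[0]
    nx, ny, nz = vol_id.shape
    for j in range(n):
        codes[j] = STEP_MOVED
        target_vol[j] = -1
        if not alive[j]:
            continue
        i = species[j]
        sd = sd_step[i]
        px = pos[j, 0] + sd * normals[j, 0]
        py = pos[j, 1] + sd * normals[j, 1]
        pz = pos[j, 2] + sd * normals[j, 2]
        if spherical:
            r_new = np.sqrt(px * px + py * py + pz * pz)
            r_old = np.sqrt(pos[j, 0] ** 2 + pos[j, 1] ** 2 + pos[j, 2] ** 2)
            if r_old > r_cell_eff[i] + 1e-9 or (r_nuc > 0.0 and r_old < r_nuc - 1e-9):
                codes[j] = STEP_CORRUPT
                continue
            if r_new >= r_cell_eff[i]:
                # plasma-membrane crossing attempt
                if p_adsorb[i] > 0.0 and uniforms[j] < p_adsorb[i]:
                    codes[j] = STEP_ADSORBED
                    alive[j] = False
                continue  # rejected: stay in place
            if r_nuc > 0.0 and r_new <= r_nuc:
                if p_import[i] > 0.0 and uniforms[j] < p_import[i]:
                    codes[j] = STEP_IMPORTED
                    alive[j] = False
                continue  # rejected at the nuclear envelope
        elif periodic:
            px = px % box[0]
            py = py % box[1]
            pz = pz % box[2]
        ix = int(np.floor((px - x0[0]) / l))
        iy = int(np.floor((py - x0[1]) / l))
        iz = int(np.floor((pz - x0[2]) / l))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            continue  # outside the bounding box: reject
        vid = vol_id[ix, iy, iz]
        if vid < 0:
            continue  # obstacle voxel or clipped-away sliver: reject
        if mode[vid, i] == 1:
            # partially absorbing level interface: accept the crossing with
            # the probability that matches the lattice exchange velocity D/l,
            # else reject the step (gross fluxes balance at equal densities)
            if uniforms[j] < p_handover[i]:
                pos[j, 0] = px
                pos[j, 1] = py
                pos[j, 2] = pz
                codes[j] = STEP_TO_POPULATION
                target_vol[j] = vid
                alive[j] = False
            continue
        pos[j, 0] = px
        pos[j, 1] = py
        pos[j, 2] = pz
    return 0


@njit(cache=False)
def detect_pairs(pos, species, alive, ids, reactive, sigma2, h, origin, dims,
                 out_a, out_b):
    """All particle pairs closer than their collision radius (strict <).

    Cell-list search with bins of edge ``h`` (>= max collision radius):
    candidate partners can only lie in the 27 surrounding bins.  ``sigma2``
    is the squared collision radius per species pair, negative for
    non-reactive pairs.  Pairs are emitted once with ids[a] < ids[b];
    returns the number written (caller enlarges the buffers if it equals
    their capacity).
    """
    n = pos.shape[0]
    sel = np.empty(n, dtype=np.int64)
    m = 0
    for j in range(n):
        if alive[j] and reactive[species[j]]:
            sel[m] = j
            m += 1
    if m < 2:
        return 0
    dy = dims[1]
    dz = dims[2]
    keys = np.empty(m, dtype=np.int64)
    for q in range(m):
        j = sel[q]
        cx = int((pos[j, 0] - origin[0]) / h)
        cy = int((pos[j, 1] - origin[1]) / h)
        cz = int((pos[j, 2] - origin[2]) / h)
        keys[q] = (cx * dy + cy) * dz + cz
    order = np.argsort(keys)
    skeys = keys[order]
    cap = out_a.shape[0]
    count = 0
    for qq in range(m):
        a = sel[order[qq]]
        ka = skeys[qq]
        cz0 = ka % dz
        rem = ka // dz
        cy0 = rem % dy
        cx0 = rem // dy
        for ddx in range(-1, 2):
            for ddy in range(-1, 2):
                # z is the fastest key dimension: the three z-neighbor bins
                # form one contiguous key run [nk0, nk0 + 2]
                nk0 = ((cx0 + ddx) * dy + (cy0 + ddy)) * dz + cz0 - 1
                nk1 = nk0 + 2
                lo = 0
                hi = m
                while lo < hi:
                    mid = (lo + hi) // 2
                    if skeys[mid] < nk0:
                        lo = mid + 1
                    else:
                        hi = mid
                p = lo
                while p < m and skeys[p] <= nk1:
                    b = sel[order[p]]
                    p += 1
                    if ids[b] <= ids[a]:
                        continue
                    s2 = sigma2[species[a], species[b]]
                    if s2 < 0.0:
                        continue
                    ddx2 = pos[a, 0] - pos[b, 0]
                    ddy2 = pos[a, 1] - pos[b, 1]
                    ddz2 = pos[a, 2] - pos[b, 2]
                    if ddx2 * ddx2 + ddy2 * ddy2 + ddz2 * ddz2 < s2:
                        if count < cap:
                            out_a[count] = a
                            out_b[count] = b
                        count += 1
    return count
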