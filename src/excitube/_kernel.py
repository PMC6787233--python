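"""Numba kernel for the lattice kinetic Monte Carlo engine.

One compiled routine advances the full exciton population: planting,
first-order decay, nearest-neighbour hopping, inter-wall transfer and the
instant-annihilation sweep.  All state lives in caller-allocated arrays so
that planting, single sweeps and long runs share the same physics code.

Conventions
-----------
* Positions are integer grid indices (circumferential, axial), periodic in
  both directions.  Layer 0 = inner wall, 1 = outer wall.
* Status codes: 0 alive, 1 decayed, 2 annihilated (deleted partner),
  3 censored (set by the Python wrapper at the horizon).
* The per-step update for each alive exciton uses one uniform draw ``u``
  for decay (``u < dt/tau``) and, if it survives, a second draw ``v``:
  ``v < H`` hop to one of the four neighbours (uniform choice);
  ``H <= v < H + k*dt`` attempt inter-wall transfer, performed only when
  the radially adjacent site is unoccupied; otherwise stay.
* After all excitons have moved, the annihilation sweep deletes one member
  of every same-layer pair closer (strictly) than the annihilation radius,
  iterating until no violating pair remains, so clusters of more than two
  excitons are resolved within the same step.
"""

import numpy as np
from numba import njit

STATUS_ALIVE = 0
STATUS_DECAYED = 1
STATUS_ANNIHILATED = 2
STATUS_CENSORED = 3


@njit(cache=True)
def _plant_layer(occ, n_circ, n_ax, n_exc, x, y, layer, lay, start):
    """Plant n_exc excitons uniformly without double occupancy (partial
    Fisher-Yates over the flattened site index)."""
    n_sites = n_circ * n_ax
    sites = np.arange(n_sites)
    for k in range(n_exc):
        j = k + np.random.randint(n_sites - k)
        tmp = sites[k]
        sites[k] = sites[j]
        sites[j] = tmp
        s = sites[k]
        xi = s // n_ax
        yi = s % n_ax
        idx = start + k
        x[idx] = xi
        y[idx] = yi
        layer[idx] = lay
        occ[xi, yi] += 1


@njit(cache=True)
def _record_sample(
    ptr, counts, msd_sum, msd_n, status, origin, layer, n_tot, n_same, ux, uy
):
    n = status.shape[0]
    acc = 0.0
    alive = 0
    for i in range(n):
        if status[i] != STATUS_ALIVE:
            continue
        alive += 1
        acc += float(ux[i]) * ux[i] + float(uy[i]) * uy[i]
        idx = origin[i] * 8 + layer[i] * 4
        if n_same[i] > 0:
            idx += 2
        if n_tot[i] > 0:
            idx += 1
        counts[ptr, idx] += 1
    msd_sum[ptr] = acc
    msd_n[ptr] = alive


@njit(cache=True)
def _sweep(
    t_ps,
    r0sq,
    n_circ_in,
    n_circ_out,
    n_ax,
    off_dx,
    off_dy,
    x,
    y,
    layer,
    status,
    origin,
    n_surv,
    n_tot,
    n_same,
    term_time,
    term_layer,
    occ_in,
    occ_out,
    head_in,
    head_out,
    nxt,
    order,
    ev_step,
    ev_deleted,
    ev_survivor,
    ev_layer,
    n_events,
    abs_step,
):
    """Annihilation sweep: delete until no same-layer pair is within R0."""
    n = status.shape[0]
    n_off = off_dx.shape[0]
    # rebuild cell linked lists from alive excitons
    for i in range(n):
        if status[i] == STATUS_ALIVE:
            if layer[i] == 0:
                head_in[x[i], y[i]] = -1
            else:
                head_out[x[i], y[i]] = -1
    for i in range(n):
        if status[i] == STATUS_ALIVE:
            if layer[i] == 0:
                nxt[i] = head_in[x[i], y[i]]
                head_in[x[i], y[i]] = i
            else:
                nxt[i] = head_out[x[i], y[i]]
                head_out[x[i], y[i]] = i
    changed = True
    while changed:
        changed = False
        for oi in range(n):
            i = order[oi]
            if status[i] != STATUS_ALIVE:
                continue
            lay = layer[i]
            nc = n_circ_in if lay == 0 else n_circ_out
            cnt = 0
            pick = -1
            for o in range(n_off):
                cx = (x[i] + off_dx[o]) % nc
                cy = (y[i] + off_dy[o]) % n_ax
                j = head_in[cx, cy] if lay == 0 else head_out[cx, cy]
                while j != -1:
                    if j != i and status[j] == STATUS_ALIVE and layer[j] == lay:
                        di = abs(x[i] - x[j])
                        if nc - di < di:
                            di = nc - di
                        dj = abs(y[i] - y[j])
                        if n_ax - dj < dj:
                            dj = n_ax - dj
                        if di * di + dj * dj < r0sq:
                            cnt += 1
                            if np.random.random() * cnt < 1.0:
                                pick = j
                    j = nxt[j]
            if pick >= 0:
                if np.random.random() < 0.5:
                    loser = i
                    winner = pick
                else:
                    loser = pick
                    winner = i
                status[loser] = STATUS_ANNIHILATED
                term_time[loser] = t_ps
                term_layer[loser] = layer[loser]
                if layer[loser] == 0:
                    occ_in[x[loser], y[loser]] -= 1
                else:
                    occ_out[x[loser], y[loser]] -= 1
                n_tot[i] += 1
                n_tot[pick] += 1
                if origin[i] == origin[pick]:
                    n_same[i] += 1
                    n_same[pick] += 1
                n_surv[winner] += 1
                ev_step[n_events] = abs_step
                ev_deleted[n_events] = loser
                ev_survivor[n_events] = winner
                ev_layer[n_events] = lay
                n_events += 1
                changed = True
    return n_events


@njit(cache=True)
def kmc_kernel(
    seed,
    plant,
    initial_sweep,
    n_steps,
    step_offset,
    sample_steps,
    dt,
    p_decay,
    hop_prob,
    k_io,
    k_oi,
    r0,
    n_circ_in,
    n_circ_out,
    n_ax,
    n_in,
    n_out,
    map_io,
    map_oi,
    off_dx,
    off_dy,
    x,
    y,
    layer,
    status,
    origin,
    ox,
    oy,
    ux,
    uy,
    n_surv,
    n_tot,
    n_same,
    n_hops,
    n_transfers,
    term_time,
    term_layer,
    occ_in,
    occ_out,
    head_in,
    head_out,
    nxt,
    counts,
    msd_sum,
    msd_n,
    ev_step,
    ev_deleted,
    ev_survivor,
    ev_layer,
    n_events_start,
):
    np.random.seed(seed)
    n = status.shape[0]
    double = n_circ_out > 0
    r0sq = r0 * r0
    p_io = k_io * dt
    p_oi = k_oi * dt
    occ_in[:, :] = 0
    occ_out[:, :] = 0
    n_events = n_events_start

    if plant:
        _plant_layer(occ_in, n_circ_in, n_ax, n_in, x, y, layer, 0, 0)
        if double:
            _plant_layer(occ_out, n_circ_out, n_ax, n_out, x, y, layer, 1, n_in)
        for i in range(n):
            status[i] = STATUS_ALIVE
            origin[i] = layer[i]
            ox[i] = x[i]
            oy[i] = y[i]
            ux[i] = 0
            uy[i] = 0
            n_surv[i] = 0
            n_tot[i] = 0
            n_same[i] = 0
            n_hops[i] = 0
            n_transfers[i] = 0
            term_time[i] = np.nan
            term_layer[i] = -1
    else:
        for i in range(n):
            if status[i] == STATUS_ALIVE:
                if layer[i] == 0:
                    occ_in[x[i], y[i]] += 1
                else:
                    occ_out[x[i], y[i]] += 1

    order = np.arange(n)

    if initial_sweep and r0 > 0.0:
        np.random.shuffle(order)
        t_ps = step_offset * dt * 1e-3
        n_events = _sweep(
            t_ps, r0sq, n_circ_in, n_circ_out, n_ax, off_dx, off_dy,
            x, y, layer, status, origin, n_surv, n_tot, n_same,
            term_time, term_layer, occ_in, occ_out, head_in, head_out,
            nxt, order, ev_step, ev_deleted, ev_survivor, ev_layer,
            n_events, step_offset,
        )

    n_samp = sample_steps.shape[0]
    ptr = 0
    while ptr < n_samp and sample_steps[ptr] < step_offset:
        ptr += 1
    if ptr < n_samp and sample_steps[ptr] == step_offset:
        _record_sample(
            ptr, counts, msd_sum, msd_n, status, origin, layer, n_tot, n_same, ux, uy
        )
        ptr += 1

    for s in range(1, n_steps + 1):
        abs_step = step_offset + s
        t_ps = abs_step * dt * 1e-3
        np.random.shuffle(order)
        for oi in range(n):
            i = order[oi]
            if status[i] != STATUS_ALIVE:
                continue
            u = np.random.random()
            if u < p_decay:
                status[i] = STATUS_DECAYED
                term_time[i] = t_ps
                term_layer[i] = layer[i]
                if layer[i] == 0:
                    occ_in[x[i], y[i]] -= 1
                else:
                    occ_out[x[i], y[i]] -= 1
                continue
            v = np.random.random()
            if v < hop_prob:
                d = np.random.randint(4)
                dx = 0
                dy = 0
                if d == 0:
                    dx = 1
                elif d == 1:
                    dx = -1
                elif d == 2:
                    dy = 1
                else:
                    dy = -1
                if layer[i] == 0:
                    occ_in[x[i], y[i]] -= 1
                    x[i] = (x[i] + dx) % n_circ_in
                    y[i] = (y[i] + dy) % n_ax
                    occ_in[x[i], y[i]] += 1
                else:
                    occ_out[x[i], y[i]] -= 1
                    x[i] = (x[i] + dx) % n_circ_out
                    y[i] = (y[i] + dy) % n_ax
                    occ_out[x[i], y[i]] += 1
                ux[i] += dx
                uy[i] += dy
                n_hops[i] += 1
            elif double:
                if layer[i] == 0:
                    if v < hop_prob + p_io:
                        ti = map_io[x[i]]
                        if occ_out[ti, y[i]] == 0:
                            occ_in[x[i], y[i]] -= 1
                            occ_out[ti, y[i]] += 1
                            x[i] = ti
                            layer[i] = 1
                            n_transfers[i] += 1
                else:
                    if v < hop_prob + p_oi:
                        ti = map_oi[x[i]]
                        if occ_in[ti, y[i]] == 0:
                            occ_out[x[i], y[i]] -= 1
                            occ_in[ti, y[i]] += 1
                            x[i] = ti
                            layer[i] = 0
                            n_transfers[i] += 1
        if r0 > 0.0:
            n_events = _sweep(
                t_ps, r0sq, n_circ_in, n_circ_out, n_ax, off_dx, off_dy,
                x, y, layer, status, origin, n_surv, n_tot, n_same,
                term_time, term_layer, occ_in, occ_out, head_in, head_out,
                nxt, order, ev_step, ev_deleted, ev_survivor, ev_layer,
                n_events, abs_step,
            )
        if ptr < n_samp and sample_steps[ptr] == abs_step:
            _record_sample(
                ptr, counts, msd_sum, msd_n, status, origin, layer,
                n_tot, n_same, ux, uy,
            )
            ptr += 1
    return n_events, ptr
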