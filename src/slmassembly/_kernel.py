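"""Numba-compiled rejection-free KMC inner loop.

One trajectory owns one explicit xorshift64* RNG state so that runs are
bit-reproducible and independent of how the driver chunks the step loop
(the closed-loop controller interrupts the loop at monitoring epochs and
shock boundaries).  Draw order per step: u for move selection, then u' for
the waiting time.

Energy and distance bookkeeping is incremental; every ``validate_every``
steps both are recomputed from scratch inside the kernel and the run aborts
on disagreement (> 1e-6 k_BT or any counter mismatch).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by run_chunk
STATUS_TIME = 0        # reached t_stop
STATUS_TCAP = 1        # global step cap reached
STATUS_ASSEMBLED = 2   # min_m d_m == 0 and stop_on_assembly
STATUS_CHUNK = 3       # chunk step budget exhausted
STATUS_BOOKKEEPING = -1
STATUS_STALLED = -2

RATE_SYMMETRIC = 0
RATE_METROPOLIS = 1

DIST_STATE_BONDS = 0
DIST_HAMMING = 1

_U64 = np.uint64


@njit(cache=True)
def seed_state(seed):
    """Initialise the RNG state from a small integer seed (splitmix64)."""
    st = np.empty(1, np.uint64)
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    st[0] = z
    return st


@njit(cache=True)
def next_uniform(st):
    """Uniform draw in (0, 1] advancing the state (xorshift64*)."""
    x = st[0]
    x ^= x >> _U64(12)
    x ^= x << _U64(25)
    x ^= x >> _U64(27)
    st[0] = x
    z = (x * _U64(0x2545F4914F6CDD1D)) >> _U64(11)
    return (np.float64(z) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _pair_j(tadj, sa, sb, a, b, j_strong, j_weak):
    return j_weak + 0.5 * (j_strong - j_weak) * (
        np.float64(tadj[sa, a, b]) + np.float64(tadj[sb, a, b])
    )


@njit(cache=True)
def _recompute(pos, occ, states, tadj, j_strong, j_weak, out_ov, out_sat, out_mism):
    """Full recomputation of E, board bond count and distance counters."""
    n = pos.shape[0]
    mt = tadj.shape[0]
    L = occ.shape[0]
    e = 0.0
    bonds = 0
    out_ov[:] = 0
    out_sat[:] = 0
    out_mism[:] = 0
    for a in range(n):
        r = pos[a, 0]
        c = pos[a, 1]
        # scan right and down only: each unordered pair once
        for k in range(2):
            rr = r + (1 if k == 0 else 0)
            cc = c + (1 if k == 1 else 0)
            if rr < L and cc < L:
                b = occ[rr, cc]
                if b >= 0:
                    e += _pair_j(
                        tadj, states[a], states[b], a, b, j_strong, j_weak
                    )
                    bonds += 1
                    for m in range(mt):
                        if tadj[m, a, b] == 1:
                            out_ov[m] += 1
                            if states[a] == m and states[b] == m:
                                out_sat[m] += 1
    for m in range(mt):
        cnt = 0
        for a in range(n):
            if states[a] != m:
                cnt += 1
        out_mism[m] = cnt
    return e, bonds


@njit(cache=True, inline="always")
def _distance(m, tbonds, bonds_board, ov, sat, mism, dist_conv):
    credit = ov[m] if dist_conv == DIST_HAMMING else sat[m]
    return 2 * (tbonds[m] + bonds_board - 2 * credit) + mism[m]


@njit(cache=True)
def run_chunk(
    pos,            # (N,2) int64, in/out
    occ,            # (L,L) int64, in/out
    states,         # (N,) int64 0-based, in/out
    tadj,           # (MT,N,N) uint8
    tbonds,         # (MT,) int64 unordered bond counts
    j_strong, j_weak, r0,
    rate_law, dist_conv,
    fstate,         # float64[2]: [energy, time], in/out
    istate,         # int64[2]: [global step, board bond count], in/out
    ov, sat, mism,  # (MT,) int64 distance counters, in/out
    t_cap,          # global step cap
    chunk_steps,    # step budget for this call
    t_stop,         # stop once simulated time >= t_stop
    stop_on_assembly,
    rng,            # uint64[1]
    rec_t, rec_e, rec_step, rec_d,  # record buffers; rec_d (cap, MT)
    rec_n,          # int64[1] records written
    stride,
    rec_code,       # int64 buffer for encoded micro-states (len 0 disables)
    fa_time,        # float64[1], NaN until first assembly
    validate_every,
):
    n = pos.shape[0]
    mt = tadj.shape[0]
    L = occ.shape[0]
    ntot = 4 * n + (mt - 1) * n
    rates = np.empty(ntot, np.float64)
    des = np.empty(ntot, np.float64)
    encode = rec_code.shape[0] > 0

    steps_done = 0
    while True:
        if fstate[1] >= t_stop:
            return STATUS_TIME
        if istate[0] >= t_cap:
            return STATUS_TCAP
        if steps_done >= chunk_steps:
            return STATUS_CHUNK

        # --- enumerate translation moves (particle-major, direction-minor)
        q_total = 0.0
        for a in range(n):
            r = pos[a, 0]
            c = pos[a, 1]
            sa = states[a]
            e_old = 0.0
            for k in range(4):
                rr = r + (-1 if k == 0 else (1 if k == 1 else 0))
                cc = c + (-1 if k == 2 else (1 if k == 3 else 0))
                if 0 <= rr < L and 0 <= cc < L:
                    b = occ[rr, cc]
                    if b >= 0:
                        e_old += _pair_j(tadj, sa, states[b], a, b, j_strong, j_weak)
            for k in range(4):
                rr = r + (-1 if k == 0 else (1 if k == 1 else 0))
                cc = c + (-1 if k == 2 else (1 if k == 3 else 0))
                idx = 4 * a + k
                if rr < 0 or rr >= L or cc < 0 or cc >= L or occ[rr, cc] >= 0:
                    rates[idx] = 0.0
                    des[idx] = 0.0
                else:
                    e_new = 0.0
                    for k2 in range(4):
                        r2 = rr + (-1 if k2 == 0 else (1 if k2 == 1 else 0))
                        c2 = cc + (-1 if k2 == 2 else (1 if k2 == 3 else 0))
                        if 0 <= r2 < L and 0 <= c2 < L:
                            b = occ[r2, c2]
                            if b >= 0 and b != a:
                                e_new += _pair_j(
                                    tadj, sa, states[b], a, b, j_strong, j_weak
                                )
                    de = e_new - e_old
                    if rate_law == RATE_SYMMETRIC:
                        rt = r0 * np.exp(-0.5 * de)
                    else:
                        rt = r0 * min(1.0, np.exp(-de))
                    rates[idx] = rt
                    des[idx] = de
                    q_total += rt

        # --- state-switch moves (particle-major, ascending new state)
        if mt > 1:
            pref = 4.0 * r0 / (mt - 1)
            half = 0.5 * (j_strong - j_weak)
            for a in range(n):
                r = pos[a, 0]
                c = pos[a, 1]
                sa = states[a]
                base = 4 * n + a * (mt - 1)
                k = 0
                for m2 in range(mt):
                    if m2 == sa:
                        continue
                    de = 0.0
                    for k2 in range(4):
                        rr = r + (-1 if k2 == 0 else (1 if k2 == 1 else 0))
                        cc = c + (-1 if k2 == 2 else (1 if k2 == 3 else 0))
                        if 0 <= rr < L and 0 <= cc < L:
                            b = occ[rr, cc]
                            if b >= 0:
                                de += half * (
                                    np.float64(tadj[m2, a, b])
                                    - np.float64(tadj[sa, a, b])
                                )
                    if rate_law == RATE_SYMMETRIC:
                        qr = pref * np.exp(-0.5 * de)
                    else:
                        qr = pref * min(1.0, np.exp(-de))
                    rates[base + k] = qr
                    des[base + k] = de
                    q_total += qr
                    k += 1

        if q_total <= 0.0:
            return STATUS_STALLED

        # --- select move: smallest I with R_{I-1} < u Q <= R_I
        u = next_uniform(rng)
        uq = u * q_total
        acc = 0.0
        sel = -1
        for i in range(ntot):
            if rates[i] > 0.0:
                acc += rates[i]
                if acc >= uq:
                    sel = i
                    break
        if sel < 0:  # float round-off at the top end: last positive-rate move
            for i in range(ntot - 1, -1, -1):
                if rates[i] > 0.0:
                    sel = i
                    break

        u2 = next_uniform(rng)
        dt = -np.log(u2) / q_total

        # --- apply the move, updating counters incrementally
        if sel < 4 * n:
            a = sel // 4
            k = sel % 4
            r = pos[a, 0]
            c = pos[a, 1]
            sa = states[a]
            nr = r + (-1 if k == 0 else (1 if k == 1 else 0))
            nc = c + (-1 if k == 2 else (1 if k == 3 else 0))
            for k2 in range(4):
                rr = r + (-1 if k2 == 0 else (1 if k2 == 1 else 0))
                cc = c + (-1 if k2 == 2 else (1 if k2 == 3 else 0))
                if 0 <= rr < L and 0 <= cc < L:
                    b = occ[rr, cc]
                    if b >= 0:
                        istate[1] -= 1
                        for m in range(mt):
                            if tadj[m, a, b] == 1:
                                ov[m] -= 1
                        sb = states[b]
                        if sb == sa and tadj[sa, a, b] == 1:
                            sat[sa] -= 1
            occ[r, c] = -1
            for k2 in range(4):
                rr = nr + (-1 if k2 == 0 else (1 if k2 == 1 else 0))
                cc = nc + (-1 if k2 == 2 else (1 if k2 == 3 else 0))
                if 0 <= rr < L and 0 <= cc < L:
                    b = occ[rr, cc]
                    if b >= 0:
                        istate[1] += 1
                        for m in range(mt):
                            if tadj[m, a, b] == 1:
                                ov[m] += 1
                        sb = states[b]
                        if sb == sa and tadj[sa, a, b] == 1:
                            sat[sa] += 1
            occ[nr, nc] = a
            pos[a, 0] = nr
            pos[a, 1] = nc
        else:
            j = sel - 4 * n
            a = j // (mt - 1)
            k = j % (mt - 1)
            sa = states[a]
            m2 = -1
            kk = 0
            for m in range(mt):
                if m == sa:
                    continue
                if kk == k:
                    m2 = m
                    break
                kk += 1
            r = pos[a, 0]
            c = pos[a, 1]
            mism[sa] += 1
            mism[m2] -= 1
            for k2 in range(4):
                rr = r + (-1 if k2 == 0 else (1 if k2 == 1 else 0))
                cc = c + (-1 if k2 == 2 else (1 if k2 == 3 else 0))
                if 0 <= rr < L and 0 <= cc < L:
                    b = occ[rr, cc]
                    if b >= 0:
                        sb = states[b]
                        if sb == sa and tadj[sa, a, b] == 1:
                            sat[sa] -= 1
                        if sb == m2 and tadj[m2, a, b] == 1:
                            sat[m2] += 1
            states[a] = m2

        fstate[0] += des[sel]
        fstate[1] += dt
        istate[0] += 1
        steps_done += 1

        # --- distances, first assembly, recording
        dmin = np.int64(2 ** 62)
        for m in range(mt):
            dm = _distance(m, tbonds, istate[1], ov, sat, mism, dist_conv)
            if dm < dmin:
                dmin = dm
        if dmin == 0 and np.isnan(fa_time[0]):
            fa_time[0] = fstate[1]

        if istate[0] % stride == 0:
            i = rec_n[0]
            rec_t[i] = fstate[1]
            rec_e[i] = fstate[0]
            rec_step[i] = istate[0]
            for m in range(mt):
                rec_d[i, m] = _distance(
                    m, tbonds, istate[1], ov, sat, mism, dist_conv
                )
            if encode:
                code = np.int64(0)
                for a in range(n):
                    code = code * (L * L) + (pos[a, 0] * L + pos[a, 1])
                for a in range(n):
                    code = code * mt + states[a]
                rec_code[i] = code
            rec_n[0] += 1

        if dmin == 0 and stop_on_assembly:
            return STATUS_ASSEMBLED

        # --- periodic self-check of the incremental bookkeeping
        if validate_every > 0 and istate[0] % validate_every == 0:
            chk_ov = np.empty(mt, np.int64)
            chk_sat = np.empty(mt, np.int64)
            chk_mism = np.empty(mt, np.int64)
            e_full, bonds_full = _recompute(
                pos, occ, states, tadj, j_strong, j_weak, chk_ov, chk_sat, chk_mism
            )
            if abs(e_full - fstate[0]) > 1e-6 or bonds_full != istate[1]:
                return STATUS_BOOKKEEPING
            for m in range(mt):
                if (
                    chk_ov[m] != ov[m]
                    or chk_sat[m] != sat[m]
                    or chk_mism[m] != mism[m]
                ):
                    return STATUS_BOOKKEEPING
            fstate[0] = e_full  # kill float drift
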