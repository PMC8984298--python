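"""Numba kernel for exact Gillespie event resolution within one window.

Agents live in flat slot arrays; a Fenwick (binary indexed) tree over the
per-slot total propensities gives O(log N) event selection and update.
Within a window every agent's rates are frozen at the nutrient value cached
at the last field update; daughters born mid-window sample the frozen field
at their own birth position. The clock draw that overshoots the window end
is discarded, which is exact for the frozen-rate (time-homogeneous) process.

All randomness comes from numba's global NumPy-compatible RNG; seed it once
per realization with :func:`seed_rng` for bit-reproducible runs.
"""

import math

import numpy as np
from numba import njit

# phase codes (match agents.Phase)
RED, YELLOW, GREEN = 0, 1, 2
# event type codes used for counters and optional event logs
EV_R2Y, EV_Y2G, EV_MITOSIS, EV_MIGRATION, EV_DEATH = 0, 1, 2, 3, 4
# kernel exit status
OK, GROW, BREACH = 0, 1, 2

# layout of the packed parameter vector
(P_RR, P_RY, P_RG, P_DMAX, P_DMIN, P_MMAX, P_MMIN, P_ETA1, P_ETA2, P_ETA3,
 P_CA, P_CM, P_CD, P_SIGMA, P_MU, P_L, P_H) = range(17)


def pack_params(p) -> np.ndarray:
    return np.array([p.Rr_max, p.Ry, p.Rg, p.d_max, p.d_min, p.m_max, p.m_min,
                     p.eta1, p.eta2, p.eta3, p.c_a, p.c_m, p.c_d,
                     p.sigma, p.mu, p.L, p.h], dtype=np.float64)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _hill(c, K, eta):
    ce = c ** eta
    return ce / (K ** eta + ce)


@njit(cache=True, inline="always")
def _propensities(phase, c, P):
    if phase == RED:
        rc = P[P_RR] * _hill(c, P[P_CA], P[P_ETA1])
    elif phase == YELLOW:
        rc = P[P_RY]
    else:
        rc = P[P_RG]
    m = (P[P_MMAX] - P[P_MMIN]) * _hill(c, P[P_CM], P[P_ETA2]) + P[P_MMIN]
    d = (P[P_DMAX] - P[P_DMIN]) * (1.0 - _hill(c, P[P_CD], P[P_ETA3])) + P[P_DMIN]
    return rc, m, d


@njit(cache=True, inline="always")
def _fen_update(tree, i, delta):
    i += 1
    n = tree.shape[0]
    while i < n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True, inline="always")
def _fen_prefix(tree, n):
    """Sum of slots [0, n)."""
    s = 0.0
    i = n
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


@njit(cache=True, inline="always")
def _fen_find(tree, u):
    """Largest slot index such that the prefix sum before it is <= u."""
    idx = 0
    n = tree.shape[0] - 1
    bit = 1
    while (bit << 1) <= n:
        bit <<= 1
    while bit:
        nxt = idx + bit
        if nxt <= n and tree[nxt] < u:
            idx = nxt
            u -= tree[nxt]
        bit >>= 1
    return idx


@njit(cache=True)
def build_tree(tree, phase, alive, cached_c, n_slots, P):
    tree[:] = 0.0
    for i in range(n_slots):
        if alive[i]:
            rc, m, d = _propensities(phase[i], cached_c[i], P)
            _fen_update(tree, i, rc + m + d)


@njit(cache=True, inline="always")
def _trilinear(cgrid, L, h, x, y, z):
    nI = cgrid.shape[0]
    gx = (x + 0.5 * L) / h
    gy = (y + 0.5 * L) / h
    gz = (z + 0.5 * L) / h
    ix = min(max(int(math.floor(gx)), 0), nI - 2)
    iy = min(max(int(math.floor(gy)), 0), nI - 2)
    iz = min(max(int(math.floor(gz)), 0), nI - 2)
    fx, fy, fz = gx - ix, gy - iy, gz - iz
    c = 0.0
    for dx in range(2):
        wx = fx if dx else 1.0 - fx
        for dy in range(2):
            wy = fy if dy else 1.0 - fy
            for dz in range(2):
                wz = fz if dz else 1.0 - fz
                c += wx * wy * wz * cgrid[ix + dx, iy + dy, iz + dz]
    return c


@njit(cache=True, inline="always")
def _random_direction():
    ct = 2.0 * np.random.random() - 1.0
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * np.random.random()
    return st * math.cos(phi), st * math.sin(phi), ct


@njit(cache=True)
def run_window(t, t_end, pos, phase, alive, cached_c, tree, n_slots, cgrid, P,
               death_pos, death_time, n_death, counts, log_t, log_k, n_log):
    """Resolve agent events from *t* to *t_end* with frozen per-agent rates.

    Returns ``(status, t, n_slots, n_death, n_log)``. ``GROW`` means the
    slot arrays are full and must be enlarged before resuming (no RNG draw
    is consumed for the pending event, so resuming is bit-exact).
    """
    half = 0.5 * P[P_L]
    cap = pos.shape[0]
    log_cap = log_t.shape[0]
    while True:
        if n_slots >= cap:
            return GROW, t, n_slots, n_death, n_log
        total = _fen_prefix(tree, cap)
        if total <= 1e-300:
            return OK, t_end, n_slots, n_death, n_log
        dt = -math.log1p(-np.random.random()) / total
        if t + dt > t_end:
            return OK, t_end, n_slots, n_death, n_log
        t += dt
        slot = _fen_find(tree, np.random.random() * total)
        if not alive[slot]:
            # float round-off in the tree descent can (with vanishing
            # probability) land on a zero-propensity slot; redraw
            continue
        c = cached_c[slot]
        ph = phase[slot]
        rc, m, d = _propensities(ph, c, P)
        tot_a = rc + m + d
        u = np.random.random() * tot_a
        if u < rc:
            # cell-cycle event
            if ph == RED:
                phase[slot] = YELLOW
                _fen_update(tree, slot, (P[P_RY] - rc))
                counts[EV_R2Y] += 1
                ev = EV_R2Y
            elif ph == YELLOW:
                phase[slot] = GREEN
                _fen_update(tree, slot, (P[P_RG] - P[P_RY]))
                counts[EV_Y2G] += 1
                ev = EV_Y2G
            else:
                # mitosis: parent slot becomes daughter 1, new slot daughter 2
                dx, dy, dz = _random_direction()
                s2 = 0.5 * P[P_SIGMA]
                x0, y0, z0 = pos[slot, 0], pos[slot, 1], pos[slot, 2]
                x1, y1, z1 = x0 + s2 * dx, y0 + s2 * dy, z0 + s2 * dz
                x2, y2, z2 = x0 - s2 * dx, y0 - s2 * dy, z0 - s2 * dz
                if (abs(x1) >= half or abs(y1) >= half or abs(z1) >= half
                        or abs(x2) >= half or abs(y2) >= half or abs(z2) >= half):
                    return BREACH, t, n_slots, n_death, n_log
                c1 = _trilinear(cgrid, P[P_L], P[P_H], x1, y1, z1)
                c2 = _trilinear(cgrid, P[P_L], P[P_H], x2, y2, z2)
                pos[slot, 0], pos[slot, 1], pos[slot, 2] = x1, y1, z1
                phase[slot] = RED
                cached_c[slot] = c1
                rc1, m1, d1 = _propensities(RED, c1, P)
                _fen_update(tree, slot, (rc1 + m1 + d1) - tot_a)
                new = n_slots
                pos[new, 0], pos[new, 1], pos[new, 2] = x2, y2, z2
                phase[new] = RED
                alive[new] = True
                cached_c[new] = c2
                rc2, m2, d2 = _propensities(RED, c2, P)
                _fen_update(tree, new, rc2 + m2 + d2)
                n_slots += 1
                counts[EV_MITOSIS] += 1
                ev = EV_MITOSIS
        elif u < rc + m:
            dx, dy, dz = _random_direction()
            x1 = pos[slot, 0] + P[P_MU] * dx
            y1 = pos[slot, 1] + P[P_MU] * dy
            z1 = pos[slot, 2] + P[P_MU] * dz
            if abs(x1) >= half or abs(y1) >= half or abs(z1) >= half:
                return BREACH, t, n_slots, n_death, n_log
            pos[slot, 0], pos[slot, 1], pos[slot, 2] = x1, y1, z1
            # cached_c (and hence the propensity) is kept until the next
            # field update, so the tree needs no change
            counts[EV_MIGRATION] += 1
            ev = EV_MIGRATION
        else:
            alive[slot] = False
            _fen_update(tree, slot, -tot_a)
            death_pos[n_death, 0] = pos[slot, 0]
            death_pos[n_death, 1] = pos[slot, 1]
            death_pos[n_death, 2] = pos[slot, 2]
            death_time[n_death] = t
            n_death += 1
            counts[EV_DEATH] += 1
            ev = EV_DEATH
        if n_log < log_cap:
            log_t[n_log] = t
            log_k[n_log] = ev
            n_log += 1
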