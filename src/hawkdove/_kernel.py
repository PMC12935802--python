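"""Compiled core of the lattice Gillespie simulation.

The direct-method loop is O(N) per event (patch chosen by scanning the
cached per-patch total rates) and only recomputes rates in the patches whose
event propensities actually changed: the event's patch, its neighbors (their
movement weights read the neighbor payoffs), and, for a movement event, the
destination's neighborhood.

Event slots per patch:
    0 hawk birth            3 dove birth
    1 hawk payoff death     4 dove payoff death
    2 hawk crowding death   5 dove crowding death
    6 hawk move left        8 dove move left
    7 hawk move right       9 dove move right

Status codes returned by :func:`run_lattice`:
    0 reached t_end, 1 population extinct (all patches empty),
    2 affine movement weight became non-positive (rule violation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

RULE_EXPONENTIAL = 0
RULE_AFFINE = 1

N_SLOTS = 10

STATUS_OK = 0
STATUS_EXTINCT = 1
STATUS_BAD_WEIGHT = 2


@njit(cache=True)
def patch_payoffs(u, v, i, T, R, S, P):
    """(p_H, p_D) at patch i; an empty patch pays 0 to both strategies."""
    tot = u[i] + v[i]
    if tot == 0:
        return 0.0, 0.0
    s = u[i] / tot
    return P * s + T * (1.0 - s), S * s + R * (1.0 - s)


@njit(cache=True)
def movement_weight(rule, w, p):
    """Neighbor weight f(w*p); nonpositive affine weights are a rule violation
    signalled by a negative return value."""
    z = w * p
    if rule == RULE_EXPONENTIAL:
        return np.exp(z)
    wt = 1.0 + z
    if wt <= 0.0:
        return -1.0
    return wt


@njit(cache=True)
def patch_rates(u, v, i, T, R, S, P, kappa, mu_u, mu_v, w_u, w_v, rule, out):
    """Fill the 10 event rates of patch i into ``out``. Returns False on an
    affine weight violation."""
    n = u.shape[0]
    p_h, p_d = patch_payoffs(u, v, i, T, R, S, P)
    tot = u[i] + v[i]
    out[0] = u[i] * p_h if p_h > 0.0 else 0.0
    out[1] = u[i] * (-p_h) if p_h < 0.0 else 0.0
    out[2] = kappa * u[i] * tot
    out[3] = v[i] * p_d if p_d > 0.0 else 0.0
    out[4] = v[i] * (-p_d) if p_d < 0.0 else 0.0
    out[5] = kappa * v[i] * tot

    has_left = i > 0
    has_right = i < n - 1
    wl_u = wr_u = 0.0
    wl_v = wr_v = 0.0
    if has_left:
        ph_l, pd_l = patch_payoffs(u, v, i - 1, T, R, S, P)
        wl_u = movement_weight(rule, w_u, ph_l)
        wl_v = movement_weight(rule, w_v, pd_l)
        if wl_u < 0.0 or wl_v < 0.0:
            return False
    if has_right:
        ph_r, pd_r = patch_payoffs(u, v, i + 1, T, R, S, P)
        wr_u = movement_weight(rule, w_u, ph_r)
        wr_v = movement_weight(rule, w_v, pd_r)
        if wr_u < 0.0 or wr_v < 0.0:
            return False
    su = wl_u + wr_u
    sv = wl_v + wr_v
    out[6] = mu_u * u[i] * (wl_u / su) if su > 0.0 else 0.0
    out[7] = mu_u * u[i] * (wr_u / su) if su > 0.0 else 0.0
    out[8] = mu_v * v[i] * (wl_v / sv) if sv > 0.0 else 0.0
    out[9] = mu_v * v[i] * (wr_v / sv) if sv > 0.0 else 0.0
    return True


@njit(cache=True)
def _refresh(u, v, i, T, R, S, P, kappa, mu_u, mu_v, w_u, w_v, rule, rates, ptot):
    ok = patch_rates(u, v, i, T, R, S, P, kappa, mu_u, mu_v, w_u, w_v, rule, rates[i])
    s = 0.0
    for k in range(N_SLOTS):
        s += rates[i, k]
    ptot[i] = s
    return ok


@njit(cache=True)
def run_lattice(
    u0,
    v0,
    T,
    R,
    S,
    P,
    kappa,
    mu_u,
    mu_v,
    w_u,
    w_v,
    rule,
    t_end,
    snap_dt,
    seed,
):
    """Exact Gillespie run; returns (snap_u, snap_v, snap_times, event_counts,
    status, t_stop).  Snapshots lie on a fixed grid 0, snap_dt, ..., t_end;
    after extinction the (empty) state is propagated to the remaining rows.
    """
    np.random.seed(seed)
    n = u0.shape[0]
    u = u0.copy()
    v = v0.copy()
    n_snaps = int(np.floor(t_end / snap_dt + 1e-9)) + 1
    snap_u = np.zeros((n_snaps, n), dtype=np.int64)
    snap_v = np.zeros((n_snaps, n), dtype=np.int64)
    snap_times = np.empty(n_snaps)
    for j in range(n_snaps):
        snap_times[j] = j * snap_dt
    event_counts = np.zeros(N_SLOTS, dtype=np.int64)

    rates = np.zeros((n, N_SLOTS))
    ptot = np.zeros(n)
    for i in range(n):
        if not _refresh(u, v, i, T, R, S, P, kappa, mu_u, mu_v, w_u, w_v, rule, rates, ptot):
            return snap_u, snap_v, snap_times, event_counts, STATUS_BAD_WEIGHT, 0.0
    lam = ptot.sum()

    t = 0.0
    snap_idx = 0
    snap_u[0] = u
    snap_v[0] = v
    snap_idx = 1
    n_events = 0
    status = STATUS_OK

    while True:
        if lam <= 1e-13:
            status = STATUS_EXTINCT
            break
        dt = -np.log(np.random.random()) / lam
        t_next = t + dt
        while snap_idx < n_snaps and snap_times[snap_idx] <= t_next:
            snap_u[snap_idx] = u
            snap_v[snap_idx] = v
            snap_idx += 1
        if t_next >= t_end:
            t = t_end
            break
        t = t_next

        r = np.random.random() * lam
        acc = 0.0
        i = n - 1
        for j in range(n):
            if acc + ptot[j] >= r:
                i = j
                break
            acc += ptot[j]
        r -= acc
        slot = N_SLOTS - 1
        acc = 0.0
        for k in range(N_SLOTS):
            if acc + rates[i, k] >= r:
                slot = k
                break
            acc += rates[i, k]

        dest = -1
        if slot == 0:
            u[i] += 1
        elif slot == 1 or slot == 2:
            u[i] -= 1
        elif slot == 3:
            v[i] += 1
        elif slot == 4 or slot == 5:
            v[i] -= 1
        elif slot == 6:
            dest = i - 1
            u[i] -= 1
            u[dest] += 1
        elif slot == 7:
            dest = i + 1
            u[i] -= 1
            u[dest] += 1
        elif slot == 8:
            dest = i - 1
            v[i] -= 1
            v[dest] += 1
        else:
            dest = i + 1
            v[i] -= 1
            v[dest] += 1
        event_counts[slot] += 1
        n_events += 1

        lo = i - 1 if i - 1 >= 0 else 0
        hi = i + 1 if i + 1 <= n - 1 else n - 1
        if dest >= 0:
            if dest - 1 < lo:
                lo = dest - 1 if dest - 1 >= 0 else 0
            if dest + 1 > hi:
                hi = dest + 1 if dest + 1 <= n - 1 else n - 1
        for j in range(lo, hi + 1):
            lam -= ptot[j]
            if not _refresh(u, v, j, T, R, S, P, kappa, mu_u, mu_v, w_u, w_v, rule, rates, ptot):
                return snap_u, snap_v, snap_times, event_counts, STATUS_BAD_WEIGHT, t
            lam += ptot[j]
        if n_events % 1_000_000 == 0:
            lam = ptot.sum()

    while snap_idx < n_snaps:
        snap_u[snap_idx] = u
        snap_v[snap_idx] = v
        snap_idx += 1
    return snap_u, snap_v, snap_times, event_counts, status, t
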