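"""Numba kernels for trail enumeration and FlatPERM growth.

Both kernels share the same incremental walk state:

* ``visits[site]`` — occupancy (0, 1 or 2),
* ``bx/by[site]`` — whether the bond toward +x / +y is used,
* ``ptype[site]`` — classification of the *first* completed passage
  (turn/partial, straight along x, straight along y), needed to recognise a
  crossing when the second passage leaves the site,
* ``straight[site]`` — whether the site is currently counted as a singly
  visited straight vertex (withdrawn if the site is visited again).

Sites are indexed on a dense ``L x L`` grid centred so that no walk of
``n_max`` steps can leave it.  Direction encoding is E=0, N=1, W=2, S=3
(matching :data:`trailzeros.walks.DIRECTIONS`).

Feature updates per step (head ``h``, new site ``s``):

* leaving a singly visited ``h`` straight creates a straight vertex
  (+1 straight) and records the passage axis;
* leaving a doubly visited ``h`` straight, when the first passage ran
  straight along the perpendicular axis, reclassifies the site from
  collision to crossing (the arrival had provisionally counted it as a
  collision — the endpoint-degenerate rule);
* arriving at a once-visited ``s`` counts a collision and withdraws any
  straight vertex previously counted there;
* a step with both endpoints on the wall (or a first visit to a wall site,
  under the site convention) counts a surface contact.

Everything is undone exactly on backtrack, so feature counters always equal
the from-scratch counts of :func:`trailzeros.walks.count_features` for the
current prefix — the test suite asserts this equivalence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# passage-type codes
PT_NONE = 0
PT_TURN = 1
PT_SX = 2  # first passage straight along x ({E,W} bonds)
PT_SY = 3  # first passage straight along y ({N,S} bonds)

# undo flags
F_STR_H = 1  # straight vertex created at departure site
F_PT = 2  # ptype recorded at departure site
F_XRECLASS = 4  # collision -> crossing reclassification at departure site
F_COLL = 8  # collision created at arrival site
F_STR_RM = 16  # straight vertex withdrawn at arrival site
F_SURF = 32  # surface contact counted

# flat-histogram binning modes
FLAT_NI = 0  # bin on total doubly visited sites n_coll + n_cross
FLAT_NS = 1  # bin on surface contacts (tau, p carried as growth weights)
FLAT_CC = 2  # bin on the (n_coll, n_cross) pair


@njit(cache=True, inline="always")
def _bond_used(bx, by, idx, d, stride):
    if d == 0:
        return bx[idx]
    if d == 1:
        return by[idx]
    if d == 2:
        return bx[idx - stride]
    return by[idx - 1]


@njit(cache=True, inline="always")
def _set_bond(bx, by, idx, d, stride, val):
    if d == 0:
        bx[idx] = val
    elif d == 1:
        by[idx] = val
    elif d == 2:
        bx[idx - stride] = val
    else:
        by[idx - 1] = val


@njit(cache=True, inline="always")
def _legal(idx, y, d, d_in, visits, bx, by, ptype, stride, visaw, surface):
    """Legality of appending direction d at head (idx, y); d_in = arriving step."""
    if d == 0:
        nidx = idx + stride
        ny = y
    elif d == 1:
        nidx = idx + 1
        ny = y + 1
    elif d == 2:
        nidx = idx - stride
        ny = y
    else:
        nidx = idx - 1
        ny = y - 1
    if surface and ny < 0:
        return False
    if _bond_used(bx, by, idx, d, stride):
        return False
    if visits[nidx] >= 2:
        return False
    if visaw and visits[idx] == 2 and d == d_in:
        # leaving straight through a doubly visited site: crossing iff the
        # first passage ran straight along the perpendicular axis
        if d == 0 or d == 2:
            if ptype[idx] == PT_SY:
                return False
        else:
            if ptype[idx] == PT_SX:
                return False
    return True


@njit(cache=True, inline="always")
def _apply_step(idx, y, d, d_in, visits, bx, by, ptype, straight, stride, feats,
                surface, site_conv):
    """Append direction d; returns (new_idx, new_y, flags).

    ``feats`` is the int64 array [n_coll, n_cross, n_straight, n_surface],
    updated in place.
    """
    flags = 0
    if visits[idx] == 1:
        # completing the first passage at the departure site
        if d_in >= 0 and d == d_in:
            straight[idx] = 1
            feats[2] += 1
            flags |= F_STR_H
            ptype[idx] = PT_SX if (d == 0 or d == 2) else PT_SY
        else:
            ptype[idx] = PT_TURN
        flags |= F_PT
    else:
        # completing the second passage
        if d == d_in:
            if (d == 0 or d == 2) and ptype[idx] == PT_SY:
                feats[0] -= 1
                feats[1] += 1
                flags |= F_XRECLASS
            elif (d == 1 or d == 3) and ptype[idx] == PT_SX:
                feats[0] -= 1
                feats[1] += 1
                flags |= F_XRECLASS
    _set_bond(bx, by, idx, d, stride, True)
    if d == 0:
        nidx = idx + stride
        ny = y
    elif d == 1:
        nidx = idx + 1
        ny = y + 1
    elif d == 2:
        nidx = idx - stride
        ny = y
    else:
        nidx = idx - 1
        ny = y - 1
    visits[nidx] += 1
    if visits[nidx] == 2:
        feats[0] += 1
        flags |= F_COLL
        if straight[nidx]:
            straight[nidx] = 0
            feats[2] -= 1
            flags |= F_STR_RM
    if surface:
        if site_conv:
            if visits[nidx] == 1 and ny == 0:
                feats[3] += 1
                flags |= F_SURF
        else:
            if y == 0 and ny == 0:
                feats[3] += 1
                flags |= F_SURF
    return nidx, ny, flags


@njit(cache=True, inline="always")
def _undo_step(prev_idx, cur_idx, d, flags, visits, bx, by, ptype, straight,
               stride, feats):
    if flags & F_SURF:
        feats[3] -= 1
    if flags & F_COLL:
        feats[0] -= 1
    if flags & F_STR_RM:
        straight[cur_idx] = 1
        feats[2] += 1
    visits[cur_idx] -= 1
    _set_bond(bx, by, prev_idx, d, stride, False)
    if flags & F_XRECLASS:
        feats[0] += 1
        feats[1] -= 1
    if flags & F_PT:
        ptype[prev_idx] = PT_NONE
    if flags & F_STR_H:
        straight[prev_idx] = 0
        feats[2] -= 1


@njit(cache=True)
def enumerate_kernel(n_max, visaw, surface, site_conv, first_dir, counts):
    """Exhaustive DFS over all trails of length <= n_max.

    ``counts`` is int64 with shape (n_max+1, mc, mx, ms, msu); every DFS
    node (walk prefix) of length n contributes 1 at its feature tuple.
    ``first_dir`` fixes the first step (symmetry reduction) when >= 0.
    """
    L = 2 * n_max + 3
    stride = L
    ntot = L * L
    visits = np.zeros(ntot, dtype=np.uint8)
    bx = np.zeros(ntot, dtype=np.bool_)
    by = np.zeros(ntot, dtype=np.bool_)
    ptype = np.zeros(ntot, dtype=np.uint8)
    straight = np.zeros(ntot, dtype=np.uint8)
    feats = np.zeros(4, dtype=np.int64)

    off = n_max + 1
    y0 = 0 if surface else off
    start = off * stride + y0
    visits[start] = 1

    # explicit DFS: next candidate direction per depth
    dirs = np.zeros(n_max + 1, dtype=np.int8)
    flags_st = np.zeros(n_max + 1, dtype=np.int8)
    idx_st = np.zeros(n_max + 1, dtype=np.int64)
    y_st = np.zeros(n_max + 1, dtype=np.int64)
    cand = np.zeros(n_max + 1, dtype=np.int8)

    idx_st[0] = start
    y_st[0] = 0  # y relative to the wall; only consulted in surface mode
    counts[0, 0, 0, 0, 0] += 1
    depth = 0
    cand[0] = 0
    while True:
        if depth < n_max:
            d = -1
            c = cand[depth]
            while c < 4:
                if first_dir >= 0 and depth == 0 and c != first_dir:
                    c += 1
                    continue
                d_in = dirs[depth - 1] if depth > 0 else -1
                if _legal(idx_st[depth], y_st[depth], c, d_in, visits, bx, by,
                          ptype, stride, visaw, surface):
                    d = c
                    break
                c += 1
            cand[depth] = c + 1
            if d >= 0:
                d_in = dirs[depth - 1] if depth > 0 else -1
                nidx, ny, fl = _apply_step(
                    idx_st[depth], y_st[depth], d, d_in, visits, bx, by, ptype,
                    straight, stride, feats, surface, site_conv)
                depth += 1
                dirs[depth - 1] = d
                flags_st[depth - 1] = fl
                idx_st[depth] = nidx
                y_st[depth] = ny
                cand[depth] = 0
                counts[depth, feats[0], feats[1], feats[2], feats[3]] += 1
                continue
        # backtrack
        if depth == 0:
            break
        d = dirs[depth - 1]
        fl = flags_st[depth - 1]
        _undo_step(idx_st[depth - 1], idx_st[depth], d, fl, visits, bx, by,
                   ptype, straight, stride, feats)
        depth -= 1


@njit(cache=True)
def flatperm_kernel(n_max, tours, visaw, surface, site_conv, flat_mode,
                    tau_c, tau_x, p_stiff, m2_cap, C, S, seed, tours_done,
                    steps_out):
    """FlatPERM tours with pruning/enrichment on a flat (n, bin) histogram.

    ``C[n, m]`` accumulates visit weights, ``S[n, m]`` visit counts; the
    coefficient estimate after T tours is ``C / T``.  ``flat_mode`` selects
    the bin: FLAT_NI (m = n_coll + n_cross), FLAT_NS (m = n_surface, with
    tau and p carried as growth weights), FLAT_CC (m = n_coll * m2_cap +
    n_cross, with p carried).  Reproducible given (seed, config);
    ``tours_done`` continues the tour numbering of a resumed state.
    ``steps_out[0]`` accumulates the number of growth steps taken.
    """
    np.random.seed(seed)
    L = 2 * n_max + 3
    stride = L
    ntot = L * L
    visits = np.zeros(ntot, dtype=np.uint8)
    bx = np.zeros(ntot, dtype=np.bool_)
    by = np.zeros(ntot, dtype=np.bool_)
    ptype = np.zeros(ntot, dtype=np.uint8)
    straight = np.zeros(ntot, dtype=np.uint8)
    feats = np.zeros(4, dtype=np.int64)

    off = n_max + 1
    start = off * stride + (0 if surface else off)
    visits[start] = 1

    dirs = np.zeros(n_max + 1, dtype=np.int8)
    flags_st = np.zeros(n_max + 1, dtype=np.int8)
    idx_st = np.zeros(n_max + 1, dtype=np.int64)
    y_st = np.zeros(n_max + 1, dtype=np.int64)
    cands = np.zeros(4, dtype=np.int8)

    cap = 4 * (n_max + 2)
    st_n = np.zeros(cap, dtype=np.int64)
    st_w = np.zeros(cap, dtype=np.float64)

    carry_p = p_stiff != 1.0
    nsteps = 0

    for tour in range(tours):
        t = tours_done + tour + 1
        C[0, 0] += 1.0
        S[0, 0] += 1
        sp = 0
        st_n[sp] = 0
        st_w[sp] = 1.0
        sp += 1
        cur_len = 0
        idx_st[0] = start
        y_st[0] = 0
        while sp > 0:
            sp -= 1
            n = st_n[sp]
            W = st_w[sp]
            while cur_len > n:
                _undo_step(idx_st[cur_len - 1], idx_st[cur_len],
                           dirs[cur_len - 1], flags_st[cur_len - 1], visits,
                           bx, by, ptype, straight, stride, feats)
                cur_len -= 1
            tested = False  # popped branches already passed the ratio test at n
            while True:
                if n == n_max:
                    break
                # atmosphere at length n
                d_in = dirs[n - 1] if n > 0 else -1
                a = 0
                for c in range(4):
                    if _legal(idx_st[n], y_st[n], c, d_in, visits, bx, by,
                              ptype, stride, visaw, surface):
                        cands[a] = c
                        a += 1
                if a == 0:
                    break
                if tested and n > 0:
                    # ratio test against the running mean weight at (n, m)
                    if flat_mode == FLAT_NI:
                        m = feats[0] + feats[1]
                    elif flat_mode == FLAT_NS:
                        m = feats[3]
                    else:
                        m = feats[0] * m2_cap + feats[1]
                    if S[n, m] > 1:
                        r = W * t / C[n, m]
                        if r < 1.0:
                            if np.random.random() < r:
                                W = C[n, m] / t
                            else:
                                break  # pruned
                        elif r > 1.0:
                            ncop = int(np.ceil(r))
                            if ncop > a:
                                ncop = a
                            if ncop > 1:
                                W = W / ncop
                                for _ in range(ncop - 1):
                                    st_n[sp] = n
                                    st_w[sp] = W
                                    sp += 1
                # grow one step
                k = int(np.random.random() * a)
                if k >= a:
                    k = a - 1
                d = cands[k]
                nidx, ny, fl = _apply_step(idx_st[n], y_st[n], d, d_in, visits,
                                           bx, by, ptype, straight, stride,
                                           feats, surface, site_conv)
                nsteps += 1
                carried = 1.0
                if flat_mode == FLAT_NS:
                    if fl & F_COLL:
                        carried *= tau_c
                    if fl & F_XRECLASS:
                        carried *= tau_x / tau_c
                    if carry_p:
                        if fl & F_STR_H:
                            carried *= p_stiff
                        if fl & F_STR_RM:
                            carried /= p_stiff
                elif carry_p:
                    if fl & F_STR_H:
                        carried *= p_stiff
                    if fl & F_STR_RM:
                        carried /= p_stiff
                W = W * a * carried
                n += 1
                dirs[n - 1] = d
                flags_st[n - 1] = fl
                idx_st[n] = nidx
                y_st[n] = ny
                cur_len = n
                if flat_mode == FLAT_NI:
                    m = feats[0] + feats[1]
                elif flat_mode == FLAT_NS:
                    m = feats[3]
                else:
                    m = feats[0] * m2_cap + feats[1]
                C[n, m] += W
                S[n, m] += 1
                tested = True
        while cur_len > 0:
            _undo_step(idx_st[cur_len - 1], idx_st[cur_len], dirs[cur_len - 1],
                       flags_st[cur_len - 1], visits, bx, by, ptype, straight,
                       stride, feats)
            cur_len -= 1
    steps_out[0] += nsteps
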