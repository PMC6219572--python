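"""Numba kernels for the rigid-body Monte Carlo of N-BAR proteins.

Everything here works on plain float64/bool arrays so the hot loop compiles
to machine code.  Geometry: each protein is a rigid union of capsules
(segments with radii) for sterics plus two H0 stadium frames for the
tabulated bilayer-mediated pair potential; an optional modified
Lennard-Jones BAR-BAR term acts between protein centres.  Periodic square
box with minimum-image distances.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e30  # sentinel for steric overlap


@njit(cache=True, fastmath=False)
def _seg_dist2(p1x, p1y, q1x, q1y, p2x, p2y, q2x, q2y):
    """Squared minimum distance between segments P1Q1 and P2Q2."""
    d1x = q1x - p1x
    d1y = q1y - p1y
    d2x = q2x - p2x
    d2y = q2y - p2y
    rx = p1x - p2x
    ry = p1y - p2y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    c = d1x * rx + d1y * ry
    b = d1x * d2x + d1y * d2y
    den = a * e - b * b
    if den > 1e-14:
        s = (b * f - c * e) / den
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    else:
        s = 0.0
    if e > 1e-14:
        t = (b * s + f) / e
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
        if a > 1e-14:
            s = -c / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    elif t > 1.0:
        t = 1.0
        if a > 1e-14:
            s = (b - c) / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    cx = p1x + s * d1x - (p2x + t * d2x)
    cy = p1y + s * d1y - (p2y + t * d2y)
    return cx * cx + cy * cy


@njit(cache=True)
def _table_lookup(energies, hx, hy, ht, xmax, ymax, dx, dy, dth):
    """Trilinear lookup with quadrant symmetry and periodic orientation."""
    if dx < 0.0:
        dx = -dx
        dth = -dth
    if dy < 0.0:
        dy = -dy
        dth = -dth
    if dx > xmax or dy > ymax:
        return 0.0
    pi = np.pi
    th = dth % pi
    nt, nx, ny = energies.shape
    fx = dx / hx
    fy = dy / hy
    ft = th / ht
    ix = int(fx)
    iy = int(fy)
    it = int(ft)
    if ix > nx - 2:
        ix = nx - 2
    if iy > ny - 2:
        iy = ny - 2
    fx -= ix
    fy -= iy
    ft -= it
    it0 = it % nt
    it1 = (it + 1) % nt
    e = 0.0
    for k in range(2):
        jt = it0 if k == 0 else it1
        wt = (1.0 - ft) if k == 0 else ft
        e += wt * (
            (1.0 - fx) * (1.0 - fy) * energies[jt, ix, iy]
            + fx * (1.0 - fy) * energies[jt, ix + 1, iy]
            + (1.0 - fx) * fy * energies[jt, ix, iy + 1]
            + fx * fy * energies[jt, ix + 1, iy + 1]
        )
    return e


@njit(cache=True)
def _pair_energy(
    xi, yi, thi, xj, yj, thj,
    caps, h0s, bar_cx, bar_cy,
    energies, hx, hy, ht, xmax, ymax,
    bar_on, eps, rm,
    box, reach, h0_cut,
):
    """Energy of one protein pair (minimum image); BIG on steric overlap."""
    dxc = xj - xi
    dyc = yj - yi
    dxc -= box * np.rint(dxc / box)
    dyc -= box * np.rint(dyc / box)
    r2 = dxc * dxc + dyc * dyc
    ci = np.cos(thi)
    si = np.sin(thi)
    cj = np.cos(thj)
    sj = np.sin(thj)
    # steric capsules
    if r2 < (2.0 * reach) ** 2:
        ncap = caps.shape[0]
        for ia in range(ncap):
            pax = ci * caps[ia, 0] - si * caps[ia, 1]
            pay = si * caps[ia, 0] + ci * caps[ia, 1]
            qax = ci * caps[ia, 2] - si * caps[ia, 3]
            qay = si * caps[ia, 2] + ci * caps[ia, 3]
            for ib in range(ncap):
                pbx = dxc + cj * caps[ib, 0] - sj * caps[ib, 1]
                pby = dyc + sj * caps[ib, 0] + cj * caps[ib, 1]
                qbx = dxc + cj * caps[ib, 2] - sj * caps[ib, 3]
                qby = dyc + sj * caps[ib, 2] + cj * caps[ib, 3]
                rr = caps[ia, 4] + caps[ib, 4]
                if _seg_dist2(pax, pay, qax, qay, pbx, pby, qbx, qby) < rr * rr:
                    return BIG
    e = 0.0
    # H0-H0 tabulated interactions (4 per pair)
    if r2 < h0_cut * h0_cut:
        for ia in range(2):
            hax = ci * h0s[ia, 0] - si * h0s[ia, 1]
            hay = si * h0s[ia, 0] + ci * h0s[ia, 1]
            tha = thi + h0s[ia, 2]
            ca = np.cos(tha)
            sa = np.sin(tha)
            for ib in range(2):
                hbx = dxc + cj * h0s[ib, 0] - sj * h0s[ib, 1]
                hby = dyc + sj * h0s[ib, 0] + cj * h0s[ib, 1]
                thb = thj + h0s[ib, 2]
                ddx = hbx - hax
                ddy = hby - hay
                # interpolation is not exactly frame-swap symmetric, so
                # average the lookups in both H0 frames: the pair energy is
                # then identical whichever protein is being moved
                ux = ca * ddx + sa * ddy
                uy = -sa * ddx + ca * ddy
                e_ab = _table_lookup(
                    energies, hx, hy, ht, xmax, ymax, ux, uy, thb - tha
                )
                cb = np.cos(thb)
                sb = np.sin(thb)
                vx = -(cb * ddx + sb * ddy)
                vy = -(-sb * ddx + cb * ddy)
                e_ba = _table_lookup(
                    energies, hx, hy, ht, xmax, ymax, vx, vy, tha - thb
                )
                e += 0.5 * (e_ab + e_ba)
    if bar_on:
        # BAR term acts between the backbone centroids (body-frame offset
        # bar_cx, bar_cy), not the pose centres
        bdx = dxc + cj * bar_cx - sj * bar_cy - (ci * bar_cx - si * bar_cy)
        bdy = dyc + sj * bar_cx + cj * bar_cy - (si * bar_cx + ci * bar_cy)
        r = np.sqrt(bdx * bdx + bdy * bdy)
        if r > 1e-9:
            phi = np.arctan2(bdy, bdx)
            pi = np.pi
            t1 = (thi - phi) % pi
            t2 = (thj - phi) % pi
            ang = 1.0 - np.abs(2.0 * t1 - pi) / (2.0 * pi) - np.abs(
                2.0 * t2 - pi
            ) / (2.0 * pi)
            sr = rm / r
            sr6 = sr**6
            e += eps * (sr6 * sr6 - 2.0 * sr6 * ang)
    return e


@njit(cache=True)
def _protein_energy(
    i, poses, caps, h0s, bar_cx, bar_cy, energies, hx, hy, ht, xmax, ymax,
    bar_on, eps, rm, box, reach, h0_cut,
):
    n = poses.shape[0]
    e = 0.0
    for j in range(n):
        if j == i:
            continue
        e += _pair_energy(
            poses[i, 0], poses[i, 1], poses[i, 2],
            poses[j, 0], poses[j, 1], poses[j, 2],
            caps, h0s, bar_cx, bar_cy, energies, hx, hy, ht, xmax, ymax,
            bar_on, eps, rm, box, reach, h0_cut,
        )
        if e >= BIG:
            return BIG
    return e


@njit(cache=True)
def _total_energy(
    poses, caps, h0s, bar_cx, bar_cy, energies, hx, hy, ht, xmax, ymax,
    bar_on, eps, rm, box, reach, h0_cut,
):
    n = poses.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            e += _pair_energy(
                poses[i, 0], poses[i, 1], poses[i, 2],
                poses[j, 0], poses[j, 1], poses[j, 2],
                caps, h0s, bar_cx, bar_cy, energies, hx, hy, ht, xmax, ymax,
                bar_on, eps, rm, box, reach, h0_cut,
            )
            if e >= BIG:
                return BIG
    return e


@njit(cache=True)
def run_mc(
    poses, n_steps, t_start, t_end,
    delta_r, delta_th,
    caps, h0s, bar_cx, bar_cy, energies, hx, hy, ht, xmax, ymax,
    bar_on, eps, rm, box, reach, h0_cut,
    seed, trace_every,
):
    """Metropolis sweeps with a linear temperature ramp.

    One step = one translation trial then one rotation trial per protein, in
    a freshly shuffled order.  Temperatures are in units of room temperature
    with energies in k_B T_rm; at T = 0 only downhill moves are accepted.
    Returns (sampled steps, sampled temperatures, sampled total energies).
    """
    np.random.seed(seed)
    n = poses.shape[0]
    order = np.arange(n)
    n_trace = n_steps // trace_every + 1
    tr_step = np.empty(n_trace, np.int64)
    tr_temp = np.empty(n_trace, np.float64)
    tr_en = np.empty(n_trace, np.float64)
    itr = 0
    for step in range(n_steps):
        if n_steps > 1:
            T = t_start + (t_end - t_start) * (step / (n_steps - 1))
        else:
            T = t_start
        # Fisher-Yates shuffle of the trial order
        for k in range(n - 1, 0, -1):
            m = np.random.randint(0, k + 1)
            tmp = order[k]
            order[k] = order[m]
            order[m] = tmp
        for k in range(n):
            i = order[k]
            e_old = _protein_energy(
                i, poses, caps, h0s, bar_cx, bar_cy,
                energies, hx, hy, ht, xmax, ymax,
                bar_on, eps, rm, box, reach, h0_cut,
            )
            for move in range(2):
                ox = poses[i, 0]
                oy = poses[i, 1]
                oth = poses[i, 2]
                if move == 0:
                    poses[i, 0] = (ox + (np.random.random() * 2.0 - 1.0) * delta_r) % box
                    poses[i, 1] = (oy + (np.random.random() * 2.0 - 1.0) * delta_r) % box
                else:
                    poses[i, 2] = oth + (np.random.random() * 2.0 - 1.0) * delta_th
                e_new = _protein_energy(
                    i, poses, caps, h0s, bar_cx, bar_cy,
                    energies, hx, hy, ht, xmax, ymax,
                    bar_on, eps, rm, box, reach, h0_cut,
                )
                de = e_new - e_old
                accept = False
                if e_new < BIG:
                    if de <= 0.0:
                        accept = True
                    elif T > 0.0 and np.random.random() < np.exp(-de / T):
                        accept = True
                if accept:
                    e_old = e_new
                else:
                    poses[i, 0] = ox
                    poses[i, 1] = oy
                    poses[i, 2] = oth
        if step % trace_every == 0:
            tr_step[itr] = step
            tr_temp[itr] = T
            tr_en[itr] = _total_energy(
                poses, caps, h0s, bar_cx, bar_cy,
                energies, hx, hy, ht, xmax, ymax,
                bar_on, eps, rm, box, reach, h0_cut,
            )
            itr += 1
    return tr_step[:itr], tr_temp[:itr], tr_en[:itr]
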