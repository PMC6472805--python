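"""Fused per-step force kernel for the integrators.

The numpy implementations in :mod:`ecmdyn.mechanics` are the reference (they
carry the per-term bookkeeping and are validated against numerical gradients
in the test suite); this module provides a numba-compiled kernel computing
the same total force in one pass, which the time-stepping loops use.  The
two paths are asserted equivalent in the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _min_img(dx, dy, lxy):
    # branches beat round(): wrapped coordinates keep |dx| < 1.5*lxy
    half = 0.5 * lxy
    if dx > half:
        dx -= lxy
    elif dx < -half:
        dx += lxy
    if dy > half:
        dy -= lxy
    elif dy < -half:
        dy += lxy
    return dx, dy


@njit(cache=True, fastmath=True)
def _seg_closest(p1x, p1y, p1z, d1x, d1y, d1z, p2x, p2y, p2z, d2x, d2y, d2z, lxy):
    """Closest approach of two segments (minimum image in x,y); returns
    (dist, t, s, nx, ny, nz) with n the unit vector from point1 to point2."""
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    rx, ry = _min_img(rx, ry, lxy)
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    b = d1x * d2x + d1y * d2y + d1z * d2z
    c = d1x * rx + d1y * ry + d1z * rz
    f = d2x * rx + d2y * ry + d2z * rz
    den = a * e - b * b
    if den > 1e-14:
        t = (b * f - c * e) / den
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    else:
        t = 0.0
    s = (b * t + f) / e if e > 1e-14 else 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    t = (b * s - c) / a if a > 1e-14 else 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    s = (b * t + f) / e if e > 1e-14 else 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    c1x = p1x + t * d1x
    c1y = p1y + t * d1y
    c1z = p1z + t * d1z
    c2x = p2x + s * d2x
    c2y = p2y + s * d2y
    c2z = p2z + s * d2z
    sx = c2x - c1x
    sy = c2y - c1y
    sz = c2z - c1z
    sx, sy = _min_img(sx, sy, lxy)
    dist = np.sqrt(sx * sx + sy * sy + sz * sz)
    return dist, t, s, sx, sy, sz


@njit(cache=True, fastmath=True)
def fused_forces(
    pos,
    seg_a,
    seg_b,
    rest,
    kappa_e,
    trip_i,
    trip_j,
    trip_k,
    kappa_b,
    cl_sa,
    cl_sb,
    cl_ta,
    cl_tb,
    cl_bound,
    cl_rest,
    k_cl,
    rp_a,
    rp_b,
    diameter,
    k_rep,
    f_cap,
    lxy,
    forces,
    tension,
):
    """Total internal force into ``forces`` (zeroed by caller); crosslink
    tensions into ``tension``.  Returns the total elastic energy."""
    energy = 0.0
    n_seg = len(seg_a)
    # stretch -----------------------------------------------------------
    for s in range(n_seg):
        ia = seg_a[s]
        ib = seg_b[s]
        dx = pos[ib, 0] - pos[ia, 0]
        dy = pos[ib, 1] - pos[ia, 1]
        dz = pos[ib, 2] - pos[ia, 2]
        dx, dy = _min_img(dx, dy, lxy)
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = length - rest[s]
        coef = kappa_e * dr / length
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        forces[ia, 0] += fx
        forces[ia, 1] += fy
        forces[ia, 2] += fz
        forces[ib, 0] -= fx
        forces[ib, 1] -= fy
        forces[ib, 2] -= fz
        energy += 0.5 * kappa_e * dr * dr
    # bend --------------------------------------------------------------
    for m in range(len(trip_i)):
        ii = trip_i[m]
        jj = trip_j[m]
        kk = trip_k[m]
        ax = pos[jj, 0] - pos[ii, 0]
        ay = pos[jj, 1] - pos[ii, 1]
        az = pos[jj, 2] - pos[ii, 2]
        ax, ay = _min_img(ax, ay, lxy)
        bx = pos[kk, 0] - pos[jj, 0]
        by = pos[kk, 1] - pos[jj, 1]
        bz = pos[kk, 2] - pos[jj, 2]
        bx, by = _min_img(bx, by, lxy)
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        ahx = ax / la
        ahy = ay / la
        ahz = az / la
        bhx = bx / lb
        bhy = by / lb
        bhz = bz / lb
        ct = ahx * bhx + ahy * bhy + ahz * bhz
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        ratio = theta / st if st > 1e-8 else 1.0
        g = kappa_b * ratio
        fix = -(g / la) * (bhx - ct * ahx)
        fiy = -(g / la) * (bhy - ct * ahy)
        fiz = -(g / la) * (bhz - ct * ahz)
        fkx = (g / lb) * (ahx - ct * bhx)
        fky = (g / lb) * (ahy - ct * bhy)
        fkz = (g / lb) * (ahz - ct * bhz)
        forces[ii, 0] += fix
        forces[ii, 1] += fiy
        forces[ii, 2] += fiz
        forces[kk, 0] += fkx
        forces[kk, 1] += fky
        forces[kk, 2] += fkz
        forces[jj, 0] -= fix + fkx
        forces[jj, 1] -= fiy + fky
        forces[jj, 2] -= fiz + fkz
        energy += 0.5 * kappa_b * theta * theta
    # crosslinks --------------------------------------------------------
    for c in range(len(cl_sa)):
        tension[c] = 0.0
        sa = cl_sa[c]
        sb = cl_sb[c]
        ta = cl_ta[c]
        tb = cl_tb[c]
        a0 = seg_a[sa]
        a1 = seg_b[sa]
        b0 = seg_a[sb]
        b1 = seg_b[sb]
        vax = pos[a1, 0] - pos[a0, 0]
        vay = pos[a1, 1] - pos[a0, 1]
        vaz = pos[a1, 2] - pos[a0, 2]
        vax, vay = _min_img(vax, vay, lxy)
        xax = pos[a0, 0] + ta * vax
        xay = pos[a0, 1] + ta * vay
        xaz = pos[a0, 2] + ta * vaz
        vbx = pos[b1, 0] - pos[b0, 0]
        vby = pos[b1, 1] - pos[b0, 1]
        vbz = pos[b1, 2] - pos[b0, 2]
        vbx, vby = _min_img(vbx, vby, lxy)
        xbx = pos[b0, 0] + tb * vbx
        xby = pos[b0, 1] + tb * vby
        xbz = pos[b0, 2] + tb * vbz
        dx = xbx - xax
        dy = xby - xay
        dz = xbz - xaz
        dx, dy = _min_img(dx, dy, lxy)
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        if not cl_bound[c]:
            continue
        ext = length - cl_rest[c]
        fmag = k_cl * ext
        if fmag > 0.0:
            tension[c] = fmag
        if length > 1e-9:
            ux = dx / length
            uy = dy / length
            uz = dz / length
            fx = fmag * ux
            fy = fmag * uy
            fz = fmag * uz
            forces[a0, 0] += (1.0 - ta) * fx
            forces[a0, 1] += (1.0 - ta) * fy
            forces[a0, 2] += (1.0 - ta) * fz
            forces[a1, 0] += ta * fx
            forces[a1, 1] += ta * fy
            forces[a1, 2] += ta * fz
            forces[b0, 0] -= (1.0 - tb) * fx
            forces[b0, 1] -= (1.0 - tb) * fy
            forces[b0, 2] -= (1.0 - tb) * fz
            forces[b1, 0] -= tb * fx
            forces[b1, 1] -= tb * fy
            forces[b1, 2] -= tb * fz
        energy += 0.5 * k_cl * ext * ext
    # repulsion ---------------------------------------------------------
    cap_depth = f_cap / k_rep if k_rep > 0.0 else 1e30
    for m in range(len(rp_a)):
        s1 = rp_a[m]
        s2 = rp_b[m]
        a0 = seg_a[s1]
        a1 = seg_b[s1]
        b0 = seg_a[s2]
        b1 = seg_b[s2]
        d1x = pos[a1, 0] - pos[a0, 0]
        d1y = pos[a1, 1] - pos[a0, 1]
        d1z = pos[a1, 2] - pos[a0, 2]
        d1x, d1y = _min_img(d1x, d1y, lxy)
        d2x = pos[b1, 0] - pos[b0, 0]
        d2y = pos[b1, 1] - pos[b0, 1]
        d2z = pos[b1, 2] - pos[b0, 2]
        d2x, d2y = _min_img(d2x, d2y, lxy)
        dist, t, s, sx, sy, sz = _seg_closest(
            pos[a0, 0], pos[a0, 1], pos[a0, 2], d1x, d1y, d1z,
            pos[b0, 0], pos[b0, 1], pos[b0, 2], d2x, d2y, d2z, lxy,
        )
        overlap = diameter - dist
        if overlap <= 0.0:
            continue
        quad = overlap if overlap < cap_depth else cap_depth
        fmag = k_rep * quad
        if dist > 1e-9:
            nx = sx / dist
            ny = sy / dist
            nz = sz / dist
        else:
            nx = 0.0
            ny = 0.0
            nz = 1.0
        # push segment 1 away from segment 2 (f1 = -fmag * n)
        fx = -fmag * nx
        fy = -fmag * ny
        fz = -fmag * nz
        forces[a0, 0] += (1.0 - t) * fx
        forces[a0, 1] += (1.0 - t) * fy
        forces[a0, 2] += (1.0 - t) * fz
        forces[a1, 0] += t * fx
        forces[a1, 1] += t * fy
        forces[a1, 2] += t * fz
        forces[b0, 0] -= (1.0 - s) * fx
        forces[b0, 1] -= (1.0 - s) * fy
        forces[b0, 2] -= (1.0 - s) * fz
        forces[b1, 0] -= s * fx
        forces[b1, 1] -= s * fy
        forces[b1, 2] -= s * fz
        energy += 0.5 * k_rep * quad * quad
        if overlap > cap_depth:
            energy += f_cap * (overlap - cap_depth)
    return energy


@njit(cache=True, fastmath=True)
def euler_update(pos, forces, fixed, dt_over_zeta, lxy, lz, cap):
    """In-place overdamped Euler update; returns the max displacement."""
    max_d = 0.0
    for i in range(len(pos)):
        if fixed[i]:
            continue
        x = pos[i, 0] + forces[i, 0] * dt_over_zeta
        y = pos[i, 1] + forces[i, 1] * dt_over_zeta
        z = pos[i, 2] + forces[i, 2] * dt_over_zeta
        if z < 0.0:
            z = 0.0
        elif z > lz:
            z = lz
        dx = x - pos[i, 0]
        dy = y - pos[i, 1]
        dz = z - pos[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > max_d:
            max_d = d
        x %= lxy
        if x >= lxy:
            x = 0.0
        y %= lxy
        if y >= lxy:
            y = 0.0
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z
    return max_d


@njit(cache=True, fastmath=True)
def build_repulsion_pairs(
    pos, seg_a, seg_b, lxy, lz, cutoff_mid, contact, max_pairs, excl_keys, n_seg_total
):
    """Cell-list shortlist of non-adjacent segment pairs with closest
    approach below ``contact`` (x,y periodic).  ``excl_keys`` is a sorted
    array of encoded bonded pairs (lo·n_seg_total + hi) to skip (crosslinked
    pairs carry no volume exclusion).  Returns (pairs, count); count == -1
    signals that ``max_pairs`` was too small."""
    n_seg = len(seg_a)
    out = np.empty((max_pairs, 2), dtype=np.int64)
    if n_seg < 2:
        return out, 0
    # midpoints (z is non-periodic; x,y wrapped)
    mx = np.empty(n_seg)
    my = np.empty(n_seg)
    mz = np.empty(n_seg)
    for s in range(n_seg):
        ia = seg_a[s]
        ib = seg_b[s]
        dx = pos[ib, 0] - pos[ia, 0]
        dy = pos[ib, 1] - pos[ia, 1]
        dx, dy = _min_img(dx, dy, lxy)
        mx[s] = (pos[ia, 0] + 0.5 * dx) % lxy
        my[s] = (pos[ia, 1] + 0.5 * dy) % lxy
        mz[s] = pos[ia, 2] + 0.5 * (pos[ib, 2] - pos[ia, 2])
    ncx = max(1, int(lxy / cutoff_mid))
    cell = lxy / ncx
    ncz = max(1, int(lz / cutoff_mid) + 1)
    # bin segments
    ci = np.empty(n_seg, dtype=np.int64)
    for s in range(n_seg):
        ix = int(mx[s] / cell) % ncx
        iy = int(my[s] / cell) % ncx
        iz = int(mz[s] / cutoff_mid)
        if iz < 0:
            iz = 0
        elif iz >= ncz:
            iz = ncz - 1
        ci[s] = (ix * ncx + iy) * ncz + iz
    ncell = ncx * ncx * ncz
    count = np.zeros(ncell + 1, dtype=np.int64)
    for s in range(n_seg):
        count[ci[s] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n_seg, dtype=np.int64)
    fill = count.copy()
    for s in range(n_seg):
        order[fill[ci[s]]] = s
        fill[ci[s]] += 1
    cut2 = cutoff_mid * cutoff_mid
    n_out = 0
    for cx in range(ncx):
        for cy in range(ncx):
            for cz in range(ncz):
                c0 = (cx * ncx + cy) * ncz + cz
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        for oz in range(0, 2):
                            if oz == 0 and (ox < 0 or (ox == 0 and oy < 0)):
                                continue  # half-neighborhood
                            nz = cz + oz
                            if nz < 0 or nz >= ncz:
                                continue
                            nx = (cx + ox) % ncx
                            ny = (cy + oy) % ncx
                            c1 = (nx * ncx + ny) * ncz + nz
                            same = c1 == c0
                            if (not same) and oz == 0 and ox == 0 and oy == 0:
                                continue
                            for u in range(count[c0], count[c0 + 1]):
                                s1 = order[u]
                                vstart = u + 1 if same else count[c1]
                                for v in range(vstart, count[c1 + 1]):
                                    s2 = order[v]
                                    dx = mx[s1] - mx[s2]
                                    dy = my[s1] - my[s2]
                                    dx, dy = _min_img(dx, dy, lxy)
                                    dz = mz[s1] - mz[s2]
                                    if dx * dx + dy * dy + dz * dz > cut2:
                                        continue
                                    a0 = seg_a[s1]
                                    a1 = seg_b[s1]
                                    b0 = seg_a[s2]
                                    b1 = seg_b[s2]
                                    if a0 == b0 or a0 == b1 or a1 == b0 or a1 == b1:
                                        continue  # adjacent on one fiber
                                    if len(excl_keys) > 0:
                                        lo = s1 if s1 < s2 else s2
                                        hi = s2 if s1 < s2 else s1
                                        key = lo * n_seg_total + hi
                                        kpos = np.searchsorted(excl_keys, key)
                                        if kpos < len(excl_keys) and excl_keys[kpos] == key:
                                            continue  # bonded (crosslinked) pair
                                    d1x = pos[a1, 0] - pos[a0, 0]
                                    d1y = pos[a1, 1] - pos[a0, 1]
                                    d1z = pos[a1, 2] - pos[a0, 2]
                                    d1x, d1y = _min_img(d1x, d1y, lxy)
                                    d2x = pos[b1, 0] - pos[b0, 0]
                                    d2y = pos[b1, 1] - pos[b0, 1]
                                    d2z = pos[b1, 2] - pos[b0, 2]
                                    d2x, d2y = _min_img(d2x, d2y, lxy)
                                    dist, _, _, _, _, _ = _seg_closest(
                                        pos[a0, 0], pos[a0, 1], pos[a0, 2],
                                        d1x, d1y, d1z,
                                        pos[b0, 0], pos[b0, 1], pos[b0, 2],
                                        d2x, d2y, d2z, lxy,
                                    )
                                    if dist >= contact:
                                        continue
                                    if n_out >= max_pairs:
                                        return out, -1
                                    if s1 < s2:
                                        out[n_out, 0] = s1
                                        out[n_out, 1] = s2
                                    else:
                                        out[n_out, 0] = s2
                                        out[n_out, 1] = s1
                                    n_out += 1
    return out, n_out
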