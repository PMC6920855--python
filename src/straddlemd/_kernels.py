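"""Compiled inner loops for the energy model.

Each kernel returns a float energy and accumulates forces into the
gradient array passed in.  A pure-numpy fallback is selected automatically
when numba is unavailable; both paths compute identical values (no
fastmath reordering).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def nb_kernel(x, pairs, charges, rmin2, ljeps, cutoff, switch_on,
              do_lj, do_coul, coulomb_k, scale, g):
    e = 0.0
    on2 = switch_on * switch_on
    off2 = cutoff * cutoff
    denom = (off2 - on2) ** 3
    for n in range(pairs.shape[0]):
        i = pairs[n, 0]
        j = pairs[n, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r >= cutoff:
            continue
        if r < 0.4:
            r = 0.4
            r2 = 0.16
        sw = 1.0
        dsw = 0.0
        if r > switch_on:
            a = off2 - r2
            b = off2 + 2.0 * r2 - 3.0 * on2
            sw = a * a * b / denom
            dsw = (2.0 * a * (-2.0 * r) * b + a * a * 4.0 * r) / denom
        e_pair = 0.0
        de_pair = 0.0
        if do_lj:
            rmin = rmin2[i] + rmin2[j]
            eps = np.sqrt(ljeps[i] * ljeps[j])
            q6 = (rmin / r) ** 6
            e_pair += eps * (q6 * q6 - 2.0 * q6)
            de_pair += eps * 12.0 * (q6 - q6 * q6) / r
        if do_coul:
            qq = coulomb_k * charges[i] * charges[j] / 4.0
            e_pair += qq / r2
            de_pair += -2.0 * qq / (r2 * r)
        e += scale * e_pair * sw
        coef = scale * (de_pair * sw + e_pair * dsw) / r
        g[i, 0] += coef * dx
        g[i, 1] += coef * dy
        g[i, 2] += coef * dz
        g[j, 0] -= coef * dx
        g[j, 1] -= coef * dy
        g[j, 2] -= coef * dz
    return e


@njit(cache=True)
def hb_kernel(x, pairs, hb_eps, hb_r0, hb_cutoff, scale, g):
    e = 0.0
    for n in range(pairs.shape[0]):
        i = pairs[n, 0]
        j = pairs[n, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= hb_cutoff:
            continue
        if r < 0.5:
            r = 0.5
        q10 = (hb_r0 / r) ** 10
        q12 = q10 * (hb_r0 / r) ** 2
        e += scale * hb_eps * (5.0 * q12 - 6.0 * q10)
        de = scale * hb_eps * (-60.0 * q12 + 60.0 * q10) / r
        coef = de / r
        g[i, 0] += coef * dx
        g[i, 1] += coef * dy
        g[i, 2] += coef * dz
        g[j, 0] -= coef * dx
        g[j, 1] -= coef * dy
        g[j, 2] -= coef * dz
    return e


@njit(cache=True)
def within_cutoff_mask(x, pairs, cutoff):
    n = pairs.shape[0]
    out = np.empty(n, dtype=np.bool_)
    c2 = cutoff * cutoff
    for m in range(n):
        i = pairs[m, 0]
        j = pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        out[m] = (dx * dx + dy * dy + dz * dz) < c2
    return out


@njit(cache=True)
def spring_kernel(x, idx_i, idx_j, r0, k, g):
    e = 0.0
    for n in range(idx_i.shape[0]):
        i = idx_i[n]
        j = idx_j[n]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            r = 1e-12
        dev = r - r0[n]
        e += k[n] * dev * dev
        coef = 2.0 * k[n] * dev / r
        g[i, 0] += coef * dx
        g[i, 1] += coef * dy
        g[i, 2] += coef * dz
        g[j, 0] -= coef * dx
        g[j, 1] -= coef * dy
        g[j, 2] -= coef * dz
    return e


@njit(cache=True)
def collision_kernel(x, pairs, r_thresh, k_rep, g):
    e = 0.0
    for n in range(pairs.shape[0]):
        i = pairs[n, 0]
        j = pairs[n, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= r_thresh:
            continue
        if r < 1e-12:
            r = 1e-12
        dev = r_thresh - r
        e += k_rep * dev * dev
        coef = -2.0 * k_rep * dev / r
        g[i, 0] += coef * dx
        g[i, 1] += coef * dy
        g[i, 2] += coef * dz
        g[j, 0] -= coef * dx
        g[j, 1] -= coef * dy
        g[j, 2] -= coef * dz
    return e


@njit(cache=True)
def plane_kernel(x, tri_a, tri_b, k, g):
    """E = sum k (1 - (u.v)^2) over pairs of atom-triple plane normals."""
    e = 0.0
    for n in range(tri_a.shape[0]):
        a0, a1, a2 = tri_a[n, 0], tri_a[n, 1], tri_a[n, 2]
        b0, b1, b2 = tri_b[n, 0], tri_b[n, 1], tri_b[n, 2]
        pax = x[a1, 0] - x[a0, 0]
        pay = x[a1, 1] - x[a0, 1]
        paz = x[a1, 2] - x[a0, 2]
        qax = x[a2, 0] - x[a0, 0]
        qay = x[a2, 1] - x[a0, 1]
        qaz = x[a2, 2] - x[a0, 2]
        pbx = x[b1, 0] - x[b0, 0]
        pby = x[b1, 1] - x[b0, 1]
        pbz = x[b1, 2] - x[b0, 2]
        qbx = x[b2, 0] - x[b0, 0]
        qby = x[b2, 1] - x[b0, 1]
        qbz = x[b2, 2] - x[b0, 2]
        nax = pay * qaz - paz * qay
        nay = paz * qax - pax * qaz
        naz = pax * qay - pay * qax
        nbx = pby * qbz - pbz * qby
        nby = pbz * qbx - pbx * qbz
        nbz = pbx * qby - pby * qbx
        la = np.sqrt(nax * nax + nay * nay + naz * naz)
        lb = np.sqrt(nbx * nbx + nby * nby + nbz * nbz)
        uax, uay, uaz = nax / la, nay / la, naz / la
        ubx, uby, ubz = nbx / lb, nby / lb, nbz / lb
        c = uax * ubx + uay * uby + uaz * ubz
        e += k[n] * (1.0 - c * c)
        f = -2.0 * k[n] * c
        # dE/du_a = f * u_b, projected through normalization of n_a
        dua_x, dua_y, dua_z = f * ubx, f * uby, f * ubz
        dot_a = dua_x * uax + dua_y * uay + dua_z * uaz
        dna_x = (dua_x - uax * dot_a) / la
        dna_y = (dua_y - uay * dot_a) / la
        dna_z = (dua_z - uaz * dot_a) / la
        dub_x, dub_y, dub_z = f * uax, f * uay, f * uaz
        dot_b = dub_x * ubx + dub_y * uby + dub_z * ubz
        dnb_x = (dub_x - ubx * dot_b) / lb
        dnb_y = (dub_y - uby * dot_b) / lb
        dnb_z = (dub_z - ubz * dot_b) / lb
        # triple a: dE/dp = q x dn, dE/dq = dn x p
        dpx = qay * dna_z - qaz * dna_y
        dpy = qaz * dna_x - qax * dna_z
        dpz = qax * dna_y - qay * dna_x
        dqx = dna_y * paz - dna_z * pay
        dqy = dna_z * pax - dna_x * paz
        dqz = dna_x * pay - dna_y * pax
        g[a0, 0] -= dpx + dqx
        g[a0, 1] -= dpy + dqy
        g[a0, 2] -= dpz + dqz
        g[a1, 0] += dpx
        g[a1, 1] += dpy
        g[a1, 2] += dpz
        g[a2, 0] += dqx
        g[a2, 1] += dqy
        g[a2, 2] += dqz
        # triple b
        dpx = qby * dnb_z - qbz * dnb_y
        dpy = qbz * dnb_x - qbx * dnb_z
        dpz = qbx * dnb_y - qby * dnb_x
        dqx = dnb_y * pbz - dnb_z * pby
        dqy = dnb_z * pbx - dnb_x * pbz
        dqz = dnb_x * pby - dnb_y * pbx
        g[b0, 0] -= dpx + dqx
        g[b0, 1] -= dpy + dqy
        g[b0, 2] -= dpz + dqz
        g[b1, 0] += dpx
        g[b1, 1] += dpy
        g[b1, 2] += dpz
        g[b2, 0] += dqx
        g[b2, 1] += dqy
        g[b2, 2] += dqz
    return e


@njit(cache=True)
def angle_kernel(x, arr, t0, k, g):
    e = 0.0
    for n in range(arr.shape[0]):
        i = arr[n, 0]
        j = arr[n, 1]
        l = arr[n, 2]
        v1x = x[i, 0] - x[j, 0]
        v1y = x[i, 1] - x[j, 1]
        v1z = x[i, 2] - x[j, 2]
        v2x = x[l, 0] - x[j, 0]
        v2y = x[l, 1] - x[j, 1]
        v2z = x[l, 2] - x[j, 2]
        n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
        n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
        c = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
        if c > 1.0 - 1e-10:
            c = 1.0 - 1e-10
        if c < -1.0 + 1e-10:
            c = -1.0 + 1e-10
        theta = np.arccos(c)
        dev = theta - t0[n]
        e += k * dev * dev
        s = np.sqrt(1.0 - c * c)
        if s < 1e-6:
            s = 1e-6
        pref = 2.0 * k * dev / -s
        inv12 = 1.0 / (n1 * n2)
        gi_x = pref * (v2x * inv12 - c * v1x / (n1 * n1))
        gi_y = pref * (v2y * inv12 - c * v1y / (n1 * n1))
        gi_z = pref * (v2z * inv12 - c * v1z / (n1 * n1))
        gl_x = pref * (v1x * inv12 - c * v2x / (n2 * n2))
        gl_y = pref * (v1y * inv12 - c * v2y / (n2 * n2))
        gl_z = pref * (v1z * inv12 - c * v2z / (n2 * n2))
        g[i, 0] += gi_x
        g[i, 1] += gi_y
        g[i, 2] += gi_z
        g[l, 0] += gl_x
        g[l, 1] += gl_y
        g[l, 2] += gl_z
        g[j, 0] -= gi_x + gl_x
        g[j, 1] -= gi_y + gl_y
        g[j, 2] -= gi_z + gl_z
    return e


@njit(cache=True)
def dihedral_kernel(x, arr, p0, k, period, g):
    e = 0.0
    for n in range(arr.shape[0]):
        i = arr[n, 0]
        j = arr[n, 1]
        kk = arr[n, 2]
        l = arr[n, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[kk, 0] - x[j, 0]
        b2y = x[kk, 1] - x[j, 1]
        b2z = x[kk, 2] - x[j, 2]
        b3x = x[l, 0] - x[kk, 0]
        b3y = x[l, 1] - x[kk, 1]
        b3z = x[l, 2] - x[kk, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2len = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m1x = (n1y * b2z - n1z * b2y) / b2len
        m1y = (n1z * b2x - n1x * b2z) / b2len
        m1z = (n1x * b2y - n1y * b2x) / b2len
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        yy = m1x * n2x + m1y * n2y + m1z * n2z
        phi = np.arctan2(yy, xx)
        dev = period * (phi - p0[n])
        e += k * (1.0 - np.cos(dev))
        if n1sq < 1e-8 or n2sq < 1e-8:
            continue
        dE = k * period * np.sin(dev)
        ci = b2len / n1sq
        cl = -b2len / n2sq
        dpi_x = ci * n1x
        dpi_y = ci * n1y
        dpi_z = ci * n1z
        dpl_x = cl * n2x
        dpl_y = cl * n2y
        dpl_z = cl * n2z
        p = -(b1x * b2x + b1y * b2y + b1z * b2z) / (b2len * b2len)
        q = -(b3x * b2x + b3y * b2y + b3z * b2z) / (b2len * b2len)
        dpj_x = (p - 1.0) * dpi_x - q * dpl_x
        dpj_y = (p - 1.0) * dpi_y - q * dpl_y
        dpj_z = (p - 1.0) * dpi_z - q * dpl_z
        dpk_x = (q - 1.0) * dpl_x - p * dpi_x
        dpk_y = (q - 1.0) * dpl_y - p * dpi_y
        dpk_z = (q - 1.0) * dpl_z - p * dpi_z
        g[i, 0] += dE * dpi_x
        g[i, 1] += dE * dpi_y
        g[i, 2] += dE * dpi_z
        g[j, 0] += dE * dpj_x
        g[j, 1] += dE * dpj_y
        g[j, 2] += dE * dpj_z
        g[kk, 0] += dE * dpk_x
        g[kk, 1] += dE * dpk_y
        g[kk, 2] += dE * dpk_z
        g[l, 0] += dE * dpl_x
        g[l, 1] += dE * dpl_y
        g[l, 2] += dE * dpl_z
    return e
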