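"""McMurchie-Davidson evaluation of Gaussian integrals (numba kernels).

Hermite expansion coefficients E_t^{ij} are generated by the standard two-term
recursions; Coulomb-type integrals use the Hermite integrals R_tuv built from
the Boys function.  Two-electron integrals are assembled per primitive quartet
as theta1 @ M @ theta2.T, where theta maps Cartesian pairs to the Hermite basis
and M collects R_{t+tau, u+nu, v+phi} with the (-1)^{tau+nu+phi} phase.

All kernels are scalar (single-threaded); the driver applies 8-fold permutation
symmetry and Cauchy-Schwarz screening.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SQRT_PI = np.sqrt(np.pi)
TWO_PI_POW = 2.0 * np.pi ** 2.5


@njit(cache=True)
def boys(mmax, T, out):
    """Boys function F_m(T) for m = 0..mmax into out."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if T > 45.0:
        # asymptotic: F_m ~ (2m-1)!! / (2T)^m * 0.5*sqrt(pi/T)
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for m in range(1, mmax + 1):
            out[m] = out[m - 1] * (2.0 * m - 1.0) / (2.0 * T)
        return
    # F_m(T) = exp(-T) * sum_{k>=0} (2T)^k (2m-1)!!/(2m+2k+1)!!, then downward
    expmT = np.exp(-T)
    s = 0.0
    term = 1.0 / (2.0 * mmax + 1.0)
    k = 0
    while True:
        s += term
        k += 1
        term *= 2.0 * T / (2.0 * mmax + 2.0 * k + 1.0)
        if term < 1e-17 * s or k > 300:
            break
    out[mmax] = expmT * s
    for m in range(mmax - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + expmT) / (2.0 * m + 1.0)


@njit(cache=True)
def e_tables(l1, l2, a, b, AB, E):
    """Hermite expansion coefficients per dimension.

    E has shape (3, l1+1+2, l2+1+2, l1+l2+1+4); entries E[d, i, j, t].
    The +2/+4 head-room lets the kinetic-energy kernel shift j by two.
    """
    p = a + b
    mu = a * b / p
    for d in range(3):
        X = AB[d]
        n_i = E.shape[1]
        n_j = E.shape[2]
        n_t = E.shape[3]
        for i in range(n_i):
            for j in range(n_j):
                for t in range(n_t):
                    E[d, i, j, t] = 0.0
        E[d, 0, 0, 0] = np.exp(-mu * X * X)
        XPA = -b * X / p  # P - A with X = A - B
        XPB = a * X / p   # P - B
        for i in range(1, n_i):
            for t in range(i + 1):
                val = XPA * E[d, i - 1, 0, t]
                if t > 0:
                    val += E[d, i - 1, 0, t - 1] / (2.0 * p)
                if t + 1 <= i - 1:
                    val += (t + 1.0) * E[d, i - 1, 0, t + 1]
                E[d, i, 0, t] = val
        for i in range(n_i):
            for j in range(1, n_j):
                for t in range(i + j + 1):
                    val = XPB * E[d, i, j - 1, t]
                    if t > 0:
                        val += E[d, i, j - 1, t - 1] / (2.0 * p)
                    if t + 1 <= i + j - 1:
                        val += (t + 1.0) * E[d, i, j - 1, t + 1]
                    E[d, i, j, t] = val


@njit(cache=True)
def hermite_R(L, p, X, Y, Z, R):
    """R^0_{tuv} for t+u+v <= L at reduced exponent p and displacement (X,Y,Z).

    R is a scratch array of shape (L+2, L+1, L+1, L+1) indexed (n, t, u, v);
    the result lives in R[0].
    """
    T = p * (X * X + Y * Y + Z * Z)
    F = np.zeros(L + 1)
    boys(L, T, F)
    for n in range(L + 1):
        R[n, 0, 0, 0] = (-2.0 * p) ** n * F[n]
    for total in range(1, L + 1):
        for n in range(L - total, -1, -1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1.0) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1.0) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1.0) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val


@njit(cache=True)
def _pair_overlap_kinetic(l1, l2, exps1, coefs1, exps2, coefs2, AB, cart1, cart2,
                          S_blk, T_blk):
    nc1 = cart1.shape[0]
    nc2 = cart2.shape[0]
    Lmax1 = l1 + 2
    Lmax2 = l2 + 2
    E = np.zeros((3, Lmax1 + 1, Lmax2 + 1, Lmax1 + Lmax2 + 1))
    for ii in range(nc1):
        for jj in range(nc2):
            S_blk[ii, jj] = 0.0
            T_blk[ii, jj] = 0.0
    for ip in range(len(exps1)):
        a = exps1[ip]
        ca = coefs1[ip]
        for jp in range(len(exps2)):
            b = exps2[jp]
            cb = coefs2[jp]
            p = a + b
            e_tables(l1 + 2, l2 + 2, a, b, AB, E)
            fac = (np.pi / p) ** 1.5
            for ii in range(nc1):
                ax, ay, az = cart1[ii, 0], cart1[ii, 1], cart1[ii, 2]
                for jj in range(nc2):
                    bx, by, bz = cart2[jj, 0], cart2[jj, 1], cart2[jj, 2]
                    sx = E[0, ax, bx, 0]
                    sy = E[1, ay, by, 0]
                    sz = E[2, az, bz, 0]
                    S_blk[ii, jj] += ca * cb * fac * sx * sy * sz
                    # kinetic along each dimension
                    tx = 4.0 * b * b * E[0, ax, bx + 2, 0] - 2.0 * b * (2.0 * bx + 1.0) * sx
                    if bx >= 2:
                        tx += bx * (bx - 1.0) * E[0, ax, bx - 2, 0]
                    ty = 4.0 * b * b * E[1, ay, by + 2, 0] - 2.0 * b * (2.0 * by + 1.0) * sy
                    if by >= 2:
                        ty += by * (by - 1.0) * E[1, ay, by - 2, 0]
                    tz = 4.0 * b * b * E[2, az, bz + 2, 0] - 2.0 * b * (2.0 * bz + 1.0) * sz
                    if bz >= 2:
                        tz += bz * (bz - 1.0) * E[2, az, bz - 2, 0]
                    T_blk[ii, jj] += (
                        -0.5 * ca * cb * fac * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
                    )


@njit(cache=True)
def _pair_nuclear(l1, l2, exps1, coefs1, exps2, coefs2, A, B, cart1, cart2,
                  charges, centers_nuc, V_blk):
    nc1 = cart1.shape[0]
    nc2 = cart2.shape[0]
    L = l1 + l2
    AB = A - B
    E = np.zeros((3, l1 + 3, l2 + 3, l1 + l2 + 5))
    R = np.zeros((L + 2, L + 1, L + 1, L + 1))
    for ii in range(nc1):
        for jj in range(nc2):
            V_blk[ii, jj] = 0.0
    for ip in range(len(exps1)):
        a = exps1[ip]
        ca = coefs1[ip]
        for jp in range(len(exps2)):
            b = exps2[jp]
            cb = coefs2[jp]
            p = a + b
            e_tables(l1, l2, a, b, AB, E)
            P = (a * A + b * B) / p
            fac = 2.0 * np.pi / p * ca * cb
            for ic in range(len(charges)):
                Z = charges[ic]
                if Z == 0.0:
                    continue
                X = P[0] - centers_nuc[ic, 0]
                Y = P[1] - centers_nuc[ic, 1]
                Zd = P[2] - centers_nuc[ic, 2]
                hermite_R(L, p, X, Y, Zd, R)
                for ii in range(nc1):
                    ax, ay, az = cart1[ii, 0], cart1[ii, 1], cart1[ii, 2]
                    for jj in range(nc2):
                        bx, by, bz = cart2[jj, 0], cart2[jj, 1], cart2[jj, 2]
                        acc = 0.0
                        for t in range(ax + bx + 1):
                            ex = E[0, ax, bx, t]
                            if ex == 0.0:
                                continue
                            for u in range(ay + by + 1):
                                ey = E[1, ay, by, u]
                                if ey == 0.0:
                                    continue
                                for v in range(az + bz + 1):
                                    acc += ex * ey * E[2, az, bz, v] * R[0, t, u, v]
                        V_blk[ii, jj] += -Z * fac * acc


# ---------------------------------------------------------------------------
# two-electron integrals
# ---------------------------------------------------------------------------


@njit(cache=True)
def _herm_list(L):
    n = (L + 1) * (L + 2) * (L + 3) // 6
    out = np.zeros((n, 3), dtype=np.int64)
    idx = 0
    for total in range(L + 1):
        for t in range(total + 1):
            for u in range(total - t + 1):
                out[idx, 0] = t
                out[idx, 1] = u
                out[idx, 2] = total - t - u
                idx += 1
    return out


@njit(cache=True)
def _build_pair_data(ls, nprim, exps, coefs, centers, cart_all, cart_off):
    """Per canonical shell pair (i >= j): primitive p, P, coefficient and theta.

    theta[prim, cart12, herm] is flattened into one array with offsets.
    """
    ns = len(ls)
    npair = ns * (ns + 1) // 2
    pair_i = np.zeros(npair, dtype=np.int64)
    pair_j = np.zeros(npair, dtype=np.int64)
    prim_count = np.zeros(npair, dtype=np.int64)
    theta_size = np.zeros(npair, dtype=np.int64)
    pp = 0
    for i in range(ns):
        for j in range(i + 1):
            pair_i[pp] = i
            pair_j[pp] = j
            L12 = ls[i] + ls[j]
            nh = (L12 + 1) * (L12 + 2) * (L12 + 3) // 6
            nc = ((ls[i] + 1) * (ls[i] + 2) // 2) * ((ls[j] + 1) * (ls[j] + 2) // 2)
            prim_count[pp] = nprim[i] * nprim[j]
            theta_size[pp] = prim_count[pp] * nc * nh
            pp += 1
    prim_off = np.zeros(npair + 1, dtype=np.int64)
    theta_off = np.zeros(npair + 1, dtype=np.int64)
    for pp in range(npair):
        prim_off[pp + 1] = prim_off[pp] + prim_count[pp]
        theta_off[pp + 1] = theta_off[pp] + theta_size[pp]
    tot_prim = prim_off[npair]
    pp_p = np.zeros(tot_prim)
    pp_P = np.zeros((tot_prim, 3))
    pp_cc = np.zeros(tot_prim)
    theta = np.zeros(theta_off[npair])

    Lm = int(np.max(ls))
    E = np.zeros((3, Lm + 3, Lm + 3, 2 * Lm + 5))
    for pp in range(npair):
        i = pair_i[pp]
        j = pair_j[pp]
        l1 = ls[i]
        l2 = ls[j]
        L12 = l1 + l2
        hlist = _herm_list(L12)
        nh = hlist.shape[0]
        nc1 = (l1 + 1) * (l1 + 2) // 2
        nc2 = (l2 + 1) * (l2 + 2) // 2
        A = centers[i]
        B = centers[j]
        AB = A - B
        kk = 0
        for ip in range(nprim[i]):
            a = exps[i, ip]
            for jp in range(nprim[j]):
                b = exps[j, jp]
                p = a + b
                idx = prim_off[pp] + kk
                pp_p[idx] = p
                for d in range(3):
                    pp_P[idx, d] = (a * A[d] + b * B[d]) / p
                pp_cc[idx] = coefs[i, ip] * coefs[j, jp]
                e_tables(l1, l2, a, b, AB, E)
                base = theta_off[pp] + kk * nc1 * nc2 * nh
                for ii in range(nc1):
                    ax = cart_all[cart_off[l1] + ii, 0]
                    ay = cart_all[cart_off[l1] + ii, 1]
                    az = cart_all[cart_off[l1] + ii, 2]
                    for jj in range(nc2):
                        bx = cart_all[cart_off[l2] + jj, 0]
                        by = cart_all[cart_off[l2] + jj, 1]
                        bz = cart_all[cart_off[l2] + jj, 2]
                        row = base + (ii * nc2 + jj) * nh
                        for h in range(nh):
                            t = hlist[h, 0]
                            u = hlist[h, 1]
                            v = hlist[h, 2]
                            if t <= ax + bx and u <= ay + by and v <= az + bz:
                                theta[row + h] = (
                                    E[0, ax, bx, t] * E[1, ay, by, u] * E[2, az, bz, v]
                                )
                            else:
                                theta[row + h] = 0.0
                kk += 1
    return (pair_i, pair_j, prim_off, theta_off, pp_p, pp_P, pp_cc, theta)


@njit(cache=True)
def _quartet(pp, qq, ls, pair_i, pair_j, prim_off, theta_off, pp_p, pp_P, pp_cc,
             theta, hlist12, hlist34, hmap, R, out):
    """Contracted Cartesian ERI block for canonical pair quartet (pp|qq)."""
    i = pair_i[pp]
    j = pair_j[pp]
    k = pair_i[qq]
    l = pair_j[qq]
    l12 = ls[i] + ls[j]
    l34 = ls[k] + ls[l]
    L = l12 + l34
    nh12 = hlist12.shape[0]
    nh34 = hlist34.shape[0]
    nc12 = ((ls[i] + 1) * (ls[i] + 2) // 2) * ((ls[j] + 1) * (ls[j] + 2) // 2)
    nc34 = ((ls[k] + 1) * (ls[k] + 2) // 2) * ((ls[l] + 1) * (ls[l] + 2) // 2)
    for a in range(nc12):
        for b in range(nc34):
            out[a, b] = 0.0
    M = np.zeros((nh12, nh34))
    tmp = np.zeros((nc12, nh34))
    for u1 in range(prim_off[pp], prim_off[pp + 1]):
        p = pp_p[u1]
        base1 = theta_off[pp] + (u1 - prim_off[pp]) * nc12 * nh12
        for u2 in range(prim_off[qq], prim_off[qq + 1]):
            q = pp_p[u2]
            alpha = p * q / (p + q)
            X = pp_P[u1, 0] - pp_P[u2, 0]
            Y = pp_P[u1, 1] - pp_P[u2, 1]
            Z = pp_P[u1, 2] - pp_P[u2, 2]
            hermite_R(L, alpha, X, Y, Z, R)
            pref = pp_cc[u1] * pp_cc[u2] * TWO_PI_POW / (p * q * np.sqrt(p + q))
            for h1 in range(nh12):
                t1 = hlist12[h1, 0]
                u1h = hlist12[h1, 1]
                v1 = hlist12[h1, 2]
                for h2 in range(nh34):
                    t2 = hlist34[h2, 0]
                    u2h = hlist34[h2, 1]
                    v2 = hlist34[h2, 2]
                    sgn = 1.0 if (t2 + u2h + v2) % 2 == 0 else -1.0
                    M[h1, h2] = sgn * R[0, t1 + t2, u1h + u2h, v1 + v2]
            base2 = theta_off[qq] + (u2 - prim_off[qq]) * nc34 * nh34
            # tmp = theta1 @ M ; out += pref * tmp @ theta2.T
            for a in range(nc12):
                row1 = base1 + a * nh12
                for h2 in range(nh34):
                    acc = 0.0
                    for h1 in range(nh12):
                        acc += theta[row1 + h1] * M[h1, h2]
                    tmp[a, h2] = acc
            for a in range(nc12):
                for b in range(nc34):
                    row2 = base2 + b * nh34
                    acc = 0.0
                    for h2 in range(nh34):
                        acc += tmp[a, h2] * theta[row2 + h2]
                    out[a, b] += pref * acc


@njit(cache=True)
def compute_eri(ls, nprim, exps, coefs, centers, sph_off, c2s_flat, c2s_nsph,
                c2s_ncart, nao, screen_thresh):
    ns = len(ls)
    cart_off = np.zeros(4, dtype=np.int64)
    ncart_tot = 0
    for l in range(3):
        cart_off[l] = ncart_tot
        ncart_tot += (l + 1) * (l + 2) // 2
    cart_off[3] = ncart_tot
    cart_all = np.zeros((ncart_tot, 3), dtype=np.int64)
    for l in range(3):
        idx = cart_off[l]
        for ii in range(l, -1, -1):
            for jj in range(l - ii, -1, -1):
                cart_all[idx, 0] = ii
                cart_all[idx, 1] = jj
                cart_all[idx, 2] = l - ii - jj
                idx += 1

    (pair_i, pair_j, prim_off, theta_off, pp_p, pp_P, pp_cc, theta) = _build_pair_data(
        ls, nprim, exps, coefs, centers, cart_all, cart_off
    )
    npair = len(pair_i)
    Lmax = int(np.max(ls))
    Lq = 4 * Lmax
    R = np.zeros((Lq + 2, Lq + 1, Lq + 1, Lq + 1))
    hmap = np.zeros((Lq + 1, Lq + 1, Lq + 1), dtype=np.int64)
    hlists = []
    for L in range(2 * Lmax + 1):
        hlists.append(_herm_list(L))
    ncmax = ((Lmax + 1) * (Lmax + 2) // 2) ** 2
    blk = np.zeros((ncmax, ncmax))

    # Schwarz screening bounds per pair
    qbound = np.zeros(npair)
    for pp in range(npair):
        l12 = ls[pair_i[pp]] + ls[pair_j[pp]]
        _quartet(pp, pp, ls, pair_i, pair_j, prim_off, theta_off, pp_p, pp_P,
                 pp_cc, theta, hlists[l12], hlists[l12], hmap, R, blk)
        nc12 = ((ls[pair_i[pp]] + 1) * (ls[pair_i[pp]] + 2) // 2) * (
            (ls[pair_j[pp]] + 1) * (ls[pair_j[pp]] + 2) // 2)
        m = 0.0
        for a in range(nc12):
            if abs(blk[a, a]) > m:
                m = abs(blk[a, a])
        qbound[pp] = np.sqrt(m)

    eri = np.zeros((nao, nao, nao, nao))
    sblk = np.zeros((25, 25))  # spherical block scratch (max d-d pair: 5*5)
    t1 = np.zeros((ncmax, ncmax))
    for pp in range(npair):
        i = pair_i[pp]
        j = pair_j[pp]
        l12 = ls[i] + ls[j]
        for qq in range(pp + 1):
            if qbound[pp] * qbound[qq] < screen_thresh:
                continue
            k = pair_i[qq]
            l = pair_j[qq]
            l34 = ls[k] + ls[l]
            _quartet(pp, qq, ls, pair_i, pair_j, prim_off, theta_off, pp_p, pp_P,
                     pp_cc, theta, hlists[l12], hlists[l34], hmap, R, blk)
            # transform cartesian block to spherical: rows (cart_i x cart_j),
            # cols (cart_k x cart_l)
            ni, nj = c2s_nsph[ls[i]], c2s_nsph[ls[j]]
            nk, nl = c2s_nsph[ls[k]], c2s_nsph[ls[l]]
            mci, mcj = c2s_ncart[ls[i]], c2s_ncart[ls[j]]
            mck, mcl = c2s_ncart[ls[k]], c2s_ncart[ls[l]]
            nc12 = mci * mcj
            nc34 = mck * mcl
            nsph12 = ni * nj
            nsph34 = nk * nl
            # rows: t1 = (Ci (x) Cj) @ blk
            for a in range(nsph12):
                ia = a // nj
                ja = a % nj
                for b in range(nc34):
                    acc = 0.0
                    for c1 in range(mci):
                        w1 = c2s_flat[ls[i], ia, c1]
                        if w1 == 0.0:
                            continue
                        for c2 in range(mcj):
                            w = w1 * c2s_flat[ls[j], ja, c2]
                            if w == 0.0:
                                continue
                            acc += w * blk[c1 * mcj + c2, b]
                    t1[a, b] = acc
            for a in range(nsph12):
                for b in range(nsph34):
                    kb = b // nl
                    lb = b % nl
                    acc = 0.0
                    for c3 in range(mck):
                        w3 = c2s_flat[ls[k], kb, c3]
                        if w3 == 0.0:
                            continue
                        for c4 in range(mcl):
                            w = w3 * c2s_flat[ls[l], lb, c4]
                            if w == 0.0:
                                continue
                            acc += w * t1[a, c3 * mcl + c4]
                    sblk[a, b] = acc
            # scatter with 8-fold symmetry
            oi = sph_off[i]
            oj = sph_off[j]
            ok = sph_off[k]
            ol = sph_off[l]
            for a in range(ni):
                for b in range(nj):
                    v12 = sblk[a * nj + b]
                    for c in range(nk):
                        for d in range(nl):
                            val = v12[c * nl + d]
                            p1 = oi + a
                            q1 = oj + b
                            r1 = ok + c
                            s1 = ol + d
                            eri[p1, q1, r1, s1] = val
                            eri[q1, p1, r1, s1] = val
                            eri[p1, q1, s1, r1] = val
                            eri[q1, p1, s1, r1] = val
                            eri[r1, s1, p1, q1] = val
                            eri[s1, r1, p1, q1] = val
                            eri[r1, s1, q1, p1] = val
                            eri[s1, r1, q1, p1] = val
    return eri
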