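"""Compiled Metropolis Monte Carlo kernels (numba).

Three samplers:

* ``pivot_kernel`` — pivot moves on an open chain under a harmonic end-to-end
  restraint; records the end-to-end distance of accepted conformations.
* ``crankshaft_kernel`` — crankshaft arc rotations on an exactly closed ring;
  tracks all joint angles incrementally and counts kinked steps.
* ``free_chain_kernel`` — direct equilibrium draws of unrestrained chains
  (i.i.d. joint angles from the single-step Boltzmann density via an
  inverse-CDF table); exact for a phantom chain, no Markov chain needed.

All kernels are seeded explicitly and deterministic for a given seed.
Energies are in kBT, lengths in nm. Models are passed as packed scalars
(code, k, B, h, b); see ``BendingModel.pack``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "pivot_kernel",
    "crankshaft_kernel",
    "hladder_crankshaft_kernel",
    "hladder_pivot_kernel",
    "free_chain_kernel",
]


@njit(cache=True, inline="always")
def _bend_e(code, k, B, h, b, th):
    if code == 0:
        return 0.5 * k * th * th
    elif code == 1:
        return B * abs(th)
    else:
        e1 = 0.5 * k * th * th
        d = th - b
        e2 = h + d * d * d * d * d * d
        return e1 if e1 < e2 else e2


@njit(cache=True, inline="always")
def _rand_rotation(ux, uy, uz, ang):
    ca = np.cos(ang)
    sa = np.sin(ang)
    C = 1.0 - ca
    return (
        ca + ux * ux * C, ux * uy * C - uz * sa, ux * uz * C + uy * sa,
        uy * ux * C + uz * sa, ca + uy * uy * C, uy * uz * C - ux * sa,
        uz * ux * C - uy * sa, uz * uy * C + ux * sa, ca + uz * uz * C,
    )


@njit(cache=True)
def pivot_kernel(code, k, B, h, b, l, K, r0, verts, n_equil, n_record, thin,
                 seed, max_proposals):
    """Pivot-move Metropolis sampling of a restrained open chain.

    A uniform random interior vertex is chosen, the shorter tail is rotated
    about a uniform random axis through it by an angle uniform in [-pi, pi].
    Only the bend angle at the pivot and the restraint term change, so the
    energy update is O(1); applying an accepted move is O(tail).

    The current end-to-end distance is recorded every ``thin``-th proposal
    after equilibration — the state repeats when a proposal is rejected, so
    recorded samples are correctly dwell-time-weighted Metropolis averages
    (recording accepted moves only would weight states by acceptance flux).

    Returns (r_out, n_recorded, n_accepted, n_proposals). ``verts`` is
    updated in place (the final conformation).
    """
    N = verts.shape[0] - 1
    out = np.empty(n_record)
    ll = l * l
    r = np.sqrt(
        (verts[N, 0] - verts[0, 0]) ** 2
        + (verts[N, 1] - verts[0, 1]) ** 2
        + (verts[N, 2] - verts[0, 2]) ** 2
    )
    np.random.seed(seed)
    acc = 0
    i_out = 0
    steps = 0
    since_record = 0
    while i_out < n_record and steps < max_proposals:
        steps += 1
        j = 1 + np.random.randint(N - 1)
        tail_hi = j >= (N + 1) // 2
        z = 2.0 * np.random.rand() - 1.0
        phi = 2.0 * np.pi * np.random.rand()
        s = np.sqrt(max(0.0, 1.0 - z * z))
        ux = s * np.cos(phi)
        uy = s * np.sin(phi)
        uz = z
        ang = (2.0 * np.random.rand() - 1.0) * np.pi
        R00, R01, R02, R10, R11, R12, R20, R21, R22 = _rand_rotation(ux, uy, uz, ang)
        px, py, pz = verts[j, 0], verts[j, 1], verts[j, 2]
        ax = verts[j, 0] - verts[j - 1, 0]
        ay = verts[j, 1] - verts[j - 1, 1]
        az = verts[j, 2] - verts[j - 1, 2]
        bx = verts[j + 1, 0] - verts[j, 0]
        by = verts[j + 1, 1] - verts[j, 1]
        bz = verts[j + 1, 2] - verts[j, 2]
        cth = (ax * bx + ay * by + az * bz) / ll
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        th_old = np.arccos(cth)
        if tail_hi:
            qx = verts[j + 1, 0] - px
            qy = verts[j + 1, 1] - py
            qz = verts[j + 1, 2] - pz
            nx = R00 * qx + R01 * qy + R02 * qz
            ny = R10 * qx + R11 * qy + R12 * qz
            nz = R20 * qx + R21 * qy + R22 * qz
            cth = (ax * nx + ay * ny + az * nz) / ll
        else:
            qx = verts[j - 1, 0] - px
            qy = verts[j - 1, 1] - py
            qz = verts[j - 1, 2] - pz
            nx = R00 * qx + R01 * qy + R02 * qz
            ny = R10 * qx + R11 * qy + R12 * qz
            nz = R20 * qx + R21 * qy + R22 * qz
            cth = -(bx * nx + by * ny + bz * nz) / ll
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        th_new = np.arccos(cth)
        dE = _bend_e(code, k, B, h, b, th_new) - _bend_e(code, k, B, h, b, th_old)
        if tail_hi:
            ex = verts[N, 0] - px
            ey = verts[N, 1] - py
            ez = verts[N, 2] - pz
            rex = R00 * ex + R01 * ey + R02 * ez
            rey = R10 * ex + R11 * ey + R12 * ez
            rez = R20 * ex + R21 * ey + R22 * ez
            r_new = np.sqrt(
                (px + rex - verts[0, 0]) ** 2
                + (py + rey - verts[0, 1]) ** 2
                + (pz + rez - verts[0, 2]) ** 2
            )
        else:
            ex = verts[0, 0] - px
            ey = verts[0, 1] - py
            ez = verts[0, 2] - pz
            rex = R00 * ex + R01 * ey + R02 * ez
            rey = R10 * ex + R11 * ey + R12 * ez
            rez = R20 * ex + R21 * ey + R22 * ez
            r_new = np.sqrt(
                (verts[N, 0] - px - rex) ** 2
                + (verts[N, 1] - py - rey) ** 2
                + (verts[N, 2] - pz - rez) ** 2
            )
        if K > 0.0:
            dE += 0.5 * K * ((r_new - r0) ** 2 - (r - r0) ** 2)
        if dE <= 0.0 or np.random.rand() < np.exp(-dE):
            if tail_hi:
                for m in range(j + 1, N + 1):
                    qx = verts[m, 0] - px
                    qy = verts[m, 1] - py
                    qz = verts[m, 2] - pz
                    verts[m, 0] = px + R00 * qx + R01 * qy + R02 * qz
                    verts[m, 1] = py + R10 * qx + R11 * qy + R12 * qz
                    verts[m, 2] = pz + R20 * qx + R21 * qy + R22 * qz
            else:
                for m in range(0, j):
                    qx = verts[m, 0] - px
                    qy = verts[m, 1] - py
                    qz = verts[m, 2] - pz
                    verts[m, 0] = px + R00 * qx + R01 * qy + R02 * qz
                    verts[m, 1] = py + R10 * qx + R11 * qy + R12 * qz
                    verts[m, 2] = pz + R20 * qx + R21 * qy + R22 * qz
            r = r_new
            acc += 1
        if steps > n_equil:
            since_record += 1
            if since_record >= thin:
                out[i_out] = r
                i_out += 1
                since_record = 0
    return out[:i_out], i_out, acc, steps


@njit(cache=True, inline="always")
def _ring_angle(verts, i, ll):
    N = verts.shape[0]
    ip = i + 1 if i + 1 < N else 0
    im = i - 1 if i > 0 else N - 1
    ax = verts[i, 0] - verts[im, 0]
    ay = verts[i, 1] - verts[im, 1]
    az = verts[i, 2] - verts[im, 2]
    bx = verts[ip, 0] - verts[i, 0]
    by = verts[ip, 1] - verts[i, 1]
    bz = verts[ip, 2] - verts[i, 2]
    c = (ax * bx + ay * by + az * bz) / ll
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c)


@njit(cache=True)
def _crank_step(code, k, B, h, b, ll, verts, th, theta_c, beta,
                lo1, hi1, lo2, hi2):
    """One crankshaft proposal on a closed ring at inverse temperature beta.

    Mutates ``verts`` and ``th`` on acceptance. Returns (accepted, dE,
    d_n_above): energy change (kBT) and change in the number of joints bent
    beyond theta_c.
    """
    N = verts.shape[0]
    i = np.random.randint(N)
    d = 2 + np.random.randint(N - 3)  # arc length, 2..N-2
    jj = i + d
    j = jj - N if jj >= N else jj
    axx = verts[j, 0] - verts[i, 0]
    axy = verts[j, 1] - verts[i, 1]
    axz = verts[j, 2] - verts[i, 2]
    norm = np.sqrt(axx * axx + axy * axy + axz * axz)
    if norm < 1e-12:
        return 0, 0.0, 0
    ux = axx / norm
    uy = axy / norm
    uz = axz / norm
    if np.random.rand() < 0.5:
        ang = lo1 + (hi1 - lo1) * np.random.rand()
    else:
        ang = lo2 + (hi2 - lo2) * np.random.rand()
    R00, R01, R02, R10, R11, R12, R20, R21, R22 = _rand_rotation(ux, uy, uz, ang)
    px, py, pz = verts[i, 0], verts[i, 1], verts[i, 2]
    # new angle at joint i: link (i-1 -> i) fixed, link (i -> i+1) rotated
    im = i - 1 if i > 0 else N - 1
    ip = i + 1 if i + 1 < N else 0
    ax = verts[i, 0] - verts[im, 0]
    ay = verts[i, 1] - verts[im, 1]
    az = verts[i, 2] - verts[im, 2]
    qx = verts[ip, 0] - px
    qy = verts[ip, 1] - py
    qz = verts[ip, 2] - pz
    nx = R00 * qx + R01 * qy + R02 * qz
    ny = R10 * qx + R11 * qy + R12 * qz
    nz = R20 * qx + R21 * qy + R22 * qz
    c = (ax * nx + ay * ny + az * nz) / ll
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th_i_new = np.arccos(c)
    # new angle at joint j: link (j-1 -> j) rotated, link (j -> j+1) fixed
    jm = j - 1 if j > 0 else N - 1
    jp = j + 1 if j + 1 < N else 0
    qx = verts[jm, 0] - px
    qy = verts[jm, 1] - py
    qz = verts[jm, 2] - pz
    nx = px + R00 * qx + R01 * qy + R02 * qz
    ny = py + R10 * qx + R11 * qy + R12 * qz
    nz = pz + R20 * qx + R21 * qy + R22 * qz
    ax = verts[j, 0] - nx
    ay = verts[j, 1] - ny
    az = verts[j, 2] - nz
    bx = verts[jp, 0] - verts[j, 0]
    by = verts[jp, 1] - verts[j, 1]
    bz = verts[jp, 2] - verts[j, 2]
    c = (ax * bx + ay * by + az * bz) / ll
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th_j_new = np.arccos(c)
    dE = (
        _bend_e(code, k, B, h, b, th_i_new)
        + _bend_e(code, k, B, h, b, th_j_new)
        - _bend_e(code, k, B, h, b, th[i])
        - _bend_e(code, k, B, h, b, th[j])
    )
    if dE <= 0.0 or np.random.rand() < np.exp(-beta * dE):
        m = i + 1
        while True:
            mm = m - N if m >= N else m
            if mm == j:
                break
            qx = verts[mm, 0] - px
            qy = verts[mm, 1] - py
            qz = verts[mm, 2] - pz
            verts[mm, 0] = px + R00 * qx + R01 * qy + R02 * qz
            verts[mm, 1] = py + R10 * qx + R11 * qy + R12 * qz
            verts[mm, 2] = pz + R20 * qx + R21 * qy + R22 * qz
            m += 1
        d_above = 0
        if th[i] > theta_c:
            d_above -= 1
        if th[j] > theta_c:
            d_above -= 1
        th[i] = th_i_new
        th[j] = th_j_new
        if th[i] > theta_c:
            d_above += 1
        if th[j] > theta_c:
            d_above += 1
        return 1, dE, d_above
    return 0, 0.0, 0


@njit(cache=True)
def crankshaft_kernel(code, k, B, h, b, l, verts, theta_c, n_equil, n_record,
                      lo1, hi1, lo2, hi2, seed, max_proposals, hist, hist_max):
    """Crankshaft Metropolis sampling of an exactly closed ring.

    Two distinct non-adjacent vertices are chosen uniformly; the forward arc
    between them is rotated about the axis through them by an angle drawn
    from one of two uniform intervals (chosen with equal probability). Only
    the two joint angles at the arc ends change, so closure and all link
    lengths are preserved exactly by construction.

    Joint angles are tracked incrementally; the state is recorded at every
    post-equilibration proposal (repeating on rejection, so averages are
    dwell-time-weighted) and the number of steps with angle > ``theta_c``
    accumulated. ``hist`` (angle histogram over [0, pi],
    populated with all joint angles of every recorded conformation) is
    filled in place.

    Returns (n_recorded, n_with_kink, kink_sum, min_energy, n_accepted,
    n_proposals).
    """
    N = verts.shape[0]
    ll = l * l
    th = np.empty(N)
    for i in range(N):
        th[i] = _ring_angle(verts, i, ll)
    E = 0.0
    n_above = 0
    for i in range(N):
        E += _bend_e(code, k, B, h, b, th[i])
        if th[i] > theta_c:
            n_above += 1
    E_min = E
    nbins = hist.shape[0]
    np.random.seed(seed)
    acc = 0
    rec = 0
    with_kink = 0
    kink_sum = 0
    steps = 0
    while rec < n_record and steps < max_proposals:
        steps += 1
        a, dE, d_above = _crank_step(code, k, B, h, b, ll, verts, th, theta_c,
                                     1.0, lo1, hi1, lo2, hi2)
        if a == 1:
            E += dE
            n_above += d_above
            if E < E_min:
                E_min = E
            acc += 1
        if steps > n_equil:
            rec += 1
            if n_above > 0:
                with_kink += 1
            kink_sum += n_above
            if rec <= hist_max:
                for m in range(N):
                    bi = int(th[m] / np.pi * nbins)
                    if bi >= nbins:
                        bi = nbins - 1
                    hist[bi] += 1
    return rec, with_kink, kink_sum, E_min, acc, steps


@njit(cache=True)
def free_chain_kernel(cdf, l, n_links, n_chains, seed, sep_grid, i_stride):
    """Direct equilibrium sampling of unrestrained chains.

    Each chain draws independent joint angles by inverse-transform sampling
    (binary search on the tabulated CDF of the single-step Boltzmann density
    with sin(theta) Jacobian over a uniform theta grid) and uniform azimuths.
    Returns (corr_sums, corr_counts, r_values): tangent-correlation sums over
    origin positions spaced ``i_stride`` apart for each separation in
    ``sep_grid`` (links), and the end-to-end distance of every chain.
    """
    G = cdf.shape[0]
    dth = np.pi / (G - 1)
    n_sep = sep_grid.shape[0]
    corr = np.zeros(n_sep)
    cnt = np.zeros(n_sep, dtype=np.int64)
    r_out = np.empty(n_chains)
    tang = np.empty((n_links, 3))
    np.random.seed(seed)
    for c in range(n_chains):
        tx, ty, tz = 0.0, 0.0, 1.0
        tang[0, 0] = tx
        tang[0, 1] = ty
        tang[0, 2] = tz
        ex, ey, ez = tx, ty, tz
        for i in range(1, n_links):
            u = np.random.rand()
            lo = 0
            hi = G - 1
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if cdf[mid] <= u:
                    lo = mid
                else:
                    hi = mid
            du = cdf[hi] - cdf[lo]
            frac = (u - cdf[lo]) / du if du > 0 else 0.0
            theta = (lo + frac) * dth
            phi = 2.0 * np.pi * np.random.rand()
            # orthonormal frame around current tangent
            if abs(tz) < 0.9:
                n1x = -ty
                n1y = tx
                n1z = 0.0
            else:
                n1x = 0.0
                n1y = -tz
                n1z = ty
            nn = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            n1x /= nn
            n1y /= nn
            n1z /= nn
            n2x = ty * n1z - tz * n1y
            n2y = tz * n1x - tx * n1z
            n2z = tx * n1y - ty * n1x
            st = np.sin(theta)
            ct = np.cos(theta)
            cp = np.cos(phi)
            sp = np.sin(phi)
            tx = ct * tx + st * (cp * n1x + sp * n2x)
            ty = ct * ty + st * (cp * n1y + sp * n2y)
            tz = ct * tz + st * (cp * n1z + sp * n2z)
            nn = np.sqrt(tx * tx + ty * ty + tz * tz)
            tx /= nn
            ty /= nn
            tz /= nn
            tang[i, 0] = tx
            tang[i, 1] = ty
            tang[i, 2] = tz
            ex += tx
            ey += ty
            ez += tz
        r_out[c] = l * np.sqrt(ex * ex + ey * ey + ez * ez)
        for si in range(n_sep):
            s = sep_grid[si]
            i = 0
            while i + s < n_links:
                corr[si] += (
                    tang[i, 0] * tang[i + s, 0]
                    + tang[i, 1] * tang[i + s, 1]
                    + tang[i, 2] * tang[i + s, 2]
                )
                cnt[si] += 1
                i += i_stride
    return corr, cnt, r_out


@njit(cache=True)
def _ring_energy_kwlc(k, h, b, th):
    E = 0.0
    for i in range(th.shape[0]):
        e1 = 0.5 * k * th[i] * th[i]
        d = th[i] - b
        e2 = h + d * d * d * d * d * d
        E += e1 if e1 < e2 else e2
    return E


@njit(cache=True)
def hladder_crankshaft_kernel(k, b, l, hs, verts, theta_c, n_equil, n_record,
                              lo1, hi1, lo2, hi2, swap_every, seed,
                              max_sweeps, hist, hist_max):
    """Crankshaft sampling of kinkable rings with Hamiltonian exchange over
    a ladder of kink barriers.

    Replica r evolves under the kinkable bending energy with barrier
    ``hs[r]`` (hs[0] is the physical barrier; subsequent entries decrease,
    so kinks form and vanish freely at the bottom of the ladder). Every
    ``swap_every`` sweeps neighboring replicas attempt a configuration
    exchange with acceptance min(1, exp(-[E_a(x_b) + E_b(x_a) - E_a(x_a) -
    E_b(x_b)])); the cross energies are recomputed exactly from the joint
    angles. Kink statistics are recorded from replica 0 only, once per
    post-equilibration sweep (dwell-time weighted).

    Returns (rec, with_kink, kink_sum, E_min, acc0, sweeps, n_swap_acc).
    """
    R = verts.shape[0]
    N = verts.shape[1]
    ll = l * l
    th = np.empty((R, N))
    E = np.zeros(R)
    n_above = np.zeros(R, dtype=np.int64)
    for r in range(R):
        for i in range(N):
            th[r, i] = _ring_angle(verts[r], i, ll)
            if th[r, i] > theta_c:
                n_above[r] += 1
        E[r] = _ring_energy_kwlc(k, hs[r], b, th[r])
    E_min = E[0]
    nbins = hist.shape[0]
    np.random.seed(seed)
    acc0 = 0
    rec = 0
    with_kink = 0
    kink_sum = 0
    sweeps = 0
    n_swap_acc = 0
    parity = 0
    while rec < n_record and sweeps < max_sweeps:
        sweeps += 1
        for r in range(R):
            a, dE, d_above = _crank_step(2, k, 0.0, hs[r], b, ll, verts[r],
                                         th[r], theta_c, 1.0,
                                         lo1, hi1, lo2, hi2)
            if a == 1:
                E[r] += dE
                n_above[r] += d_above
                if r == 0:
                    if E[0] < E_min:
                        E_min = E[0]
                    acc0 += 1
            if r == 0 and sweeps > n_equil:
                rec += 1
                if n_above[0] > 0:
                    with_kink += 1
                kink_sum += n_above[0]
                if rec <= hist_max:
                    for m in range(N):
                        bi = int(th[0, m] / np.pi * nbins)
                        if bi >= nbins:
                            bi = nbins - 1
                        hist[bi] += 1
        if sweeps % swap_every == 0:
            for r in range(parity, R - 1, 2):
                e_r_xb = _ring_energy_kwlc(k, hs[r], b, th[r + 1])
                e_rp_xa = _ring_energy_kwlc(k, hs[r + 1], b, th[r])
                darg = -(e_r_xb + e_rp_xa - E[r] - E[r + 1])
                if darg >= 0.0 or np.random.rand() < np.exp(darg):
                    for i in range(N):
                        for c3 in range(3):
                            tmp = verts[r, i, c3]
                            verts[r, i, c3] = verts[r + 1, i, c3]
                            verts[r + 1, i, c3] = tmp
                        tmpa = th[r, i]
                        th[r, i] = th[r + 1, i]
                        th[r + 1, i] = tmpa
                    E[r] = e_r_xb
                    E[r + 1] = e_rp_xa
                    tmpn = n_above[r]
                    n_above[r] = n_above[r + 1]
                    n_above[r + 1] = tmpn
                    n_swap_acc += 1
            parity = 1 - parity
    return rec, with_kink, kink_sum, E_min, acc0, sweeps, n_swap_acc


@njit(cache=True)
def _open_chain_kwlc_energy(k, h, b, verts, ll):
    """Total kinkable bending energy of an open chain from its joint angles."""
    N = verts.shape[0] - 1
    E = 0.0
    for i in range(1, N):
        ax = verts[i, 0] - verts[i - 1, 0]
        ay = verts[i, 1] - verts[i - 1, 1]
        az = verts[i, 2] - verts[i - 1, 2]
        bx = verts[i + 1, 0] - verts[i, 0]
        by = verts[i + 1, 1] - verts[i, 1]
        bz = verts[i + 1, 2] - verts[i, 2]
        c = (ax * bx + ay * by + az * bz) / ll
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        e1 = 0.5 * k * th * th
        d = th - b
        e2 = h + d * d * d * d * d * d
        E += e1 if e1 < e2 else e2
    return E


@njit(cache=True)
def _pivot_step(code, k, B, h, b, l, ll, K, r0, verts, r_cur):
    """One pivot proposal on an open restrained chain. Mutates ``verts`` on
    acceptance; returns (accepted, dE, r_new)."""
    N = verts.shape[0] - 1
    j = 1 + np.random.randint(N - 1)
    tail_hi = j >= (N + 1) // 2
    z = 2.0 * np.random.rand() - 1.0
    phi = 2.0 * np.pi * np.random.rand()
    s = np.sqrt(max(0.0, 1.0 - z * z))
    ux = s * np.cos(phi)
    uy = s * np.sin(phi)
    uz = z
    ang = (2.0 * np.random.rand() - 1.0) * np.pi
    R00, R01, R02, R10, R11, R12, R20, R21, R22 = _rand_rotation(ux, uy, uz, ang)
    px, py, pz = verts[j, 0], verts[j, 1], verts[j, 2]
    ax = verts[j, 0] - verts[j - 1, 0]
    ay = verts[j, 1] - verts[j - 1, 1]
    az = verts[j, 2] - verts[j - 1, 2]
    bx = verts[j + 1, 0] - verts[j, 0]
    by = verts[j + 1, 1] - verts[j, 1]
    bz = verts[j + 1, 2] - verts[j, 2]
    cth = (ax * bx + ay * by + az * bz) / ll
    if cth > 1.0:
        cth = 1.0
    elif cth < -1.0:
        cth = -1.0
    th_old = np.arccos(cth)
    if tail_hi:
        qx = verts[j + 1, 0] - px
        qy = verts[j + 1, 1] - py
        qz = verts[j + 1, 2] - pz
        nx = R00 * qx + R01 * qy + R02 * qz
        ny = R10 * qx + R11 * qy + R12 * qz
        nz = R20 * qx + R21 * qy + R22 * qz
        cth = (ax * nx + ay * ny + az * nz) / ll
    else:
        qx = verts[j - 1, 0] - px
        qy = verts[j - 1, 1] - py
        qz = verts[j - 1, 2] - pz
        nx = R00 * qx + R01 * qy + R02 * qz
        ny = R10 * qx + R11 * qy + R12 * qz
        nz = R20 * qx + R21 * qy + R22 * qz
        cth = -(bx * nx + by * ny + bz * nz) / ll
    if cth > 1.0:
        cth = 1.0
    elif cth < -1.0:
        cth = -1.0
    th_new = np.arccos(cth)
    dE = _bend_e(code, k, B, h, b, th_new) - _bend_e(code, k, B, h, b, th_old)
    if tail_hi:
        ex = verts[N, 0] - px
        ey = verts[N, 1] - py
        ez = verts[N, 2] - pz
        rex = R00 * ex + R01 * ey + R02 * ez
        rey = R10 * ex + R11 * ey + R12 * ez
        rez = R20 * ex + R21 * ey + R22 * ez
        r_new = np.sqrt(
            (px + rex - verts[0, 0]) ** 2
            + (py + rey - verts[0, 1]) ** 2
            + (pz + rez - verts[0, 2]) ** 2
        )
    else:
        ex = verts[0, 0] - px
        ey = verts[0, 1] - py
        ez = verts[0, 2] - pz
        rex = R00 * ex + R01 * ey + R02 * ez
        rey = R10 * ex + R11 * ey + R12 * ez
        rez = R20 * ex + R21 * ey + R22 * ez
        r_new = np.sqrt(
            (verts[N, 0] - px - rex) ** 2
            + (verts[N, 1] - py - rey) ** 2
            + (verts[N, 2] - pz - rez) ** 2
        )
    if K > 0.0:
        dE += 0.5 * K * ((r_new - r0) ** 2 - (r_cur - r0) ** 2)
    if dE <= 0.0 or np.random.rand() < np.exp(-dE):
        if tail_hi:
            for m in range(j + 1, N + 1):
                qx = verts[m, 0] - px
                qy = verts[m, 1] - py
                qz = verts[m, 2] - pz
                verts[m, 0] = px + R00 * qx + R01 * qy + R02 * qz
                verts[m, 1] = py + R10 * qx + R11 * qy + R12 * qz
                verts[m, 2] = pz + R20 * qx + R21 * qy + R22 * qz
        else:
            for m in range(0, j):
                qx = verts[m, 0] - px
                qy = verts[m, 1] - py
                qz = verts[m, 2] - pz
                verts[m, 0] = px + R00 * qx + R01 * qy + R02 * qz
                verts[m, 1] = py + R10 * qx + R11 * qy + R12 * qz
                verts[m, 2] = pz + R20 * qx + R21 * qy + R22 * qz
        return 1, dE, r_new
    return 0, dE, r_cur


@njit(cache=True)
def hladder_pivot_kernel(k, b, l, K, r0, hs, verts, n_equil, n_record, thin,
                         swap_every, seed, max_sweeps):
    """Pivot sampling of a restrained kinkable loop with Hamiltonian exchange
    over a ladder of kink barriers ``hs`` (hs[0] physical; decreasing).

    Kink formation in a sharply bent loop is a rare barrier-crossing event
    under plain pivot dynamics; replicas at reduced barriers nucleate and
    anneal kinks freely and exchange configurations with the physical
    replica (the shared restraint cancels in the swap, so only the kinkable
    bending energies cross). The end-to-end distance of the physical replica
    is recorded every ``thin``-th sweep after equilibration (dwell-time
    weighted).

    Returns (r_out, n_recorded, n_accepted0, sweeps, n_swap_acc).
    """
    R = verts.shape[0]
    N = verts.shape[1] - 1
    ll = l * l
    out = np.empty(n_record)
    r = np.empty(R)
    Eb = np.empty(R)  # bending energy under each replica's own barrier
    for q in range(R):
        r[q] = np.sqrt(
            (verts[q, N, 0] - verts[q, 0, 0]) ** 2
            + (verts[q, N, 1] - verts[q, 0, 1]) ** 2
            + (verts[q, N, 2] - verts[q, 0, 2]) ** 2
        )
        Eb[q] = _open_chain_kwlc_energy(k, hs[q], b, verts[q], ll)
    np.random.seed(seed)
    acc0 = 0
    i_out = 0
    sweeps = 0
    n_swap_acc = 0
    parity = 0
    since = 0
    while i_out < n_record and sweeps < max_sweeps:
        sweeps += 1
        for q in range(R):
            a, dE, r_new = _pivot_step(2, k, 0.0, hs[q], b, l, ll, K, r0,
                                       verts[q], r[q])
            if a == 1:
                if K > 0.0:
                    dE -= 0.5 * K * ((r_new - r0) ** 2 - (r[q] - r0) ** 2)
                Eb[q] += dE
                r[q] = r_new
                if q == 0:
                    acc0 += 1
        if sweeps > n_equil:
            since += 1
            if since >= thin:
                out[i_out] = r[0]
                i_out += 1
                since = 0
        if sweeps % swap_every == 0:
            for q in range(parity, R - 1, 2):
                e_q_xb = _open_chain_kwlc_energy(k, hs[q], b, verts[q + 1], ll)
                e_qp_xa = _open_chain_kwlc_energy(k, hs[q + 1], b, verts[q], ll)
                darg = -(e_q_xb + e_qp_xa - Eb[q] - Eb[q + 1])
                if darg >= 0.0 or np.random.rand() < np.exp(darg):
                    for i in range(N + 1):
                        for c3 in range(3):
                            tmp = verts[q, i, c3]
                            verts[q, i, c3] = verts[q + 1, i, c3]
                            verts[q + 1, i, c3] = tmp
                    Eb[q] = e_q_xb
                    Eb[q + 1] = e_qp_xa
                    tmpr = r[q]
                    r[q] = r[q + 1]
                    r[q + 1] = tmpr
                    n_swap_acc += 1
            parity = 1 - parity
    return out[:i_out], i_out, acc0, sweeps, n_swap_acc
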