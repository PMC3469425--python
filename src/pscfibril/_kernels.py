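"""Numba kernels: segment geometry, patchy pair potential, DMC sweep loop.

Everything here operates on plain float64 arrays so the hot loop stays in
nopython mode.  Model parameters travel as a packed float64 vector ``pp``
(see :data:`PP_FIELDS`); orientations are carried as two orthonormal unit
vectors per particle (cylinder axis and patch direction) rather than
quaternions, which keeps the energy evaluation allocation-free.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Layout of the packed parameter vector handed to every kernel.
PP_FIELDS = (
    "half_length",        # 0: half of the cylinder length, nm
    "sigma",              # 1: spherocylinder diameter, nm
    "cutoff",             # 2: attraction cutoff on the axis-axis distance, nm
    "eps_aa",             # 3: well depth alpha-alpha, kBT
    "eps_ab",             # 4: well depth alpha-beta (Berthelot), kBT
    "eps_bb",             # 5: well depth beta-beta, kBT
    "hw_alpha",           # 6: patch half-width, alpha state, rad
    "hw_beta",            # 7: patch half-width, beta state, rad
    "shoulder",           # 8: smooth gate shoulder width, rad
    "chirality",          # 9: patch twist at the cylinder end, rad
)

_EPS_PAR = 1e-12


@njit(cache=True)
def seg_seg_closest(rx, ry, rz, uax, uay, uaz, ubx, uby, ubz, hl):
    """Closest approach of two finite axis segments.

    Segment a runs through the origin along u_a, segment b through
    (rx, ry, rz) along u_b; both have half-length ``hl``.  Returns
    (distance, t_a, t_b) with the closest-point parameters in [-hl, hl].
    """
    b = uax * ubx + uay * uby + uaz * ubz
    c1 = uax * rx + uay * ry + uaz * rz
    c2 = ubx * rx + uby * ry + ubz * rz
    denom = 1.0 - b * b
    if denom > _EPS_PAR:
        ta = (c1 - b * c2) / denom
    else:
        ta = 0.0
    if ta > hl:
        ta = hl
    elif ta < -hl:
        ta = -hl
    tb = b * ta - c2
    if tb > hl or tb < -hl:
        if tb > hl:
            tb = hl
        else:
            tb = -hl
        ta = b * tb + c1
        if ta > hl:
            ta = hl
        elif ta < -hl:
            ta = -hl
    dx = ta * uax - (rx + tb * ubx)
    dy = ta * uay - (ry + tb * uby)
    dz = ta * uaz - (rz + tb * ubz)
    return np.sqrt(dx * dx + dy * dy + dz * dz), ta, tb


@njit(cache=True)
def _gate(ang, hw, shoulder):
    """Angular patch gate: 1 inside the half-width, cos^2 shoulder, then 0."""
    if ang <= hw:
        return 1.0
    if ang >= hw + shoulder:
        return 0.0
    c = np.cos(0.5 * np.pi * (ang - hw) / shoulder)
    return c * c


@njit(cache=True)
def _patch_gate(nx, ny, nz, ux, uy, uz, px, py, pz, t, hl, chi, hw, shoulder):
    """Gate of one particle: angle between the contact normal (projected
    perpendicular to the axis) and the patch direction twisted by the
    chirality angle at axial position t."""
    # remove axial component of the contact normal
    dot_nu = nx * ux + ny * uy + nz * uz
    mx = nx - dot_nu * ux
    my = ny - dot_nu * uy
    mz = nz - dot_nu * uz
    mn = np.sqrt(mx * mx + my * my + mz * mz)
    if mn < 1e-12:
        return 0.0  # end-on contact: the side stripe is not involved
    mx /= mn
    my /= mn
    mz /= mn
    # patch direction twisted linearly along the axis
    if chi != 0.0:
        phi = chi * (t / hl)
        cph = np.cos(phi)
        sph = np.sin(phi)
        # u x p
        cxx = uy * pz - uz * py
        cxy = uz * px - ux * pz
        cxz = ux * py - uy * px
        pdx = px * cph + cxx * sph
        pdy = py * cph + cxy * sph
        pdz = pz * cph + cxz * sph
    else:
        pdx = px
        pdy = py
        pdz = pz
    ca = mx * pdx + my * pdy + mz * pdz
    if ca > 1.0:
        ca = 1.0
    elif ca < -1.0:
        ca = -1.0
    return _gate(np.arccos(ca), hw, shoulder)


@njit(cache=True)
def pair_energy_s(rx, ry, rz,
                  uax, uay, uaz, pax, pay, paz,
                  ubx, uby, ubz, pbx, pby, pbz,
                  sa, sb, pp, soft_core):
    """Pair energy of two patchy spherocylinders (kBT).

    ``(rx, ry, rz)`` is the center-to-center vector (minimum image already
    applied).  States: 0 = alpha, 1 = beta.  With ``soft_core`` nonzero an
    overlapping pair returns a finite positive penalty instead of +inf,
    which keeps local optimizers informed.
    """
    hl = pp[0]
    sigma = pp[1]
    rc = pp[2]
    d, ta, tb = seg_seg_closest(rx, ry, rz, uax, uay, uaz, ubx, uby, ubz, hl)
    if d < sigma:
        if soft_core != 0:
            return 200.0 * (sigma - d) / sigma
        return np.inf
    if d >= rc:
        return 0.0
    if sa == 0 and sb == 0:
        eps = pp[3]
    elif sa == 1 and sb == 1:
        eps = pp[5]
    else:
        eps = pp[4]
    # distance switch: 1 at contact, 0 at the cutoff, zero slope at both ends
    x = (d - sigma) / (rc - sigma)
    cs = np.cos(0.5 * np.pi * x)
    switch = cs * cs
    # contact normal from a's closest point to b's
    cax = ta * uax
    cay = ta * uay
    caz = ta * uaz
    cbx = rx + tb * ubx
    cby = ry + tb * uby
    cbz = rz + tb * ubz
    nx = (cbx - cax) / d
    ny = (cby - cay) / d
    nz = (cbz - caz) / d
    hw_a = pp[6] if sa == 0 else pp[7]
    hw_b = pp[6] if sb == 0 else pp[7]
    shoulder = pp[8]
    chi = pp[9]
    ga = _patch_gate(nx, ny, nz, uax, uay, uaz, pax, pay, paz,
                     ta, hl, chi, hw_a, shoulder)
    if ga == 0.0:
        return 0.0
    gb = _patch_gate(-nx, -ny, -nz, ubx, uby, ubz, pbx, pby, pbz,
                     tb, hl, chi, hw_b, shoulder)
    if gb == 0.0:
        return 0.0
    # axial overlap fraction of the two segments (mean of both projections)
    pb_c = uax * rx + uay * ry + uaz * rz
    babs = abs(uax * ubx + uay * uby + uaz * ubz)
    hb = hl * babs
    lo = max(-hl, pb_c - hb)
    hi = min(hl, pb_c + hb)
    ov_a = (hi - lo) / (2.0 * hl) if hi > lo else 0.0
    pa_c = -(ubx * rx + uby * ry + ubz * rz)
    lo = max(-hl, pa_c - hb)
    hi = min(hl, pa_c + hb)
    ov_b = (hi - lo) / (2.0 * hl) if hi > lo else 0.0
    w = 0.5 * (ov_a + ov_b)
    if w == 0.0:
        return 0.0
    return -eps * switch * ga * gb * w


@njit(cache=True)
def pair_energy_idx(i, j, pos, ax, pt, st, box, pp, soft_core):
    rx = pos[j, 0] - pos[i, 0]
    ry = pos[j, 1] - pos[i, 1]
    rz = pos[j, 2] - pos[i, 2]
    if box > 0.0:
        rx -= box * np.rint(rx / box)
        ry -= box * np.rint(ry / box)
        rz -= box * np.rint(rz / box)
    return pair_energy_s(rx, ry, rz,
                         ax[i, 0], ax[i, 1], ax[i, 2],
                         pt[i, 0], pt[i, 1], pt[i, 2],
                         ax[j, 0], ax[j, 1], ax[j, 2],
                         pt[j, 0], pt[j, 1], pt[j, 2],
                         st[i], st[j], pp, soft_core)


@njit(cache=True)
def total_energy_kernel(pos, ax, pt, st, box, pp, soft_core):
    """Sum of pair energies over unique pairs; +inf on first overlap
    (unless soft_core)."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            eij = pair_energy_idx(i, j, pos, ax, pt, st, box, pp, soft_core)
            if not np.isfinite(eij):
                return np.inf
            e += eij
    return e


@njit(cache=True)
def bond_edges_kernel(pos, ax, pt, st, box, pp, cut):
    """Edges (i, j) of the bond graph: pairs with pair energy below ``cut``."""
    n = pos.shape[0]
    # generous upper bound on edge count
    cap = 8 * n + 16
    edges = np.empty((cap, 2), dtype=np.int64)
    m = 0
    reach = 2.0 * pp[0] + pp[2]  # centers farther apart cannot interact
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[j, 0] - pos[i, 0]
            ry = pos[j, 1] - pos[i, 1]
            rz = pos[j, 2] - pos[i, 2]
            if box > 0.0:
                rx -= box * np.rint(rx / box)
                ry -= box * np.rint(ry / box)
                rz -= box * np.rint(rz / box)
            if rx * rx + ry * ry + rz * rz > reach * reach:
                continue
            eij = pair_energy_s(rx, ry, rz,
                                ax[i, 0], ax[i, 1], ax[i, 2],
                                pt[i, 0], pt[i, 1], pt[i, 2],
                                ax[j, 0], ax[j, 1], ax[j, 2],
                                pt[j, 0], pt[j, 1], pt[j, 2],
                                st[i], st[j], pp, 0)
            if eij < cut:
                if m >= cap:
                    cap = 2 * cap
                    new = np.empty((cap, 2), dtype=np.int64)
                    new[:m] = edges[:m]
                    edges = new
                edges[m, 0] = i
                edges[m, 1] = j
                m += 1
    return edges[:m]


# ---------------------------------------------------------------------------
# neighbour (Verlet) lists

@njit(cache=True)
def build_neighbours(pos, box, r_list, nbr, nbr_count):
    n = pos.shape[0]
    r2 = r_list * r_list
    for i in range(n):
        nbr_count[i] = 0
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[j, 0] - pos[i, 0]
            ry = pos[j, 1] - pos[i, 1]
            rz = pos[j, 2] - pos[i, 2]
            rx -= box * np.rint(rx / box)
            ry -= box * np.rint(ry / box)
            rz -= box * np.rint(rz / box)
            if rx * rx + ry * ry + rz * rz <= r2:
                nbr[i, nbr_count[i]] = j
                nbr_count[i] += 1
                nbr[j, nbr_count[j]] = i
                nbr_count[j] += 1


@njit(cache=True)
def local_energy(i, pos, ax, pt, st, box, pp, nbr, nbr_count):
    e = 0.0
    for k in range(nbr_count[i]):
        j = nbr[i, k]
        eij = pair_energy_idx(i, j, pos, ax, pt, st, box, pp, 0)
        if not np.isfinite(eij):
            return np.inf
        e += eij
    return e


# ---------------------------------------------------------------------------
# moves

@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG state (separate from numpy's)."""
    np.random.seed(seed)


@njit(cache=True)
def _rand_unit():
    while True:
        x = np.random.standard_normal()
        y = np.random.standard_normal()
        z = np.random.standard_normal()
        n2 = x * x + y * y + z * z
        if n2 > 1e-12:
            inv = 1.0 / np.sqrt(n2)
            return x * inv, y * inv, z * inv


@njit(cache=True)
def _rand_in_ball():
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        z = 2.0 * np.random.random() - 1.0
        if x * x + y * y + z * z <= 1.0:
            return x, y, z


@njit(cache=True)
def _rotate(vx, vy, vz, kx, ky, kz, ang):
    """Rodrigues rotation of v about unit axis k."""
    c = np.cos(ang)
    s = np.sin(ang)
    dot = kx * vx + ky * vy + kz * vz
    cx = ky * vz - kz * vy
    cy = kz * vx - kx * vz
    cz = kx * vy - ky * vx
    rx = vx * c + cx * s + kx * dot * (1.0 - c)
    ry = vy * c + cy * s + ky * dot * (1.0 - c)
    rz = vz * c + cz * s + kz * dot * (1.0 - c)
    return rx, ry, rz


@njit(cache=True)
def try_move(i, pos, ax, pt, st, box, pp, dmax, thmax, nbr, nbr_count):
    """One translation+rotation Metropolis attempt. Returns 1 if accepted."""
    e_old = local_energy(i, pos, ax, pt, st, box, pp, nbr, nbr_count)
    opx = pos[i, 0]
    opy = pos[i, 1]
    opz = pos[i, 2]
    oax = ax[i, 0]
    oay = ax[i, 1]
    oaz = ax[i, 2]
    opx2 = pt[i, 0]
    opy2 = pt[i, 1]
    opz2 = pt[i, 2]
    bx, by, bz = _rand_in_ball()
    pos[i, 0] = (opx + dmax * bx) % box
    pos[i, 1] = (opy + dmax * by) % box
    pos[i, 2] = (opz + dmax * bz) % box
    kx, ky, kz = _rand_unit()
    ang = thmax * np.random.random()
    nax, nay, naz = _rotate(oax, oay, oaz, kx, ky, kz, ang)
    npx, npy, npz = _rotate(opx2, opy2, opz2, kx, ky, kz, ang)
    # re-orthonormalize to prevent numerical drift
    an = 1.0 / np.sqrt(nax * nax + nay * nay + naz * naz)
    nax *= an
    nay *= an
    naz *= an
    dp = npx * nax + npy * nay + npz * naz
    npx -= dp * nax
    npy -= dp * nay
    npz -= dp * naz
    pn = 1.0 / np.sqrt(npx * npx + npy * npy + npz * npz)
    ax[i, 0] = nax
    ax[i, 1] = nay
    ax[i, 2] = naz
    pt[i, 0] = npx * pn
    pt[i, 1] = npy * pn
    pt[i, 2] = npz * pn
    e_new = local_energy(i, pos, ax, pt, st, box, pp, nbr, nbr_count)
    accept = False
    if np.isfinite(e_new):
        de = e_new - e_old
        if de <= 0.0 or np.random.random() < np.exp(-de):
            accept = True
    if not accept:
        pos[i, 0] = opx
        pos[i, 1] = opy
        pos[i, 2] = opz
        ax[i, 0] = oax
        ax[i, 1] = oay
        ax[i, 2] = oaz
        pt[i, 0] = opx2
        pt[i, 1] = opy2
        pt[i, 2] = opz2
        return 0
    return 1


@njit(cache=True)
def try_switch(i, pos, ax, pt, st, box, pp, dg_internal, nbr, nbr_count):
    """One internal-state flip attempt. Returns 1 if accepted."""
    e_old = local_energy(i, pos, ax, pt, st, box, pp, nbr, nbr_count)
    old = st[i]
    st[i] = 1 - old
    e_new = local_energy(i, pos, ax, pt, st, box, pp, nbr, nbr_count)
    # alpha(0) -> beta(1) pays the internal penalty, the reverse gains it
    dg = dg_internal if old == 0 else -dg_internal
    de = e_new - e_old + dg
    if np.isfinite(e_new) and (de <= 0.0 or np.random.random() < np.exp(-de)):
        return 1
    st[i] = old
    return 0


@njit(cache=True)
def _max_drift(pos, ax, pos0, ax0, box, hl):
    n = pos.shape[0]
    worst = 0.0
    for i in range(n):
        rx = pos[i, 0] - pos0[i, 0]
        ry = pos[i, 1] - pos0[i, 1]
        rz = pos[i, 2] - pos0[i, 2]
        rx -= box * np.rint(rx / box)
        ry -= box * np.rint(ry / box)
        rz -= box * np.rint(rz / box)
        dx = ax[i, 0] - ax0[i, 0]
        dy = ax[i, 1] - ax0[i, 1]
        dz = ax[i, 2] - ax0[i, 2]
        d = np.sqrt(rx * rx + ry * ry + rz * rz) + \
            hl * np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > worst:
            worst = d
    return worst


@njit(cache=True)
def run_sweeps(pos, ax, pt, st, box, pp, dg_internal,
               n_sweeps, dmax, thmax, p_switch, seed,
               record_every,
               fr_pos, fr_ax, fr_pt, fr_st, fr_sweep,
               skin):
    """Main DMC loop.  Frames land in the preallocated fr_* arrays
    (frame 0 is the initial configuration).  Returns
    (n_frames, accepted_moves, attempted_moves, accepted_switches,
    attempted_switches, n_rebuilds)."""
    np.random.seed(seed)
    n = pos.shape[0]
    hl = pp[0]
    r_list = 2.0 * hl + pp[2] + skin
    nbr = np.empty((n, n), dtype=np.int64)
    nbr_count = np.zeros(n, dtype=np.int64)
    build_neighbours(pos, box, r_list, nbr, nbr_count)
    pos0 = pos.copy()
    ax0 = ax.copy()
    n_rebuild = 0
    nf = 0
    fr_pos[nf] = pos
    fr_ax[nf] = ax
    fr_pt[nf] = pt
    fr_st[nf] = st
    fr_sweep[nf] = 0
    nf += 1
    acc_m = 0
    att_m = 0
    acc_s = 0
    att_s = 0
    for sweep in range(1, n_sweeps + 1):
        for _ in range(n):
            i = np.random.randint(0, n)
            if p_switch > 0.0 and np.random.random() < p_switch:
                att_s += 1
                acc_s += try_switch(i, pos, ax, pt, st, box, pp,
                                    dg_internal, nbr, nbr_count)
            else:
                att_m += 1
                acc_m += try_move(i, pos, ax, pt, st, box, pp,
                                  dmax, thmax, nbr, nbr_count)
        if _max_drift(pos, ax, pos0, ax0, box, hl) > 0.5 * skin:
            build_neighbours(pos, box, r_list, nbr, nbr_count)
            pos0[:] = pos
            ax0[:] = ax
            n_rebuild += 1
        if sweep % record_every == 0:
            fr_pos[nf] = pos
            fr_ax[nf] = ax
            fr_pt[nf] = pt
            fr_st[nf] = st
            fr_sweep[nf] = sweep
            nf += 1
    return nf, acc_m, att_m, acc_s, att_s, n_rebuild


@njit(cache=True)
def random_insertion(n, box, hl, sigma, seed, max_attempts):
    """Random sequential insertion of non-overlapping spherocylinders.

    Returns (pos, axis, patch, ok_flag)."""
    np.random.seed(seed)
    pos = np.empty((n, 3))
    axv = np.empty((n, 3))
    ptv = np.empty((n, 3))
    attempts = 0
    for i in range(n):
        placed = False
        while attempts < max_attempts:
            attempts += 1
            px = box * np.random.random()
            py = box * np.random.random()
            pz = box * np.random.random()
            ux, uy, uz = _rand_unit()
            vx, vy, vz = _rand_unit()
            dp = vx * ux + vy * uy + vz * uz
            wx = vx - dp * ux
            wy = vy - dp * uy
            wz = vz - dp * uz
            wn = np.sqrt(wx * wx + wy * wy + wz * wz)
            if wn < 1e-9:
                continue
            wx /= wn
            wy /= wn
            wz /= wn
            ok = True
            for j in range(i):
                rx = pos[j, 0] - px
                ry = pos[j, 1] - py
                rz = pos[j, 2] - pz
                rx -= box * np.rint(rx / box)
                ry -= box * np.rint(ry / box)
                rz -= box * np.rint(rz / box)
                d, _, _ = seg_seg_closest(rx, ry, rz, ux, uy, uz,
                                          axv[j, 0], axv[j, 1], axv[j, 2], hl)
                if d < sigma:
                    ok = False
                    break
            if ok:
                pos[i, 0] = px
                pos[i, 1] = py
                pos[i, 2] = pz
                axv[i, 0] = ux
                axv[i, 1] = uy
                axv[i, 2] = uz
                ptv[i, 0] = wx
                ptv[i, 1] = wy
                ptv[i, 2] = wz
                placed = True
                break
        if not placed:
            return pos, axv, ptv, 0
    return pos, axv, ptv, 1


@njit(cache=True)
def min_pair_distance(pos, ax, box, hl):
    """Smallest axis-axis distance over all pairs (hard-core audit)."""
    n = pos.shape[0]
    best = 1e30
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[j, 0] - pos[i, 0]
            ry = pos[j, 1] - pos[i, 1]
            rz = pos[j, 2] - pos[i, 2]
            rx -= box * np.rint(rx / box)
            ry -= box * np.rint(ry / box)
            rz -= box * np.rint(rz / box)
            d, _, _ = seg_seg_closest(rx, ry, rz,
                                      ax[i, 0], ax[i, 1], ax[i, 2],
                                      ax[j, 0], ax[j, 1], ax[j, 2], hl)
            if d < best:
                best = d
    return best
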