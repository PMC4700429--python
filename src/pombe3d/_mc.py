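"""Numba kernels for conformation initialization and Metropolis Monte Carlo.

The move set is single-granule displacement plus crankshaft rotation of a
short chain segment about the axis through its two flanking granules
(crankshaft moves preserve every bond length in the rotated stretch).  Hard
constraints — nuclear confinement, nucleolar exclusion, the bond-length
window and the excluded-volume floor — are enforced by rejecting violating
moves throughout the anneal, starting from a feasible initial conformation,
so every returned structure satisfies them by construction; in that regime
excluded volume acts as a hard core and carries no soft energy.  With hard
constraints disabled (free-diffusion mode) a soft-core quadratic overlap
penalty is used instead.

All kernels use numpy's legacy global RNG *inside numba* (per-kernel
``np.random.seed``), which is deterministic for a fixed seed.
"""

import numpy as np
from numba import njit

# anchor region codes (must match genome.ANCHOR_REGIONS)
_SPB_ZONE = 0
_PERIPHERY = 1
_NUCL_SURFACE = 2


@njit(cache=True, inline="always")
def _pos(coords, prop, m0, m1, use_prop, i):
    if use_prop and m0 <= i <= m1:
        return prop[i, 0], prop[i, 1], prop[i, 2]
    return coords[i, 0], coords[i, 1], coords[i, 2]


@njit(cache=True)
def _soft_energy(
    coords, prop, m0, m1, use_prop,
    bondprev, anch_type, anch_k, c_off, c_nbr,
    R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol,
    k_bond, b0, kappa, k_ev, k_conf, k_contact, c_rest,
    include_ev,
):
    """Soft-term energy touched by moving the contiguous range [m0, m1].

    Moves are either single-bead displacements or rigid rotations of the
    range, so all pairwise geometry internal to the range is preserved; only
    terms crossing the range boundary and per-bead terms contribute to the
    energy difference and are evaluated here.
    """
    n = coords.shape[0]
    e = 0.0

    # boundary bonds: (m0-1, m0) and (m1, m1+1)
    for i in (m0, m1 + 1):
        if i <= 0 or i >= n or not bondprev[i]:
            continue
        x1, y1, z1 = _pos(coords, prop, m0, m1, use_prop, i - 1)
        x2, y2, z2 = _pos(coords, prop, m0, m1, use_prop, i)
        d = np.sqrt((x2 - x1) ** 2 + (y2 - y1) ** 2 + (z2 - z1) ** 2)
        e += 0.5 * k_bond * (d - b0) ** 2

    # bending at boundary vertices (interior angles are rigid-preserved)
    for v in range(m0 - 1, m1 + 2):
        if m0 < v < m1:
            continue
        if v <= 0 or v >= n - 1 or not (bondprev[v] and bondprev[v + 1]):
            continue
        ax, ay, az = _pos(coords, prop, m0, m1, use_prop, v - 1)
        bx, by, bz = _pos(coords, prop, m0, m1, use_prop, v)
        cx, cy, cz = _pos(coords, prop, m0, m1, use_prop, v + 1)
        ux, uy, uz = bx - ax, by - ay, bz - az
        wx, wy, wz = cx - bx, cy - by, cz - bz
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if nu > 1e-12 and nw > 1e-12:
            cosang = (ux * wx + uy * wy + uz * wz) / (nu * nw)
            e += kappa * (1.0 - cosang)

    # per-bead environment + anchors
    for b in range(m0, m1 + 1):
        x, y, z = _pos(coords, prop, m0, m1, use_prop, b)
        d = np.sqrt(x * x + y * y + z * z)
        lim = R - grad
        if d > lim:
            e += 0.5 * k_conf * (d - lim) ** 2
        dn = np.sqrt(x * x + y * y + (z - ncz) ** 2)
        nlim = nrad + grad
        if nrad > 0.0 and dn < nlim:
            e += 0.5 * k_conf * (nlim - dn) ** 2
        t = anch_type[b]
        if t == _SPB_ZONE:
            dd = np.sqrt(x * x + y * y + (z - R) ** 2)
            if dd > zone_r:
                e += 0.5 * anch_k[b] * (dd - zone_r) ** 2
        elif t == _PERIPHERY:
            if d < shell_lo:
                e += 0.5 * anch_k[b] * (shell_lo - d) ** 2
        elif t == _NUCL_SURFACE:
            dev = abs(dn - nlim)
            if dev > nsurf_tol:
                e += 0.5 * anch_k[b] * (dev - nsurf_tol) ** 2

    # contact springs (flat-bottomed) crossing the moved-range boundary
    for b in range(m0, m1 + 1):
        xb, yb, zb = _pos(coords, prop, m0, m1, use_prop, b)
        for p in range(c_off[b], c_off[b + 1]):
            v = c_nbr[p]
            if m0 <= v <= m1:
                continue
            xv, yv, zv = coords[v, 0], coords[v, 1], coords[v, 2]
            d = np.sqrt((xv - xb) ** 2 + (yv - yb) ** 2 + (zv - zb) ** 2)
            if d > c_rest:
                e += 0.5 * k_contact * (d - c_rest) ** 2

    # soft-core excluded volume (free-diffusion mode only): moved vs unmoved
    if include_ev:
        dmin = 2.0 * grad
        for b in range(m0, m1 + 1):
            xb, yb, zb = _pos(coords, prop, m0, m1, use_prop, b)
            for w in range(n):
                if m0 <= w <= m1:
                    continue
                if (w == b - 1 and bondprev[b]) or (w == b + 1 and bondprev[w]):
                    continue
                d = np.sqrt(
                    (coords[w, 0] - xb) ** 2
                    + (coords[w, 1] - yb) ** 2
                    + (coords[w, 2] - zb) ** 2
                )
                if d < dmin:
                    e += 0.5 * k_ev * (dmin - d) ** 2
    return e


@njit(cache=True)
def _segment_feasible(
    coords, prop, m0, m1, bondprev,
    R, grad, ncz, nrad, b0, ev_tol,
):
    """Hard-constraint check of a proposal (squared distances, single pass)."""
    n = coords.shape[0]
    lim2 = (R - grad + 1e-9) ** 2
    nlim2 = max(nrad + grad - 1e-9, 0.0) ** 2
    blo2, bhi2 = (0.8 * b0 - 1e-9) ** 2, (1.2 * b0 + 1e-9) ** 2
    dmin2 = (2.0 * grad * (1.0 - ev_tol)) ** 2
    for b in range(m0, m1 + 1):
        x, y, z = prop[b, 0], prop[b, 1], prop[b, 2]
        if x * x + y * y + z * z > lim2:
            return False
        if nrad > 0.0:
            dz = z - ncz
            if x * x + y * y + dz * dz < nlim2:
                return False
    # boundary bonds only; bonds internal to the range are rigid-preserved
    for i in (m0, m1 + 1):
        if i <= 0 or i >= n or not bondprev[i]:
            continue
        x1, y1, z1 = _pos(coords, prop, m0, m1, True, i - 1)
        x2, y2, z2 = _pos(coords, prop, m0, m1, True, i)
        d2 = (x2 - x1) ** 2 + (y2 - y1) ** 2 + (z2 - z1) ** 2
        if d2 < blo2 or d2 > bhi2:
            return False
    # excluded-volume floor: moved beads against unmoved beads
    for b in range(m0, m1 + 1):
        xb, yb, zb = prop[b, 0], prop[b, 1], prop[b, 2]
        for w in range(n):
            if m0 <= w <= m1:
                continue
            if (w == b - 1 and bondprev[b]) or (w == b + 1 and bondprev[w]):
                continue
            d2 = (
                (coords[w, 0] - xb) ** 2
                + (coords[w, 1] - yb) ** 2
                + (coords[w, 2] - zb) ** 2
            )
            if d2 < dmin2:
                return False
    return True


@njit(cache=True)
def run_mc(
    coords, bondprev, anch_type, anch_k, c_off, c_nbr,
    R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol,
    k_bond, b0, kappa, k_ev, k_conf, k_contact, c_rest,
    temps, sweeps_per_temp, step, crank_prob, crank_max, crank_amp,
    pivot_prob, pivot_amp,
    enforce_hard, ev_tol, seed,
):
    """Metropolis anneal in place; returns (accepted, attempted)."""
    n = coords.shape[0]
    np.random.seed(seed)
    prop = np.empty((n, 3))
    accepted = 0
    attempted = 0
    include_ev = not enforce_hard
    for it in range(temps.shape[0]):
        T = temps[it]
        for _s in range(sweeps_per_temp):
            for _mv in range(n):
                u_move = np.random.random()
                if u_move < pivot_prob and n >= 2:
                    # pivot: rotate the chain tail a+1..end about a random axis
                    # through bead a (large-scale relaxation move)
                    a = np.random.randint(0, n)
                    ce = a + 1
                    while ce < n and bondprev[ce]:
                        ce += 1
                    if ce - (a + 1) < 1:
                        continue
                    zz = 2.0 * np.random.random() - 1.0
                    ph = 2.0 * np.pi * np.random.random()
                    sq = np.sqrt(max(0.0, 1.0 - zz * zz))
                    kx = sq * np.cos(ph)
                    ky = sq * np.sin(ph)
                    kz = zz
                    theta = (2.0 * np.random.random() - 1.0) * pivot_amp
                    ct = np.cos(theta)
                    st = np.sin(theta)
                    for q in range(a + 1, ce):
                        vx = coords[q, 0] - coords[a, 0]
                        vy = coords[q, 1] - coords[a, 1]
                        vz = coords[q, 2] - coords[a, 2]
                        dot = kx * vx + ky * vy + kz * vz
                        cxx = ky * vz - kz * vy
                        cyy = kz * vx - kx * vz
                        czz = kx * vy - ky * vx
                        prop[q, 0] = coords[a, 0] + vx * ct + cxx * st + kx * dot * (1.0 - ct)
                        prop[q, 1] = coords[a, 1] + vy * ct + cyy * st + ky * dot * (1.0 - ct)
                        prop[q, 2] = coords[a, 2] + vz * ct + czz * st + kz * dot * (1.0 - ct)
                    m0, m1 = a + 1, ce - 1
                elif u_move < pivot_prob + crank_prob and n >= 3:
                    # crankshaft: rotate beads a+1..j-1 about axis coords[a]->coords[j]
                    a = np.random.randint(0, n - 2)
                    span = 2 + np.random.randint(0, crank_max)
                    j = a + span
                    if j >= n:
                        j = n - 1
                    if j < a + 2:
                        continue
                    ok = True
                    for q in range(a + 1, j + 1):
                        if not bondprev[q]:
                            ok = False
                            break
                    if not ok:
                        continue
                    kx = coords[j, 0] - coords[a, 0]
                    ky = coords[j, 1] - coords[a, 1]
                    kz = coords[j, 2] - coords[a, 2]
                    nk = np.sqrt(kx * kx + ky * ky + kz * kz)
                    if nk < 1e-12:
                        continue
                    kx /= nk
                    ky /= nk
                    kz /= nk
                    theta = (2.0 * np.random.random() - 1.0) * crank_amp
                    ct = np.cos(theta)
                    st = np.sin(theta)
                    for q in range(a + 1, j):
                        vx = coords[q, 0] - coords[a, 0]
                        vy = coords[q, 1] - coords[a, 1]
                        vz = coords[q, 2] - coords[a, 2]
                        dot = kx * vx + ky * vy + kz * vz
                        cxx = ky * vz - kz * vy
                        cyy = kz * vx - kx * vz
                        czz = kx * vy - ky * vx
                        prop[q, 0] = coords[a, 0] + vx * ct + cxx * st + kx * dot * (1.0 - ct)
                        prop[q, 1] = coords[a, 1] + vy * ct + cyy * st + ky * dot * (1.0 - ct)
                        prop[q, 2] = coords[a, 2] + vz * ct + czz * st + kz * dot * (1.0 - ct)
                    m0, m1 = a + 1, j - 1
                else:
                    i = np.random.randint(0, n)
                    prop[i, 0] = coords[i, 0] + step * np.random.normal(0.0, 1.0)
                    prop[i, 1] = coords[i, 1] + step * np.random.normal(0.0, 1.0)
                    prop[i, 2] = coords[i, 2] + step * np.random.normal(0.0, 1.0)
                    m0 = m1 = i
                attempted += 1
                if enforce_hard and not _segment_feasible(
                    coords, prop, m0, m1, bondprev, R, grad, ncz, nrad, b0, ev_tol
                ):
                    continue
                e_old = _soft_energy(
                    coords, prop, m0, m1, False,
                    bondprev, anch_type, anch_k, c_off, c_nbr,
                    R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol,
                    k_bond, b0, kappa, k_ev, k_conf, k_contact, c_rest,
                    include_ev,
                )
                e_new = _soft_energy(
                    coords, prop, m0, m1, True,
                    bondprev, anch_type, anch_k, c_off, c_nbr,
                    R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol,
                    k_bond, b0, kappa, k_ev, k_conf, k_contact, c_rest,
                    include_ev,
                )
                dE = e_new - e_old
                if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                    for q in range(m0, m1 + 1):
                        coords[q, 0] = prop[q, 0]
                        coords[q, 1] = prop[q, 1]
                        coords[q, 2] = prop[q, 2]
                    accepted += 1
    return accepted, attempted


@njit(cache=True)
def _in_region(x, y, z, t, R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol):
    if t == _SPB_ZONE:
        return np.sqrt(x * x + y * y + (z - R) ** 2) <= zone_r
    if t == _PERIPHERY:
        return np.sqrt(x * x + y * y + z * z) >= shell_lo
    if t == _NUCL_SURFACE:
        return abs(np.sqrt(x * x + y * y + (z - ncz) ** 2) - (nrad + grad)) <= nsurf_tol
    return True


@njit(cache=True)
def _bead_feasible(coords, n_placed, x, y, z, R, grad, ncz, nrad, skip_bonded):
    """Inside nucleus, outside nucleolus, no overlap with beads [0, n_placed)."""
    if np.sqrt(x * x + y * y + z * z) > R - grad:
        return False
    if nrad > 0.0 and np.sqrt(x * x + y * y + (z - ncz) ** 2) < nrad + grad:
        return False
    dmin2 = (2.0 * grad) ** 2
    last = n_placed - 1 if skip_bonded else n_placed
    for w in range(last):
        d2 = (coords[w, 0] - x) ** 2 + (coords[w, 1] - y) ** 2 + (coords[w, 2] - z) ** 2
        if d2 < dmin2:
            return False
    return True


@njit(cache=True)
def grow_conformation(
    n, chain_start, anch_type, next_anchor,
    R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol,
    b0, persist, chain_retries, seed,
):
    """Self-avoiding persistent (worm-like) walk with anchor steering.

    Chains grow bead by bead at fixed bond length ``b0``; each new bead must
    lie inside the nucleus, outside the nucleolus, and at least one diameter
    from every previously placed bead.  Step directions are correlated with
    the previous step (weight ``persist``), giving an expanded worm-like
    starting coil at the model's persistence length.  When an anchored bead
    lies ahead on the chain, directions additionally blend toward its target
    region as the remaining contour length approaches the distance still to
    cover, so anchored beads start inside their regions.

    Returns (coords, status); status 0 = ok, 1 = placement failed.
    """
    np.random.seed(seed)
    coords = np.empty((n, 3))
    i = 0
    while i < n:
        # find chain extent [i, ce)
        ce = i + 1
        while ce < n and not chain_start[ce]:
            ce += 1
        placed = False
        for _retry in range(chain_retries):
            ok = True
            k = i
            pdx = 0.0
            pdy = 0.0
            pdz = 0.0
            has_prev = False
            while k < ce:
                success = False
                if k == i:
                    for _t in range(4000):
                        # uniform point in the feasible ball
                        u = np.random.random()
                        rr = (R - grad) * u ** (1.0 / 3.0)
                        zz = 2.0 * np.random.random() - 1.0
                        ph = 2.0 * np.pi * np.random.random()
                        sq = np.sqrt(max(0.0, 1.0 - zz * zz))
                        x = rr * sq * np.cos(ph)
                        y = rr * sq * np.sin(ph)
                        z = rr * zz
                        if anch_type[k] >= 0 and not _in_region(
                            x, y, z, anch_type[k], R, grad, ncz, nrad,
                            zone_r, shell_lo, nsurf_tol,
                        ):
                            continue
                        if _bead_feasible(coords, k, x, y, z, R, grad, ncz, nrad, False):
                            coords[k, 0], coords[k, 1], coords[k, 2] = x, y, z
                            success = True
                            break
                else:
                    px, py, pz = coords[k - 1, 0], coords[k - 1, 1], coords[k - 1, 2]
                    na = next_anchor[k]
                    for _t in range(80):
                        zz = 2.0 * np.random.random() - 1.0
                        ph = 2.0 * np.pi * np.random.random()
                        sq = np.sqrt(max(0.0, 1.0 - zz * zz))
                        dx = sq * np.cos(ph)
                        dy = sq * np.sin(ph)
                        dz = zz
                        # persistence is dropped after many failed tries so the
                        # walk can turn away from the envelope/nucleolus
                        if has_prev and persist > 0.0 and _t < 40:
                            dx = persist * pdx + (1.0 - persist) * dx
                            dy = persist * pdy + (1.0 - persist) * dy
                            dz = persist * pdz + (1.0 - persist) * dz
                            dn0 = np.sqrt(dx * dx + dy * dy + dz * dz)
                            if dn0 < 1e-9:
                                continue
                            dx /= dn0
                            dy /= dn0
                            dz /= dn0
                        if na >= 0:
                            # steer toward the anchor's region when slack runs out
                            t = anch_type[na]
                            remaining = (na - (k - 1)) * b0
                            if t == _SPB_ZONE:
                                tx, ty, tz = -px, -py, R - pz
                                dist = max(0.0, np.sqrt(tx * tx + ty * ty + tz * tz) - zone_r)
                            elif t == _PERIPHERY:
                                dc = np.sqrt(px * px + py * py + pz * pz)
                                tx, ty, tz = px, py, pz
                                dist = max(0.0, shell_lo - dc)
                            else:
                                tx, ty, tz = -px, -py, ncz - pz
                                dn = np.sqrt(tx * tx + ty * ty + tz * tz)
                                dist = max(0.0, dn - (nrad + grad + nsurf_tol))
                            tn = np.sqrt(tx * tx + ty * ty + tz * tz)
                            if tn > 1e-9 and remaining > 0:
                                blend = (dist - 0.6 * remaining) / (0.4 * remaining)
                                if blend > 1.0:
                                    blend = 1.0
                                if blend > 0.0:
                                    dx = (1.0 - blend) * dx + blend * tx / tn
                                    dy = (1.0 - blend) * dy + blend * ty / tn
                                    dz = (1.0 - blend) * dz + blend * tz / tn
                                    dn2 = np.sqrt(dx * dx + dy * dy + dz * dz)
                                    if dn2 < 1e-9:
                                        continue
                                    dx /= dn2
                                    dy /= dn2
                                    dz /= dn2
                        x = px + b0 * dx
                        y = py + b0 * dy
                        z = pz + b0 * dz
                        if anch_type[k] >= 0 and not _in_region(
                            x, y, z, anch_type[k], R, grad, ncz, nrad,
                            zone_r, shell_lo, nsurf_tol,
                        ):
                            continue
                        if _bead_feasible(coords, k, x, y, z, R, grad, ncz, nrad, True):
                            coords[k, 0], coords[k, 1], coords[k, 2] = x, y, z
                            pdx, pdy, pdz = dx, dy, dz
                            has_prev = True
                            success = True
                            break
                if not success:
                    ok = False
                    break
                k += 1
            if ok:
                placed = True
                break
        if not placed:
            return coords, 1
        i = ce
    return coords, 0
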