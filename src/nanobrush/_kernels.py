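"""Numba-compiled kernels: neighbor lists, forces, and the Langevin driver.

Everything here operates on plain numpy arrays; the object-level API lives in
:mod:`nanobrush.engine`.  Species codes: 0 = monomer, 1 = nanoparticle.

The integrator is BAOAB Langevin splitting:

    B  v += dt/2 * F/m
    A  x += dt/2 * v
    O  v  = c1*v + c2*sqrt(kT/m)*xi,   c1 = exp(-gamma*dt), c2 = sqrt(1-c1^2)
    A  x += dt/2 * v
    B  v += dt/2 * F(x)/m

With gamma = 0 the O step is the identity and the scheme reduces exactly to
velocity Verlet (NVE).  Frozen particles (graft beads) are skipped by every
sub-step and by the thermostat.
"""

import numpy as np
from numba import njit

RC_WCA = 2.0 ** (1.0 / 6.0)

# status codes returned by the driver
OK = 0
BOND_OVERSTRETCH = 1
CORE_BREACH = 2
NON_FINITE = 3


@njit(cache=True, inline="always")
def _min_image(d, L, per):
    if per:
        d -= L * np.rint(d / L)
    return d


@njit(cache=True, inline="always")
def _list_cut2(si, sj, c2_mm, c2_nn, c2_nm):
    """Species-resolved squared list cutoff (interaction cutoff + skin)."""
    if si == sj:
        return c2_mm if si == 0 else c2_nn
    return c2_nm


@njit(cache=True, fastmath=True)
def count_pairs_brute(pos, species, box, perx, pery, perz,
                      c2_mm, c2_nn, c2_nm):
    n = pos.shape[0]
    m = 0
    for i in range(n - 1):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        si = species[i]
        for j in range(i + 1, n):
            dx = _min_image(xi - pos[j, 0], box[0], perx)
            dy = _min_image(yi - pos[j, 1], box[1], pery)
            dz = _min_image(zi - pos[j, 2], box[2], perz)
            if dx * dx + dy * dy + dz * dz < _list_cut2(si, species[j],
                                                       c2_mm, c2_nn, c2_nm):
                m += 1
    return m


@njit(cache=True, fastmath=True)
def build_pairs_brute(pos, species, box, perx, pery, perz,
                      c2_mm, c2_nn, c2_nm):
    n = pos.shape[0]
    m = count_pairs_brute(pos, species, box, perx, pery, perz,
                          c2_mm, c2_nn, c2_nm)
    pairs = np.empty((m, 2), dtype=np.int32)
    k = 0
    for i in range(n - 1):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        si = species[i]
        for j in range(i + 1, n):
            dx = _min_image(xi - pos[j, 0], box[0], perx)
            dy = _min_image(yi - pos[j, 1], box[1], pery)
            dz = _min_image(zi - pos[j, 2], box[2], perz)
            if dx * dx + dy * dy + dz * dz < _list_cut2(si, species[j],
                                                       c2_mm, c2_nn, c2_nm):
                pairs[k, 0] = i
                pairs[k, 1] = j
                k += 1
    return pairs


@njit(cache=True, fastmath=True)
def build_pairs_cells(pos, species, box, perx, pery, perz, cutoff,
                      c2_mm, c2_nn, c2_nm):
    """Cell-binned Verlet list build.

    Caller must guarantee >= 3 cells along every periodic dimension so each
    pair is generated through at most one periodic image.
    """
    n = pos.shape[0]
    nc = np.empty(3, dtype=np.int64)
    for d in range(3):
        nc[d] = max(1, int(box[d] / cutoff))
    ncx, ncy, ncz = nc[0], nc[1], nc[2]
    ncell = ncx * ncy * ncz

    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * ncx)
        iy = int(pos[i, 1] / box[1] * ncy)
        iz = int(pos[i, 2] / box[2] * ncz)
        ix = min(max(ix, 0), ncx - 1)
        iy = min(max(iy, 0), ncy - 1)
        iz = min(max(iz, 0), ncz - 1)
        c = (ix * ncy + iy) * ncz + iz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    cap = max(64, n * 64)
    pairs = np.empty((cap, 2), dtype=np.int32)
    m = 0
    for i in range(n):
        ci = cell_of[i]
        iz0 = ci % ncz
        iy0 = (ci // ncz) % ncy
        ix0 = ci // (ncy * ncz)
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        si = species[i]
        for ox in range(-1, 2):
            ix = ix0 + ox
            if perx:
                ix = (ix + ncx) % ncx
            elif ix < 0 or ix >= ncx:
                continue
            for oy in range(-1, 2):
                iy = iy0 + oy
                if pery:
                    iy = (iy + ncy) % ncy
                elif iy < 0 or iy >= ncy:
                    continue
                for oz in range(-1, 2):
                    iz = iz0 + oz
                    if perz:
                        iz = (iz + ncz) % ncz
                    elif iz < 0 or iz >= ncz:
                        continue
                    c = (ix * ncy + iy) * ncz + iz
                    for k in range(counts[c], counts[c + 1]):
                        j = order[k]
                        if j <= i:
                            continue
                        dx = _min_image(xi - pos[j, 0], box[0], perx)
                        dy = _min_image(yi - pos[j, 1], box[1], pery)
                        dz = _min_image(zi - pos[j, 2], box[2], perz)
                        if dx * dx + dy * dy + dz * dz < _list_cut2(
                                si, species[j], c2_mm, c2_nn, c2_nm):
                            if m >= cap:
                                cap *= 2
                                grown = np.empty((cap, 2), dtype=np.int32)
                                grown[:m] = pairs[:m]
                                pairs = grown
                            pairs[m, 0] = i
                            pairs[m, 1] = j
                            m += 1
    return pairs[:m].copy()


@njit(cache=True)
def build_pairs(pos, species, box, perx, pery, perz, cutoff,
                c2_mm, c2_nn, c2_nm, use_cells):
    """Verlet list build; ``cutoff`` is the largest list range (cell size)."""
    if use_cells:
        return build_pairs_cells(pos, species, box, perx, pery, perz, cutoff,
                                 c2_mm, c2_nn, c2_nm)
    return build_pairs_brute(pos, species, box, perx, pery, perz,
                             c2_mm, c2_nn, c2_nm)


@njit(cache=True)
def partition_pairs(pairs, species):
    """Split a mixed pair list into (mm, nn, nm) type-pure lists."""
    m = pairs.shape[0]
    n_mm = n_nn = n_nm = 0
    for k in range(m):
        si = species[pairs[k, 0]]
        sj = species[pairs[k, 1]]
        if si == sj:
            if si == 0:
                n_mm += 1
            else:
                n_nn += 1
        else:
            n_nm += 1
    mm = np.empty((n_mm, 2), dtype=np.int32)
    nn = np.empty((n_nn, 2), dtype=np.int32)
    nm = np.empty((n_nm, 2), dtype=np.int32)
    a = b = c = 0
    for k in range(m):
        si = species[pairs[k, 0]]
        sj = species[pairs[k, 1]]
        if si == sj:
            if si == 0:
                mm[a, 0] = pairs[k, 0]
                mm[a, 1] = pairs[k, 1]
                a += 1
            else:
                nn[b, 0] = pairs[k, 0]
                nn[b, 1] = pairs[k, 1]
                b += 1
        else:
            nm[c, 0] = pairs[k, 0]
            nm[c, 1] = pairs[k, 1]
            c += 1
    return mm, nn, nm


@njit(cache=True, fastmath=True)
def wca_pair_forces(pos, pairs, box, perx, pery, perz, sig, eps, rc2, f):
    """Purely repulsive WCA forces over a type-pure pair list."""
    e = 0.0
    sig2 = sig * sig
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0], perx)
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1], pery)
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2], perz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            r2inv = 1.0 / r2
            s2 = sig2 * r2inv
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            e += 4.0 * eps * (s12 - s6) + eps
            fr = 24.0 * eps * (2.0 * s12 - s6) * r2inv
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz
    return e


@njit(cache=True, fastmath=True)
def nm_pair_forces(pos, pairs, box, perx, pery, perz,
                   sig_m, eps_b, delta, rc2_nm, shift_e, f):
    """Attractive monomer-nanoparticle forces over a type-pure pair list."""
    e = 0.0
    status = OK
    core = 0.05 * sig_m
    sig2 = sig_m * sig_m
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0], perx)
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1], pery)
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2], perz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2_nm:
            if delta == 0.0:
                if r2 <= core * core:
                    status = CORE_BREACH
                    r2 = core * core
                r2inv = 1.0 / r2
                x2 = sig2 * r2inv
                x6 = x2 * x2 * x2
                x12 = x6 * x6
                e += 4.0 * eps_b * (x12 - x6) - shift_e
                fr = 4.0 * eps_b * (12.0 * x12 - 6.0 * x6) * r2inv
            else:
                r = np.sqrt(r2)
                rr = r - delta
                if rr <= core:
                    status = CORE_BREACH
                    rr = core
                x2 = sig2 / (rr * rr)
                x6 = x2 * x2 * x2
                x12 = x6 * x6
                e += 4.0 * eps_b * (x12 - x6) - shift_e
                fr = 4.0 * eps_b * (12.0 * x12 - 6.0 * x6) / (rr * r)
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz
    return e, status


@njit(cache=True, fastmath=True)
def pair_forces(pos, species, pairs, box, perx, pery, perz,
                sig_m, sig_n, eps, eps_b, delta,
                rc2_mm, rc2_nn, rc2_nm, shift_e, f):
    """Non-bonded forces from a pair list.  Returns (energy, status)."""
    e = 0.0
    status = OK
    core = 0.05 * sig_m
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0], perx)
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1], pery)
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2], perz)
        r2 = dx * dx + dy * dy + dz * dz
        si = species[i]
        sj = species[j]
        if si == sj:
            if si == 0:
                rc2 = rc2_mm
                sig = sig_m
            else:
                rc2 = rc2_nn
                sig = sig_n
            if r2 < rc2:
                r2inv = 1.0 / r2
                s2 = sig * sig * r2inv
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                e += 4.0 * eps * (s12 - s6) + eps
                fr = 24.0 * eps * (2.0 * s12 - s6) * r2inv
                f[i, 0] += fr * dx
                f[i, 1] += fr * dy
                f[i, 2] += fr * dz
                f[j, 0] -= fr * dx
                f[j, 1] -= fr * dy
                f[j, 2] -= fr * dz
        else:
            if r2 < rc2_nm:
                if delta == 0.0:
                    # equal-size pair: plain LJ in r, no sqrt needed
                    if r2 <= core * core:
                        status = CORE_BREACH
                        r2 = core * core
                    r2inv = 1.0 / r2
                    x2 = sig_m * sig_m * r2inv
                    x6 = x2 * x2 * x2
                    x12 = x6 * x6
                    e += 4.0 * eps_b * (x12 - x6) - shift_e
                    fr = 4.0 * eps_b * (12.0 * x12 - 6.0 * x6) * r2inv
                else:
                    r = np.sqrt(r2)
                    rr = r - delta
                    if rr <= core:
                        status = CORE_BREACH
                        rr = core
                    x2 = sig_m * sig_m / (rr * rr)
                    x6 = x2 * x2 * x2
                    x12 = x6 * x6
                    e += 4.0 * eps_b * (x12 - x6) - shift_e
                    # fr = -(dU/dr)/r
                    fr = 4.0 * eps_b * (12.0 * x12 - 6.0 * x6) / (rr * r)
                f[i, 0] += fr * dx
                f[i, 1] += fr * dy
                f[i, 2] += fr * dz
                f[j, 0] -= fr * dx
                f[j, 1] -= fr * dy
                f[j, 2] -= fr * dz
    return e, status


@njit(cache=True, fastmath=True)
def bond_forces(pos, bonds, box, perx, pery, perz, fene_k, fene_r0, f):
    """FENE bond forces.  Returns (energy, max_bond_length)."""
    e = 0.0
    maxb = 0.0
    r02 = fene_r0 * fene_r0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0], perx)
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1], pery)
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2], perz)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r > maxb:
            maxb = r
        if r >= fene_r0:
            return e, maxb
        w = 1.0 - r2 / r02
        e += -0.5 * fene_k * r02 * np.log(w)
        fr = -fene_k / w  # = -(dU/dr)/r
        f[i, 0] += fr * dx
        f[i, 1] += fr * dy
        f[i, 2] += fr * dz
        f[j, 0] -= fr * dx
        f[j, 1] -= fr * dy
        f[j, 2] -= fr * dz
    return e, maxb


@njit(cache=True, fastmath=True)
def wall_forces(pos, species, frozen, geom_code, Lz, R, cy, cz,
                wall_eps, sig_m, sig_n, f):
    """Confining-wall forces.  Returns (energy, status).

    geom_code 0: planar slab, WCA on distance to the z=0 and z=Lz walls for
    both species (length scale sigma of the species).
    geom_code 1: cylinder, WCA on (R - distance from axis) for monomers only;
    nanoparticles pass freely (permeable wall).
    """
    e = 0.0
    status = OK
    n = pos.shape[0]
    for i in range(n):
        if frozen[i]:
            continue
        if geom_code == 0:
            sig = sig_m if species[i] == 0 else sig_n
            rc = RC_WCA * sig
            z = pos[i, 2]
            # bottom wall
            d = z
            if d < rc:
                if d <= 1e-9:
                    status = CORE_BREACH
                    d = 1e-3
                s2 = sig * sig / (d * d)
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                e += 4.0 * wall_eps * (s12 - s6) + wall_eps
                dudd = 4.0 * wall_eps * (-12.0 * s12 + 6.0 * s6) / d
                f[i, 2] -= dudd
            # top wall
            d = Lz - z
            if d < rc:
                if d <= 1e-9:
                    status = CORE_BREACH
                    d = 1e-3
                s2 = sig * sig / (d * d)
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                e += 4.0 * wall_eps * (s12 - s6) + wall_eps
                dudd = 4.0 * wall_eps * (-12.0 * s12 + 6.0 * s6) / d
                f[i, 2] += dudd
        else:
            if species[i] != 0:
                continue
            uy = pos[i, 1] - cy
            uz = pos[i, 2] - cz
            rho = np.sqrt(uy * uy + uz * uz)
            d = R - rho
            rc = RC_WCA * sig_m
            if d < rc:
                if d <= 1e-9:
                    status = CORE_BREACH
                    d = 1e-3
                s2 = sig_m * sig_m / (d * d)
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                e += 4.0 * wall_eps * (s12 - s6) + wall_eps
                dudd = 4.0 * wall_eps * (-12.0 * s12 + 6.0 * s6) / d
                if rho > 1e-12:
                    f[i, 1] += dudd * uy / rho
                    f[i, 2] += dudd * uz / rho
    return e, status


@njit(cache=True)
def eval_forces(pos, species, frozen, bonds, pairs, box, perx, pery, perz,
                geom_code, R, cy, cz, wall_eps,
                sig_m, sig_n, eps, eps_b, delta,
                rc2_mm, rc2_nn, rc2_nm, shift_e, fene_k, fene_r0, f):
    f[:, :] = 0.0
    e_pair, st1 = pair_forces(pos, species, pairs, box, perx, pery, perz,
                              sig_m, sig_n, eps, eps_b, delta,
                              rc2_mm, rc2_nn, rc2_nm, shift_e, f)
    e_bond, maxb = bond_forces(pos, bonds, box, perx, pery, perz,
                               fene_k, fene_r0, f)
    e_wall, st2 = wall_forces(pos, species, frozen, geom_code, box[2], R,
                              cy, cz, wall_eps, sig_m, sig_n, f)
    status = st1 if st1 != OK else st2
    return e_pair, e_bond, e_wall, maxb, status


@njit(cache=True)
def max_pair_energy_kernel(pos, species, box, perx, pery, perz,
                           sig_m, sig_n, eps, eps_b, delta,
                           rc2_mm, rc2_nn, rc2_nm, shift_e):
    """Largest single non-bonded pair energy (brute force over all pairs)."""
    n = pos.shape[0]
    worst = -1.0e300
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0], perx)
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1], pery)
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2], perz)
            r2 = dx * dx + dy * dy + dz * dz
            si = species[i]
            sj = species[j]
            e = 0.0
            if si == sj:
                sig = sig_m if si == 0 else sig_n
                rc2 = rc2_mm if si == 0 else rc2_nn
                if r2 < rc2:
                    s6 = (sig * sig / r2) ** 3
                    e = 4.0 * eps * (s6 * s6 - s6) + eps
            else:
                if r2 < rc2_nm:
                    rr = np.sqrt(r2) - delta
                    if rr <= 0.0:
                        return 1.0e300
                    x6 = (sig_m / rr) ** 6
                    e = 4.0 * eps_b * (x6 * x6 - x6) - shift_e
            if e > worst:
                worst = e
    return worst


@njit(cache=True)
def eval_forces_split(pos, species, frozen, bonds, p_mm, p_nn, p_nm, box,
                      perx, pery, perz, geom_code, R, cy, cz, wall_eps,
                      sig_m, sig_n, eps, eps_b, delta,
                      rc2_mm, rc2_nn, rc2_nm, shift_e, fene_k, fene_r0, f):
    """Force evaluation over type-partitioned pair lists (hot path)."""
    f[:, :] = 0.0
    e_p = wca_pair_forces(pos, p_mm, box, perx, pery, perz,
                          sig_m, eps, rc2_mm, f)
    e_p += wca_pair_forces(pos, p_nn, box, perx, pery, perz,
                           sig_n, eps, rc2_nn, f)
    e_x, st_x = nm_pair_forces(pos, p_nm, box, perx, pery, perz,
                               sig_m, eps_b, delta, rc2_nm, shift_e, f)
    e_b, mb = bond_forces(pos, bonds, box, perx, pery, perz,
                          fene_k, fene_r0, f)
    e_w, st_w = wall_forces(pos, species, frozen, geom_code, box[2], R,
                            cy, cz, wall_eps, sig_m, sig_n, f)
    st = st_x if st_x != OK else st_w
    return e_p + e_x, e_b, e_w, mb, st


@njit(cache=True, fastmath=True)
def run_langevin(pos, vel, species, frozen, bonds, box, perx, pery, perz,
                 geom_code, R, cy, cz, wall_eps,
                 sig_m, sig_n, eps, eps_b, delta,
                 rc2_mm, rc2_nn, rc2_nm, shift_e, fene_k, fene_r0,
                 dt, gamma, kT, n_steps, seed, step0,
                 snap_stride, snaps, snap_steps,
                 log_stride, log_rows,
                 list_cutoff, lc2_mm, lc2_nn, lc2_nm, skin, use_cells):
    """Integrate n_steps of BAOAB Langevin dynamics in place.

    Returns (status, step): status OK(0) on success, otherwise the failure
    code and the global step index at which it was detected.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    half = 0.5 * dt
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1) * kT))
    c2u = c2 * np.sqrt(12.0)
    n_free = 0
    for i in range(n):
        if not frozen[i]:
            n_free += 1
    rebuild2 = (0.5 * skin) ** 2

    pairs = build_pairs(pos, species, box, perx, pery, perz, list_cutoff,
                        lc2_mm, lc2_nn, lc2_nm, use_cells)
    p_mm, p_nn, p_nm = partition_pairs(pairs, species)
    ref = pos.copy()

    e_pair, e_bond, e_wall, maxb, status = eval_forces_split(
        pos, species, frozen, bonds, p_mm, p_nn, p_nm, box,
        perx, pery, perz, geom_code, R, cy, cz, wall_eps,
        sig_m, sig_n, eps, eps_b, delta, rc2_mm, rc2_nn, rc2_nm, shift_e,
        fene_k, fene_r0, f)
    if status != OK:
        return status, step0
    if maxb >= fene_r0:
        return BOND_OVERSTRETCH, step0

    i_snap = 0
    i_log = 0
    for s in range(n_steps):
        # fused B-A-O-A sweep with wrapping and displacement tracking
        maxd2 = 0.0
        for i in range(n):
            if frozen[i]:
                continue
            vx = vel[i, 0] + half * f[i, 0]
            vy = vel[i, 1] + half * f[i, 1]
            vz = vel[i, 2] + half * f[i, 2]
            x = pos[i, 0] + half * vx
            y = pos[i, 1] + half * vy
            z = pos[i, 2] + half * vz
            if gamma > 0.0:
                # uniform noise with unit variance; the O-step mixing
                # (c1 ~ 1) keeps the velocity distribution Gaussian
                vx = c1 * vx + c2u * (np.random.random() - 0.5)
                vy = c1 * vy + c2u * (np.random.random() - 0.5)
                vz = c1 * vz + c2u * (np.random.random() - 0.5)
            x += half * vx
            y += half * vy
            z += half * vz
            if perx:
                x -= box[0] * np.floor(x / box[0])
            if pery:
                y -= box[1] * np.floor(y / box[1])
            if perz:
                z -= box[2] * np.floor(z / box[2])
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            dx = _min_image(x - ref[i, 0], box[0], perx)
            dy = _min_image(y - ref[i, 1], box[1], pery)
            dz = _min_image(z - ref[i, 2], box[2], perz)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2

        # neighbor-list validity: rebuild after skin/2 displacement
        if maxd2 > rebuild2:
            if not np.all(np.isfinite(pos)):
                return NON_FINITE, step0 + s + 1
            pairs = build_pairs(pos, species, box, perx, pery, perz,
                                list_cutoff, lc2_mm, lc2_nn, lc2_nm,
                                use_cells)
            p_mm, p_nn, p_nm = partition_pairs(pairs, species)
            ref[:, :] = pos

        e_pair, e_bond, e_wall, maxb, status = eval_forces_split(
            pos, species, frozen, bonds, p_mm, p_nn, p_nm, box,
            perx, pery, perz, geom_code, R, cy, cz, wall_eps,
            sig_m, sig_n, eps, eps_b, delta, rc2_mm, rc2_nn, rc2_nm,
            shift_e, fene_k, fene_r0, f)
        if status != OK:
            return status, step0 + s + 1
        if maxb >= fene_r0:
            return BOND_OVERSTRETCH, step0 + s + 1
        for i in range(n):
            if frozen[i]:
                continue
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]

        if log_stride > 0 and (s + 1) % log_stride == 0 \
                and i_log < log_rows.shape[0]:
            ke = 0.0
            for i in range(n):
                if frozen[i]:
                    continue
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            t_inst = ke / (3.0 * n_free) if n_free > 0 else 0.0
            log_rows[i_log, 0] = step0 + s + 1
            log_rows[i_log, 1] = t_inst
            log_rows[i_log, 2] = e_pair
            log_rows[i_log, 3] = e_bond
            log_rows[i_log, 4] = e_wall
            i_log += 1
        if snap_stride > 0 and (s + 1) % snap_stride == 0 \
                and i_snap < snaps.shape[0]:
            snaps[i_snap, :, :] = pos
            snap_steps[i_snap] = step0 + s + 1
            i_snap += 1
    return OK, step0 + n_steps
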