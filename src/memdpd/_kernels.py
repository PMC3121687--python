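"""Numba kernels for the DPD force loop.

The nonbonded kernel uses a linked-cell neighbor search (falling back to an
all-pairs loop when the box is too small for 3 cells per dimension) and a
counter-based random number stream: the noise for a pair (i, j) at step t is
a pure hash of (seed, t, min(i,j), max(i,j)), so trajectories are
bit-reproducible for a given seed regardless of the order in which the cell
walk visits pairs. The noise is uniform, scaled to zero mean and unit
variance (the standard cheap choice in DPD; only the first two moments
matter for the thermostat).

Every kernel accumulates the pairwise virial diagonal, from which the
pressure tensor and the lateral tension are assembled in
:mod:`memdpd.engine`.
"""

import numpy as np
from numba import njit

U64 = np.uint64
_GOLD = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_SQRT3 = 1.7320508075688772
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = x + _GOLD
    z = (x ^ (x >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def pair_zeta(seed, step, i, j):
    """Zero-mean unit-variance draw for pair (i<j) at a given step."""
    h = _splitmix64(U64(seed) ^ (U64(step) * _MIX1))
    h = _splitmix64(h ^ (U64(i) * _GOLD) ^ U64(j))
    u = np.float64(h >> U64(11)) * _INV_2_53
    return _SQRT3 * (2.0 * u - 1.0)


@njit(cache=True, inline="always")
def _pair_interaction(i, j, sx, sy, sz, pos, vel, species, a, gamma, sigma,
                      rc, inv_sqrt_dt, seed, step, forces, virial):
    # (sx, sy, sz) is the periodic shift applied to bead j, precomputed
    # per cell pair so no per-pair division is needed
    dx = pos[i, 0] - pos[j, 0] - sx
    dy = pos[i, 1] - pos[j, 1] - sy
    dz = pos[i, 2] - pos[j, 2] - sz
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc or r2 <= 1e-24:
        return
    r = np.sqrt(r2)
    w = 1.0 - r / rc
    ex = dx / r
    ey = dy / r
    ez = dz / r
    # conservative
    f = a[species[i], species[j]] * w
    # dissipative
    dvx = vel[i, 0] - vel[j, 0]
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    rv = ex * dvx + ey * dvy + ez * dvz
    f += -gamma * w * w * rv
    # random (pair-shared draw, ordered indices for order-independence)
    if i < j:
        zeta = pair_zeta(seed, step, i, j)
    else:
        zeta = pair_zeta(seed, step, j, i)
    f += sigma * w * zeta * inv_sqrt_dt
    fx = f * ex
    fy = f * ey
    fz = f * ez
    forces[i, 0] += fx
    forces[i, 1] += fy
    forces[i, 2] += fz
    forces[j, 0] -= fx
    forces[j, 1] -= fy
    forces[j, 2] -= fz
    virial[0] += fx * dx
    virial[1] += fy * dy
    virial[2] += fz * dz


@njit(cache=True)
def nonbonded_forces(pos, vel, species, box, a, gamma, sigma, rc,
                     inv_sqrt_dt, seed, step, forces, virial):
    """Accumulate all nonbonded pair forces and their virial diagonal.

    Beads are counting-sorted by cell so cell contents are contiguous in
    memory; the cell walk visits each unordered cell pair once via a
    13-offset half shell, with the periodic shift precomputed per cell
    pair. Small or thin boxes fall back to an all-pairs loop.
    """
    n = pos.shape[0]
    ncx = int(box[0] / rc)
    ncy = int(box[1] / rc)
    ncz = int(box[2] / rc)
    if ncx < 3 or ncy < 3 or ncz < 3 or n < 64:
        hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
        for i in range(n):
            for j in range(i + 1, n):
                sx = 0.0
                sy = 0.0
                sz = 0.0
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if dx > hx:
                    sx = box[0]
                elif dx < -hx:
                    sx = -box[0]
                if dy > hy:
                    sy = box[1]
                elif dy < -hy:
                    sy = -box[1]
                if dz > hz:
                    sz = box[2]
                elif dz < -hz:
                    sz = -box[2]
                _pair_interaction(i, j, sx, sy, sz, pos, vel, species, a,
                                  gamma, sigma, rc, inv_sqrt_dt, seed, step,
                                  forces, virial)
        return
    ncell = ncx * ncy * ncz
    count = np.zeros(ncell + 1, dtype=np.int64)
    cellid = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx)
        cy = int(pos[i, 1] / box[1] * ncy)
        cz = int(pos[i, 2] / box[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cellid[i] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cellid[i]
        order[fill[c]] = i
        fill[c] += 1
    ps = pos[order]
    vs = vel[order]
    sp = species[order]
    fs = np.zeros((n, 3))
    rc2 = rc * rc
    offs = np.array([
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ], dtype=np.int64)
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                s0 = count[c]
                e0 = count[c + 1]
                for ii in range(s0, e0):
                    for jj in range(ii + 1, e0):
                        dx = ps[ii, 0] - ps[jj, 0] - 0.0
                        dy = ps[ii, 1] - ps[jj, 1] - 0.0
                        dz = ps[ii, 2] - ps[jj, 2] - 0.0
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2 and r2 > 1e-24:
                            r = np.sqrt(r2)
                            w = 1.0 - r / rc
                            ex = dx / r
                            ey = dy / r
                            ez = dz / r
                            f = a[sp[ii], sp[jj]] * w
                            rv = (ex * (vs[ii, 0] - vs[jj, 0])
                                  + ey * (vs[ii, 1] - vs[jj, 1])
                                  + ez * (vs[ii, 2] - vs[jj, 2]))
                            f += -gamma * w * w * rv
                            gi = order[ii]
                            gj = order[jj]
                            if gi < gj:
                                zeta = pair_zeta(seed, step, gi, gj)
                            else:
                                zeta = pair_zeta(seed, step, gj, gi)
                            f += sigma * w * zeta * inv_sqrt_dt
                            fx = f * ex
                            fy = f * ey
                            fz = f * ez
                            fs[ii, 0] += fx
                            fs[ii, 1] += fy
                            fs[ii, 2] += fz
                            fs[jj, 0] -= fx
                            fs[jj, 1] -= fy
                            fs[jj, 2] -= fz
                            virial[0] += fx * dx
                            virial[1] += fy * dy
                            virial[2] += fz * dz
                for k in range(13):
                    ox = cx + offs[k, 0]
                    oy = cy + offs[k, 1]
                    oz = cz + offs[k, 2]
                    sx = 0.0
                    sy = 0.0
                    sz = 0.0
                    if ox >= ncx:
                        ox -= ncx
                        sx = box[0]
                    elif ox < 0:
                        ox += ncx
                        sx = -box[0]
                    if oy >= ncy:
                        oy -= ncy
                        sy = box[1]
                    elif oy < 0:
                        oy += ncy
                        sy = -box[1]
                    if oz >= ncz:
                        oz -= ncz
                        sz = box[2]
                    elif oz < 0:
                        oz += ncz
                        sz = -box[2]
                    c2 = (ox * ncy + oy) * ncz + oz
                    s1 = count[c2]
                    e1 = count[c2 + 1]
                    for ii in range(s0, e0):
                        for jj in range(s1, e1):
                            dx = ps[ii, 0] - ps[jj, 0] - sx
                            dy = ps[ii, 1] - ps[jj, 1] - sy
                            dz = ps[ii, 2] - ps[jj, 2] - sz
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2 and r2 > 1e-24:
                                r = np.sqrt(r2)
                                w = 1.0 - r / rc
                                ex = dx / r
                                ey = dy / r
                                ez = dz / r
                                f = a[sp[ii], sp[jj]] * w
                                rv = (ex * (vs[ii, 0] - vs[jj, 0])
                                      + ey * (vs[ii, 1] - vs[jj, 1])
                                      + ez * (vs[ii, 2] - vs[jj, 2]))
                                f += -gamma * w * w * rv
                                gi = order[ii]
                                gj = order[jj]
                                if gi < gj:
                                    zeta = pair_zeta(seed, step, gi, gj)
                                else:
                                    zeta = pair_zeta(seed, step, gj, gi)
                                f += sigma * w * zeta * inv_sqrt_dt
                                fx = f * ex
                                fy = f * ey
                                fz = f * ez
                                fs[ii, 0] += fx
                                fs[ii, 1] += fy
                                fs[ii, 2] += fz
                                fs[jj, 0] -= fx
                                fs[jj, 1] -= fy
                                fs[jj, 2] -= fz
                                virial[0] += fx * dx
                                virial[1] += fy * dy
                                virial[2] += fz * dz
    for ii in range(n):
        i = order[ii]
        forces[i, 0] += fs[ii, 0]
        forces[i, 1] += fs[ii, 1]
        forces[i, 2] += fs[ii, 2]


@njit(cache=True)
def bond_forces(pos, box, bonds, bond_params, forces, virial):
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        k = bond_params[b, 0]
        l0 = bond_params[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        f = -k * (r - l0) / r
        fx = f * dx
        fy = f * dy
        fz = f * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz


@njit(cache=True)
def angle_forces(pos, box, angles, angle_params, forces, virial):
    """Three-point bending forces, U = 1/2 k (theta - theta0)^2.

    Central bead is the second index. Near theta = pi the 1/sin(theta)
    factor is regularized; since (theta - theta0) vanishes there for the
    straight-chain rest angle the force stays finite and smooth.
    """
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        kb = angle_params[t, 0]
        th0 = angle_params[t, 1]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ux -= box[0] * np.round(ux / box[0])
        uy -= box[1] * np.round(uy / box[1])
        uz -= box[2] * np.round(uz / box[2])
        vx -= box[0] * np.round(vx / box[0])
        vy -= box[1] * np.round(vy / box[1])
        vz -= box[2] * np.round(vz / box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if ru < 1e-12 or rv < 1e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = kb * (theta - th0) / s
        # dtheta/dr_i = -(v_hat - c*u_hat)/(ru*s); F = -dU/dr
        fix = coef * (vx / rv - c * ux / ru) / ru
        fiy = coef * (vy / rv - c * uy / ru) / ru
        fiz = coef * (vz / rv - c * uz / ru) / ru
        fkx = coef * (ux / ru - c * vx / rv) / rv
        fky = coef * (uy / ru - c * vy / rv) / rv
        fkz = coef * (uz / ru - c * vz / rv) / rv
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        virial[0] += fix * ux + fkx * vx
        virial[1] += fiy * uy + fky * vy
        virial[2] += fiz * uz + fkz * vz


@njit(cache=True)
def bonded_energy(pos, box, bonds, bond_params, angles, angle_params):
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bond_params[b, 1]
        e += 0.5 * bond_params[b, 0] * d * d
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ux -= box[0] * np.round(ux / box[0])
        uy -= box[1] * np.round(uy / box[1])
        uz -= box[2] * np.round(uz / box[2])
        vx -= box[0] * np.round(vx / box[0])
        vy -= box[1] * np.round(vy / box[1])
        vz -= box[2] * np.round(vz / box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        d = np.arccos(c) - angle_params[t, 1]
        e += 0.5 * angle_params[t, 0] * d * d
    return e
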