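"""Compiled inner loops for DPD dynamics and local-stress analysis.

Everything here is numba-jitted and operates on plain ndarrays; the
object-level API lives in :mod:`vesibud.engine` and
:mod:`vesibud.stress_elastic`.  All kernels are serial and deterministic
given the numba RNG seed set through :func:`seed_rng`.

Pair forces follow the standard DPD form: soft linear conservative
repulsion f_ij (1 - r/d), pairwise drag -gamma (1 - r/d)^2 (v_ij . rhat)
and matched random kicks sigma (1 - r/d) xi / sqrt(dt), so that momentum
is conserved exactly and the fluctuation-dissipation relation
sigma^2 = 2 gamma k_B T fixes the temperature.  The chain-stiffness
potential bend_k (1 - cos phi) is evaluated in its distance form
cos phi = (r_ik^2 - r_ij^2 - r_jk^2) / (2 r_ij r_jk), which yields an
exact central-force decomposition over the three bead pairs - the same
decomposition feeds the Irving-Kirkwood stress bins.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SQRT3 = np.sqrt(3.0)


@njit(cache=True, fastmath=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True, inline="always")
def _min_image(d, L):
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(cache=True)
def wrap_positions(pos, box):
    n = pos.shape[0]
    for i in range(n):
        for a in range(3):
            L = box[a]
            x = pos[i, a] % L
            if x < 0.0:
                x += L
            pos[i, a] = x


@njit(cache=True, fastmath=True)
def _bonded_forces(pos, box, bonds, bond_k, bond_l0, angles, bend_k, forces):
    """Harmonic bonds + distance-form angle stiffness. Returns virial sum F.r."""
    vir = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        g = -bond_k * (r - bond_l0)  # force on i along +rij
        inv = g / r
        forces[i, 0] += inv * dx
        forces[i, 1] += inv * dy
        forces[i, 2] += inv * dz
        forces[j, 0] -= inv * dx
        forces[j, 1] -= inv * dy
        forces[j, 2] -= inv * dz
        vir += g * r
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        # pair vectors i-j (a), j-k (b), i-k (c)
        ax = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], box[1])
        az = _min_image(pos[i, 2] - pos[j, 2], box[2])
        bx = _min_image(pos[j, 0] - pos[k, 0], box[0])
        by = _min_image(pos[j, 1] - pos[k, 1], box[1])
        bz = _min_image(pos[j, 2] - pos[k, 2], box[2])
        cx = ax + bx
        cy = ay + by
        cz = az + bz
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb = np.sqrt(bx * bx + by * by + bz * bz)
        rc2 = cx * cx + cy * cy + cz * cz
        rc = np.sqrt(rc2)
        if ra < 1e-12 or rb < 1e-12:
            continue
        # U = bend_k (1 - cos phi), cos phi = (rc^2 - ra^2 - rb^2)/(2 ra rb)
        # central pair force magnitudes g = -dU/dr (positive = repulsive)
        ga = bend_k * (-ra * ra + rb * rb - rc2) / (2.0 * ra * ra * rb)
        gb = bend_k * (-rb * rb + ra * ra - rc2) / (2.0 * ra * rb * rb)
        gc = bend_k * rc / (ra * rb)
        inv = ga / ra
        forces[i, 0] += inv * ax
        forces[i, 1] += inv * ay
        forces[i, 2] += inv * az
        forces[j, 0] -= inv * ax
        forces[j, 1] -= inv * ay
        forces[j, 2] -= inv * az
        inv = gb / rb
        forces[j, 0] += inv * bx
        forces[j, 1] += inv * by
        forces[j, 2] += inv * bz
        forces[k, 0] -= inv * bx
        forces[k, 1] -= inv * by
        forces[k, 2] -= inv * bz
        if rc > 1e-12:
            inv = gc / rc
            forces[i, 0] += inv * cx
            forces[i, 1] += inv * cy
            forces[i, 2] += inv * cz
            forces[k, 0] -= inv * cx
            forces[k, 1] -= inv * cy
            forces[k, 2] -= inv * cz
        vir += ga * ra + gb * rb + gc * rc
    return vir


@njit(cache=True, fastmath=True, inline="always")
def _pair_kernel(dx, dy, dz, r2, i, j, ti, tj, vel, fmat, rc, gamma, sigma, inv_sqrt_dt, with_thermo, forces):
    r = np.sqrt(r2)
    if r < 1e-12:
        return 0.0
    w = 1.0 - r / rc
    fc = fmat[ti, tj] * w
    g = fc
    if with_thermo:
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        rv = (dx * vx + dy * vy + dz * vz) / r
        g += -gamma * w * w * rv
        xi = (np.random.random() * 2.0 - 1.0) * SQRT3  # unit-variance uniform
        g += sigma * w * xi * inv_sqrt_dt
    inv = g / r
    forces[i, 0] += inv * dx
    forces[i, 1] += inv * dy
    forces[i, 2] += inv * dz
    forces[j, 0] -= inv * dx
    forces[j, 1] -= inv * dy
    forces[j, 2] -= inv * dz
    return fc * r  # conservative virial only


@njit(cache=True, fastmath=True)
def compute_forces_allpairs(pos, vel, types, box, fmat, rc, gamma, sigma, inv_sqrt_dt, with_thermo,
                            bonds, bond_k, bond_l0, angles, bend_k, forces):
    n = pos.shape[0]
    forces[:] = 0.0
    rc2 = rc * rc
    vir = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                vir += _pair_kernel(dx, dy, dz, r2, i, j, types[i], types[j], vel, fmat, rc,
                                    gamma, sigma, inv_sqrt_dt, with_thermo, forces)
    vir += _bonded_forces(pos, box, bonds, bond_k, bond_l0, angles, bend_k, forces)
    return vir


@njit(cache=True, fastmath=True)
def _build_cells(pos, box, ncx, ncy, ncz, cellid, counts, cellstart, order):
    """Counting sort of beads into cells; fills cellstart (prefix sums) and
    order (bead indices grouped by cell)."""
    n = pos.shape[0]
    counts[:] = 0
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
        # clamp below too: guards against non-finite coordinates (int(nan))
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        cellid[i] = c
        counts[c] += 1
    cellstart[0] = 0
    for c in range(counts.shape[0]):
        cellstart[c + 1] = cellstart[c] + counts[c]
    for c in range(counts.shape[0]):
        counts[c] = cellstart[c]
    for i in range(n):
        order[counts[cellid[i]]] = i
        counts[cellid[i]] += 1


@njit(cache=True, fastmath=True)
def compute_forces_cells(pos, vel, types, box, fmat, rc, gamma, sigma, inv_sqrt_dt, with_thermo,
                         bonds, bond_k, bond_l0, angles, bend_k, forces,
                         cellid, counts, cellstart, order, ncx, ncy, ncz):
    """Cell-sorted half-stencil pair loop; requires >= 3 cells per axis."""
    forces[:] = 0.0
    rc2 = rc * rc
    vir = 0.0
    _build_cells(pos, box, ncx, ncy, ncz, cellid, counts, cellstart, order)
    ncells = ncx * ncy * ncz
    for c in range(ncells):
        cz = c % ncz
        cy = (c // ncz) % ncy
        cx = c // (ncz * ncy)
        # s = 0: pairs within the cell; s = 1..13: forward neighbor cells
        for s in range(14):
            if s == 0:
                c2 = c
            else:
                nx = (cx + _STENCIL[s - 1, 0]) % ncx
                ny = (cy + _STENCIL[s - 1, 1]) % ncy
                nz = (cz + _STENCIL[s - 1, 2]) % ncz
                c2 = (nx * ncy + ny) * ncz + nz
            for ii in range(cellstart[c], cellstart[c + 1]):
                i = order[ii]
                pix = pos[i, 0]
                piy = pos[i, 1]
                piz = pos[i, 2]
                ti = types[i]
                j0 = ii + 1 if s == 0 else cellstart[c2]
                for jj in range(j0, cellstart[c2 + 1]):
                    j = order[jj]
                    dx = _min_image(pix - pos[j, 0], box[0])
                    dy = _min_image(piy - pos[j, 1], box[1])
                    dz = _min_image(piz - pos[j, 2], box[2])
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < rc2:
                        vir += _pair_kernel(dx, dy, dz, r2, i, j, ti, types[j], vel, fmat,
                                            rc, gamma, sigma, inv_sqrt_dt, with_thermo, forces)
    vir += _bonded_forces(pos, box, bonds, bond_k, bond_l0, angles, bend_k, forces)
    return vir


_STENCIL = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def advance(pos, vel, types, box, fmat, rc, gamma, sigma, dt, lam, nsteps,
            bonds, bond_k, bond_l0, angles, bend_k, use_cells,
            forces, fnew, vpred, cellid, counts, cellstart, order, ncx, ncy, ncz,
            sample_every, temp_out, vir_out):
    """Modified velocity-Verlet DPD integration for ``nsteps`` steps.

    The dissipative force at t+dt is evaluated with velocities predicted as
    v + lambda dt f(t).  Samples kinetic temperature and the conservative
    virial sum every ``sample_every`` steps into the output arrays; returns
    the number of samples written.
    """
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    if use_cells:
        vir = compute_forces_cells(pos, vel, types, box, fmat, rc, gamma, sigma, inv_sqrt_dt, True,
                                   bonds, bond_k, bond_l0, angles, bend_k, forces,
                                   cellid, counts, cellstart, order, ncx, ncy, ncz)
    else:
        vir = compute_forces_allpairs(pos, vel, types, box, fmat, rc, gamma, sigma, inv_sqrt_dt, True,
                                      bonds, bond_k, bond_l0, angles, bend_k, forces)
    ns = 0
    for step in range(nsteps):
        for i in range(n):
            for a in range(3):
                vpred[i, a] = vel[i, a] + lam * dt * forces[i, a]
                pos[i, a] += dt * vel[i, a] + 0.5 * dt * dt * forces[i, a]
        wrap_positions(pos, box)
        if use_cells:
            vir = compute_forces_cells(pos, vpred, types, box, fmat, rc, gamma, sigma, inv_sqrt_dt, True,
                                       bonds, bond_k, bond_l0, angles, bend_k, fnew,
                                       cellid, counts, cellstart, order, ncx, ncy, ncz)
        else:
            vir = compute_forces_allpairs(pos, vpred, types, box, fmat, rc, gamma, sigma, inv_sqrt_dt, True,
                                          bonds, bond_k, bond_l0, angles, bend_k, fnew)
        ke2 = 0.0
        for i in range(n):
            for a in range(3):
                vel[i, a] += 0.5 * dt * (forces[i, a] + fnew[i, a])
                forces[i, a] = fnew[i, a]
                ke2 += vel[i, a] * vel[i, a]
        if not np.isfinite(ke2):
            return -(step + 1)  # divergence: caller raises naming the step
        if (step + 1) % sample_every == 0:
            temp_out[ns] = ke2 / (3.0 * n)
            vir_out[ns] = vir
            ns += 1
    return ns


@njit(cache=True, fastmath=True)
def stress_accumulate(pos, vel, types, box, center, fmat, rc,
                      bonds, bond_k, bond_l0, angles, bend_k,
                      bin_width, accN, accT):
    """Accumulate one frame's spherical pressure-tensor sums per radial shell.

    Kinetic terms use the bead velocities at the bead radius; configurational
    terms (conservative + bonded central forces only) are spread along the
    straight Irving-Kirkwood contour between the two beads, subdivided into
    pieces of ~bin_width/4, each projected onto the local radial/tangential
    directions.  accN/accT collect extensive sums (pressure x volume); shell
    normalization happens in the caller.  Total conservative virial and total
    kinetic energy are conserved exactly by the binning.
    """
    n = pos.shape[0]
    nbins = accN.shape[0]
    # kinetic part
    for i in range(n):
        rx = _min_image(pos[i, 0] - center[0], box[0])
        ry = _min_image(pos[i, 1] - center[1], box[1])
        rz = _min_image(pos[i, 2] - center[2], box[2])
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        k = int(r / bin_width)
        if k >= nbins:
            k = nbins - 1
        v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        if r > 1e-9:
            vr = (vel[i, 0] * rx + vel[i, 1] * ry + vel[i, 2] * rz) / r
        else:
            vr = 0.0
        accN[k] += vr * vr
        accT[k] += 0.5 * (v2 - vr * vr)
    # configurational: nonbonded pairs via the sorted cell grid when the box
    # admits one (>= 3 cells per axis), else all-pairs
    rc2 = rc * rc
    ncx = int(box[0] / rc)
    ncy = int(box[1] / rc)
    ncz = int(box[2] / rc)
    if ncx >= 3 and ncy >= 3 and ncz >= 3:
        ncells = ncx * ncy * ncz
        cellid = np.empty(n, np.int64)
        counts = np.empty(ncells, np.int64)
        cellstart = np.empty(ncells + 1, np.int64)
        order = np.empty(n, np.int64)
        _build_cells(pos, box, ncx, ncy, ncz, cellid, counts, cellstart, order)
        for c in range(ncells):
            cz = c % ncz
            cy = (c // ncz) % ncy
            cx = c // (ncz * ncy)
            for s in range(14):
                if s == 0:
                    c2 = c
                else:
                    nx = (cx + _STENCIL[s - 1, 0]) % ncx
                    ny = (cy + _STENCIL[s - 1, 1]) % ncy
                    nz = (cz + _STENCIL[s - 1, 2]) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                for ii in range(cellstart[c], cellstart[c + 1]):
                    i = order[ii]
                    j0 = ii + 1 if s == 0 else cellstart[c2]
                    for jj in range(j0, cellstart[c2 + 1]):
                        j = order[jj]
                        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2:
                            r = np.sqrt(r2)
                            if r < 1e-12:
                                continue
                            g = fmat[types[i], types[j]] * (1.0 - r / rc)
                            _spread_pair(pos, box, center, i, j, dx, dy, dz, r, g, bin_width, accN, accT)
    else:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc2:
                    r = np.sqrt(r2)
                    if r < 1e-12:
                        continue
                    g = fmat[types[i], types[j]] * (1.0 - r / rc)
                    _spread_pair(pos, box, center, i, j, dx, dy, dz, r, g, bin_width, accN, accT)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        _spread_pair(pos, box, center, i, j, dx, dy, dz, r, -bond_k * (r - bond_l0), bin_width, accN, accT)
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        ax = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], box[1])
        az = _min_image(pos[i, 2] - pos[j, 2], box[2])
        bx = _min_image(pos[j, 0] - pos[k, 0], box[0])
        by = _min_image(pos[j, 1] - pos[k, 1], box[1])
        bz = _min_image(pos[j, 2] - pos[k, 2], box[2])
        cx = ax + bx
        cy = ay + by
        cz = az + bz
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb = np.sqrt(bx * bx + by * by + bz * bz)
        rc2a = cx * cx + cy * cy + cz * cz
        rcl = np.sqrt(rc2a)
        if ra < 1e-12 or rb < 1e-12:
            continue
        ga = bend_k * (-ra * ra + rb * rb - rc2a) / (2.0 * ra * ra * rb)
        gb = bend_k * (-rb * rb + ra * ra - rc2a) / (2.0 * ra * rb * rb)
        gc = bend_k * rcl / (ra * rb)
        _spread_pair(pos, box, center, i, j, ax, ay, az, ra, ga, bin_width, accN, accT)
        _spread_pair(pos, box, center, j, k, bx, by, bz, rb, gb, bin_width, accN, accT)
        if rcl > 1e-12:
            _spread_pair(pos, box, center, i, k, cx, cy, cz, rcl, gc, bin_width, accN, accT)


@njit(cache=True, fastmath=True, inline="always")
def _spread_pair(pos, box, center, i, j, dx, dy, dz, r, g, bin_width, accN, accT):
    """Spread one central pair force (magnitude g along i-j) over radial bins."""
    nbins = accN.shape[0]
    ax = _min_image(pos[i, 0] - center[0], box[0])
    ay = _min_image(pos[i, 1] - center[1], box[1])
    az = _min_image(pos[i, 2] - center[2], box[2])
    # j placed at the image nearest to i (consistent with the pair vector)
    m = int(r / (0.25 * bin_width)) + 1
    wpiece = 1.0 / m
    gr = g * r
    for p in range(m):
        t = (p + 0.5) / m
        xm = ax - t * dx
        ym = ay - t * dy
        zm = az - t * dz
        rm = np.sqrt(xm * xm + ym * ym + zm * zm)
        k = int(rm / bin_width)
        if k >= nbins:
            k = nbins - 1
        if rm > 1e-9:
            c = (dx * xm + dy * ym + dz * zm) / (r * rm)
        else:
            c = 0.0
        c2 = c * c
        accN[k] += wpiece * gr * c2
        accT[k] += wpiece * gr * (1.0 - c2) * 0.5
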