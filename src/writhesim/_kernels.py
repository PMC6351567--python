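"""Numba kernels: pair forces, Langevin velocity-Verlet loop, writhe double sum.

All kernels operate on plain float64 arrays in reduced units (lengths in
sigma, energies in epsilon, time in tau = sigma*sqrt(m/eps)).  Status codes
returned by the dynamics loop:

    0  ok
    1  FENE bond reached r0 (overstretch)
    2  bead pair at zero separation (overlap)
    3  non-finite energy/coordinates (blowup)
    4  bead at or beyond a confining surface (escape)
    5  neighbour-list capacity exceeded
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)


# ----------------------------------------------------------------------------
# neighbour list (Verlet list with skin; exact pair sums, O(N^2) rebuilds)
# ----------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(pos, cutoff, pairs):
    """Fill `pairs` with all i<j within `cutoff`; return count (-1 on overflow)."""
    n = pos.shape[0]
    cap = pairs.shape[0]
    c2 = cutoff * cutoff
    m = 0
    for i in range(n - 1):
        xi = pos[i, 0]; yi = pos[i, 1]; zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                if m >= cap:
                    return -1
                pairs[m, 0] = i
                pairs[m, 1] = j
                m += 1
    return m


# ----------------------------------------------------------------------------
# forces
# ----------------------------------------------------------------------------

@njit(cache=True)
def _compute_forces(pos, f, bonds, fene_k, fene_r0, angles, kb,
                    eps, sig, use_soft, soft_a, soft_rc,
                    has_wall, radius, has_pistons, z_lo, z_hi,
                    pairs, npairs):
    """Accumulate all forces into f; return (potential energy, status, index).

    Nonbonded term is WCA on *all* listed pairs (Kremer-Grest convention,
    bonded neighbours included) or, when use_soft != 0, the soft overlap-
    removal potential A*(1 + cos(pi r / rc)).
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    energy = 0.0
    status = 0
    bad = -1

    # --- nonbonded pairs ---
    if use_soft != 0:
        cut2 = soft_rc * soft_rc
    else:
        cut2 = (WCA_CUT * sig) * (WCA_CUT * sig)
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        if use_soft != 0:
            r = np.sqrt(r2)
            energy += soft_a * (1.0 + np.cos(np.pi * r / soft_rc))
            if r > 1e-12:
                fr = soft_a * np.pi / soft_rc * np.sin(np.pi * r / soft_rc) / r
            else:
                fr = 0.0
        else:
            if r2 < 1e-24:
                status = 2
                bad = i
                continue
            sr2 = sig * sig / r2
            sr6 = sr2 * sr2 * sr2
            energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
            fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        f[i, 0] += fr * dx
        f[i, 1] += fr * dy
        f[i, 2] += fr * dz
        f[j, 0] -= fr * dx
        f[j, 1] -= fr * dy
        f[j, 2] -= fr * dz

    # --- FENE bonds ---
    r02 = fene_r0 * fene_r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            status = 1
            bad = b
            continue
        x = 1.0 - r2 / r02
        energy += -0.5 * fene_k * r02 * np.log(x)
        fr = -fene_k / x
        f[i, 0] += fr * dx
        f[i, 1] += fr * dy
        f[i, 2] += fr * dz
        f[j, 0] -= fr * dx
        f[j, 1] -= fr * dy
        f[j, 2] -= fr * dz

    # --- harmonic bending U = kb (theta - pi)^2, theta at the middle bead ---
    if kb > 0.0:
        for a in range(angles.shape[0]):
            i = angles[a, 0]
            j = angles[a, 1]
            k = angles[a, 2]
            d1x = pos[i, 0] - pos[j, 0]
            d1y = pos[i, 1] - pos[j, 1]
            d1z = pos[i, 2] - pos[j, 2]
            d2x = pos[k, 0] - pos[j, 0]
            d2y = pos[k, 1] - pos[j, 1]
            d2z = pos[k, 2] - pos[j, 2]
            rsq1 = d1x * d1x + d1y * d1y + d1z * d1z
            rsq2 = d2x * d2x + d2y * d2y + d2z * d2z
            r1 = np.sqrt(rsq1)
            r2_ = np.sqrt(rsq2)
            c = (d1x * d2x + d1y * d2y + d1z * d2z) / (r1 * r2_)
            if c > 1.0:
                c = 1.0
            if c < -1.0:
                c = -1.0
            s = np.sqrt(1.0 - c * c)
            if s < 1e-8:
                s = 1e-8
            dtheta = np.arccos(c) - np.pi
            energy += kb * dtheta * dtheta
            aa = -2.0 * kb * dtheta / s
            a11 = aa * c / rsq1
            a12 = -aa / (r1 * r2_)
            a22 = aa * c / rsq2
            f1x = a11 * d1x + a12 * d2x
            f1y = a11 * d1y + a12 * d2y
            f1z = a11 * d1z + a12 * d2z
            f3x = a22 * d2x + a12 * d1x
            f3y = a22 * d2y + a12 * d1y
            f3z = a22 * d2z + a12 * d1z
            f[i, 0] += f1x
            f[i, 1] += f1y
            f[i, 2] += f1z
            f[k, 0] += f3x
            f[k, 1] += f3y
            f[k, 2] += f3z
            f[j, 0] -= f1x + f3x
            f[j, 1] -= f1y + f3y
            f[j, 2] -= f1z + f3z

    # --- confining surfaces: WCA on the distance to the surface ---
    wcut = WCA_CUT * sig
    if has_wall != 0:
        for i in range(n):
            rho = np.sqrt(pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1])
            d = radius - rho
            if d <= 0.0:
                status = 4
                bad = i
                continue
            if d < wcut and rho > 1e-12:
                sr2 = sig * sig / (d * d)
                sr6 = sr2 * sr2 * sr2
                energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
                g = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d  # > 0, repulsive
                f[i, 0] -= g * pos[i, 0] / rho
                f[i, 1] -= g * pos[i, 1] / rho
    if has_pistons != 0:
        for i in range(n):
            d = pos[i, 2] - z_lo
            if d <= 0.0:
                status = 4
                bad = i
                continue
            if d < wcut:
                sr2 = sig * sig / (d * d)
                sr6 = sr2 * sr2 * sr2
                energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
                f[i, 2] += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d
            d = z_hi - pos[i, 2]
            if d <= 0.0:
                status = 4
                bad = i
                continue
            if d < wcut:
                sr2 = sig * sig / (d * d)
                sr6 = sr2 * sr2 * sr2
                energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
                f[i, 2] -= 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d

    return energy, status, bad


# ----------------------------------------------------------------------------
# Langevin velocity-Verlet loop
# ----------------------------------------------------------------------------

@njit(cache=True)
def _run(pos, vel, bonds, angles, kb, fene_k, fene_r0, eps, sig,
         use_soft, soft_a0, soft_a1, soft_rc,
         has_wall, radius, has_pistons, z_lo0, z_hi0,
         piston_speed, target_gap,
         dt, gamma, temp, mass, seed, n_steps, stride,
         out_pos, out_vel, out_times, out_energy, t0):
    """Integrate n_steps of Langevin dynamics (impulse friction/noise).

    The random force is drawn once per step and held constant across both
    half-kicks (variance 2*gamma*m*kBT/dt per component), which reproduces
    the Ornstein-Uhlenbeck velocity variance to O(dt).  gamma = 0 recovers
    plain (symplectic) velocity Verlet.

    Returns (status, fail_step, n_samples, z_lo, z_hi, n_rebuilds).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    xi = np.zeros((n, 3))

    skin = 0.4 * sig
    if use_soft != 0:
        base_cut = soft_rc
    else:
        base_cut = WCA_CUT * sig
    cutoff = base_cut + skin
    cap = 320 * n + 20000
    pairs = np.empty((cap, 2), np.int64)
    npairs = _build_pairs(pos, cutoff, pairs)
    if npairs < 0:
        return 5, 0, 0, z_lo0, z_hi0, 0
    ref = pos.copy()
    n_rebuilds = 1
    half_skin2 = (0.5 * skin) * (0.5 * skin)

    z_lo = z_lo0
    z_hi = z_hi0
    soft_a = soft_a0

    energy, status, bad = _compute_forces(
        pos, f, bonds, fene_k, fene_r0, angles, kb, eps, sig,
        use_soft, soft_a, soft_rc, has_wall, radius, has_pistons,
        z_lo, z_hi, pairs, npairs)
    if status != 0:
        return status, 0, 0, z_lo, z_hi, n_rebuilds

    if gamma > 0.0:
        pref = np.sqrt(2.0 * gamma * mass * temp / dt)
    else:
        pref = 0.0
    half_dt_m = 0.5 * dt / mass
    nsample = 0

    for step in range(n_steps):
        if use_soft != 0 and n_steps > 1:
            soft_a = soft_a0 + (soft_a1 - soft_a0) * step / (n_steps - 1.0)
        if gamma > 0.0:
            for i in range(n):
                xi[i, 0] = pref * np.random.standard_normal()
                xi[i, 1] = pref * np.random.standard_normal()
                xi[i, 2] = pref * np.random.standard_normal()
        # first half-kick and drift
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt_m * (
                    f[i, d] + xi[i, d] - gamma * mass * vel[i, d])
                pos[i, d] += dt * vel[i, d]
        # piston motion (symmetric, constant speed, clamped at target)
        if piston_speed > 0.0 and (z_hi - z_lo) > target_gap:
            z_lo += piston_speed * dt
            z_hi -= piston_speed * dt
            if (z_hi - z_lo) < target_gap:
                zc = 0.5 * (z_hi + z_lo)
                z_lo = zc - 0.5 * target_gap
                z_hi = zc + 0.5 * target_gap
        # neighbour-list validity
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half_skin2:
            npairs = _build_pairs(pos, cutoff, pairs)
            if npairs < 0:
                return 5, step, nsample, z_lo, z_hi, n_rebuilds
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
            n_rebuilds += 1
        energy, status, bad = _compute_forces(
            pos, f, bonds, fene_k, fene_r0, angles, kb, eps, sig,
            use_soft, soft_a, soft_rc, has_wall, radius, has_pistons,
            z_lo, z_hi, pairs, npairs)
        if status != 0:
            return status, step, nsample, z_lo, z_hi, n_rebuilds
        # second half-kick (same random impulse)
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt_m * (
                    f[i, d] + xi[i, d] - gamma * mass * vel[i, d])
        if (step + 1) % 1000 == 0 and not np.isfinite(energy):
            return 3, step, nsample, z_lo, z_hi, n_rebuilds
        if stride > 0 and (step + 1) % stride == 0:
            ke = 0.0
            for i in range(n):
                out_pos[nsample, i, 0] = pos[i, 0]
                out_pos[nsample, i, 1] = pos[i, 1]
                out_pos[nsample, i, 2] = pos[i, 2]
                out_vel[nsample, i, 0] = vel[i, 0]
                out_vel[nsample, i, 1] = vel[i, 1]
                out_vel[nsample, i, 2] = vel[i, 2]
                ke += 0.5 * mass * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                    + vel[i, 2] ** 2)
            out_times[nsample] = t0 + (step + 1) * dt
            out_energy[nsample, 0] = energy
            out_energy[nsample, 1] = ke
            nsample += 1

    return 0, n_steps, nsample, z_lo, z_hi, n_rebuilds


# ----------------------------------------------------------------------------
# writhe: exact signed solid angle per segment pair (closed form)
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _tri_solid_angle(ax, ay, az, bx, by, bz, cx, cy, cz):
    """Signed solid angle of the spherical triangle of three unit vectors:
    2 atan2(a.(b x c), 1 + a.b + b.c + c.a) (numerically stable)."""
    num = (ax * (by * cz - bz * cy) + ay * (bz * cx - bx * cz)
           + az * (bx * cy - by * cx))
    den = (1.0 + ax * bx + ay * by + az * bz
           + bx * cx + by * cy + bz * cz
           + cx * ax + cy * ay + cz * az)
    return 2.0 * np.arctan2(num, den)


@njit(cache=True, inline="always")
def _pair_solid_angle(p1x, p1y, p1z, p2x, p2y, p2z,
                      p3x, p3y, p3z, p4x, p4y, p4z):
    """Signed Gauss integral over one ordered segment pair (p1->p2, p3->p4).

    The contribution is the signed area of the quadrilateral cut on the
    unit sphere by the directions between the segment endpoints, split into
    two spherical triangles evaluated with the stable atan2 form; the
    traversal orientation carries the crossing handedness, so no separate
    sign factor is needed.
    """
    r13x = p3x - p1x; r13y = p3y - p1y; r13z = p3z - p1z
    r14x = p4x - p1x; r14y = p4y - p1y; r14z = p4z - p1z
    r23x = p3x - p2x; r23y = p3y - p2y; r23z = p3z - p2z
    r24x = p4x - p2x; r24y = p4y - p2y; r24z = p4z - p2z

    m13 = np.sqrt(r13x * r13x + r13y * r13y + r13z * r13z)
    m14 = np.sqrt(r14x * r14x + r14y * r14y + r14z * r14z)
    m23 = np.sqrt(r23x * r23x + r23y * r23y + r23z * r23z)
    m24 = np.sqrt(r24x * r24x + r24y * r24y + r24z * r24z)
    if m13 < 1e-14 or m14 < 1e-14 or m23 < 1e-14 or m24 < 1e-14:
        return 0.0  # segments touch: degenerate pair contributes nothing
    u1x = r13x / m13; u1y = r13y / m13; u1z = r13z / m13
    u2x = r14x / m14; u2y = r14y / m14; u2z = r14z / m14
    u3x = r24x / m24; u3y = r24y / m24; u3z = r24z / m24
    u4x = r23x / m23; u4y = r23y / m23; u4z = r23z / m23

    return -(_tri_solid_angle(u1x, u1y, u1z, u2x, u2y, u2z,
                              u3x, u3y, u3z)
             + _tri_solid_angle(u1x, u1y, u1z, u3x, u3y, u3z,
                                u4x, u4y, u4z))


@njit(cache=True)
def _polygon_writhe(verts, closed):
    """Writhe of a polygonal curve: Gauss double sum over non-adjacent
    segment pairs (adjacent pairs share a vertex, hence are coplanar and
    contribute exactly zero)."""
    n = verts.shape[0]
    if closed:
        nseg = n
    else:
        nseg = n - 1
    total = 0.0
    for i in range(nseg - 1):
        i2 = i + 1
        if i2 == n:
            i2 = 0
        for j in range(i + 1, nseg):
            if j == i + 1:
                continue
            if closed and i == 0 and j == nseg - 1:
                continue
            j2 = j + 1
            if j2 == n:
                j2 = 0
            total += _pair_solid_angle(
                verts[i, 0], verts[i, 1], verts[i, 2],
                verts[i2, 0], verts[i2, 1], verts[i2, 2],
                verts[j, 0], verts[j, 1], verts[j, 2],
                verts[j2, 0], verts[j2, 1], verts[j2, 2])
    return total / (2.0 * np.pi)
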