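"""Numba kernels for force evaluation and time integration.

The scalar interaction laws implemented here mirror the reference
implementations in :mod:`fibrilmd.forcefield`; the two routes are held
equal by tests.  All kernels work on packed plain arrays; unit bookkeeping
(kcal/mol, Å, fs, amu) is handled by the single conversion constant
``ACCEL`` = 4.184e-4 (amu Å² fs⁻² per kcal/mol).

Bond state codes: 0 intact, 1 broken (passed ``r_break`` at least once,
still force-bearing by the trilinear law), 2 dead (passed ``r_break + a``;
permanently removed from force evaluation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

ACCEL = 4.184e-4

# run_block status codes
OK = 0
NEIGHBOR_OVERFLOW = 1
STEP_TOO_LARGE = 2
NONFINITE = 3


@njit(cache=True, fastmath=True)
def _bond_scalar_force(r, r0, r1, rb, k0, k1, a):
    """Tension of the trilinear law (positive pulls beads together)."""
    if r < r1:
        return k0 * (r - r0)
    fp = k0 * (r1 - r0) + k1 * (rb - r1)
    if r < rb:
        return k0 * (r1 - r0) + k1 * (r - r1)
    if r < rb + a:
        return fp * (1.0 - (r - rb) / a)
    return 0.0


@njit(cache=True, fastmath=True)
def _bond_scalar_energy(r, r0, r1, rb, k0, k1, a):
    f1 = k0 * (r1 - r0)
    fp = f1 + k1 * (rb - r1)
    e_r1 = 0.5 * k0 * (r1 - r0) ** 2
    d2 = rb - r1
    e_rb = e_r1 + f1 * d2 + 0.5 * k1 * d2 * d2
    if r < r1:
        return 0.5 * k0 * (r - r0) ** 2
    if r < rb:
        d = r - r1
        return e_r1 + f1 * d + 0.5 * k1 * d * d
    if r < rb + a:
        d = r - rb
        return e_rb + fp * d - 0.5 * fp * d * d / a
    return e_rb + 0.5 * fp * a


@njit(cache=True)
def build_neighbors(pos, rlist2, excl_keys, pair_i, pair_j):
    """O(N²) Verlet-list build skipping excluded (bonded) pairs.

    Returns the pair count, or -1 if capacity was exceeded.
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    cnt = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2:
                key = i * n + j
                # binary search in sorted exclusion keys
                lo = 0
                hi = excl_keys.shape[0]
                found = False
                while lo < hi:
                    mid = (lo + hi) // 2
                    k = excl_keys[mid]
                    if k == key:
                        found = True
                        break
                    elif k < key:
                        lo = mid + 1
                    else:
                        hi = mid
                if found:
                    continue
                if cnt >= cap:
                    return -1
                pair_i[cnt] = i
                pair_j[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def compute_forces(
    pos,
    forces,
    bonds,
    bspec,
    bstate,
    b_r0,
    b_r1,
    b_rb,
    b_k0,
    b_k1,
    b_a,
    angles,
    phi0_rad,
    kb_eff,
    eps,
    sig,
    r_core,
    f_core,
    e_core,
    rc2,
    e_shift,
    pair_i,
    pair_j,
    n_pairs,
    step,
    ev_step,
    ev_bond,
    ev_r,
    ev_n,
):
    """Fill ``forces`` (kcal mol⁻¹ Å⁻¹); returns (E_bond, E_angle, E_pair).

    Bond rupture bookkeeping is fused into the bond loop: a bond is flagged
    broken (state 1, one event recorded) at its first crossing of
    ``r_break`` and retired (state 2, no force) beyond ``r_break + a``.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    e_bond = 0.0
    for b in range(bonds.shape[0]):
        s = bspec[b]
        if bstate[b] == 2:
            e_bond += _bond_scalar_energy(
                b_rb[s] + b_a[s] + 1.0, b_r0[s], b_r1[s], b_rb[s], b_k0[s], b_k1[s], b_a[s]
            )
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        # rupture bookkeeping
        if r >= b_rb[s]:
            if bstate[b] == 0:
                bstate[b] = 1
                k = ev_n[0]
                if k < ev_step.shape[0]:
                    ev_step[k] = step
                    ev_bond[k] = b
                    ev_r[k] = r
                    ev_n[0] = k + 1
            if r >= b_rb[s] + b_a[s]:
                bstate[b] = 2
                e_bond += _bond_scalar_energy(
                    r, b_r0[s], b_r1[s], b_rb[s], b_k0[s], b_k1[s], b_a[s]
                )
                continue
        f = _bond_scalar_force(r, b_r0[s], b_r1[s], b_rb[s], b_k0[s], b_k1[s], b_a[s])
        e_bond += _bond_scalar_energy(
            r, b_r0[s], b_r1[s], b_rb[s], b_k0[s], b_k1[s], b_a[s]
        )
        if r > 0.0:
            f_over_r = f / r
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz

    e_angle = 0.0
    for t in range(angles.shape[0]):
        i1 = angles[t, 0]
        i2 = angles[t, 1]
        i3 = angles[t, 2]
        d1x = pos[i1, 0] - pos[i2, 0]
        d1y = pos[i1, 1] - pos[i2, 1]
        d1z = pos[i1, 2] - pos[i2, 2]
        d2x = pos[i3, 0] - pos[i2, 0]
        d2y = pos[i3, 1] - pos[i2, 1]
        d2z = pos[i3, 2] - pos[i2, 2]
        rsq1 = d1x * d1x + d1y * d1y + d1z * d1z
        rsq2 = d2x * d2x + d2y * d2y + d2z * d2z
        r1 = np.sqrt(rsq1)
        r2 = np.sqrt(rsq2)
        c = (d1x * d2x + d1y * d2y + d1z * d2z) / (r1 * r2)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        s2 = np.sqrt(1.0 - c * c)
        if s2 < 1e-8:
            s2 = 1e-8
        dtheta = np.arccos(c) - phi0_rad[t]
        e_angle += kb_eff * dtheta * dtheta
        aa = -2.0 * kb_eff * dtheta / s2
        a11 = aa * c / rsq1
        a12 = -aa / (r1 * r2)
        a22 = aa * c / rsq2
        f1x = a11 * d1x + a12 * d2x
        f1y = a11 * d1y + a12 * d2y
        f1z = a11 * d1z + a12 * d2z
        f3x = a22 * d2x + a12 * d1x
        f3y = a22 * d2y + a12 * d1y
        f3z = a22 * d2z + a12 * d1z
        forces[i1, 0] += f1x
        forces[i1, 1] += f1y
        forces[i1, 2] += f1z
        forces[i3, 0] += f3x
        forces[i3, 1] += f3y
        forces[i3, 2] += f3z
        forces[i2, 0] -= f1x + f3x
        forces[i2, 1] -= f1y + f3y
        forces[i2, 2] -= f1z + f3z

    e_pair = 0.0
    sig2 = sig * sig
    core2 = r_core * r_core
    c48 = 48.0 * eps
    c24 = 24.0 * eps
    c4 = 4.0 * eps
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < core2:
            # soft core: constant repulsive force magnitude below λσ
            r = np.sqrt(r2)
            f_over_r = f_core / r
            e_pair += e_core + f_core * (r_core - r)
        else:
            inv_r2 = 1.0 / r2
            sr2 = sig2 * inv_r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            f_over_r = (c48 * sr12 - c24 * sr6) * inv_r2
            e_pair += c4 * (sr12 - sr6) - e_shift
        # positive = repulsive: push i and j apart
        fx = f_over_r * dx
        fy = f_over_r * dy
        fz = f_over_r * dz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz

    return e_bond, e_angle, e_pair


@njit(cache=True, fastmath=True)
def run_block(
    pos,
    vel,
    masses,
    clamp_member,
    clamp_vx,
    bonds,
    bspec,
    bstate,
    b_r0,
    b_r1,
    b_rb,
    b_k0,
    b_k1,
    b_a,
    angles,
    phi0_rad,
    kb_eff,
    eps,
    sig,
    r_core,
    f_core,
    e_core,
    rc2,
    e_shift,
    excl_keys,
    pair_i,
    pair_j,
    n_pairs_arr,
    ref_pos,
    rlist2,
    skin,
    forces,
    dt,
    gamma,
    kbt_u,
    thermostat_interval,
    seed,
    n_steps,
    step0,
    ev_step,
    ev_bond,
    ev_r,
    ev_n,
    steps_done,
    chain_id,
    n_chains,
    streaming,
):
    """Advance ``n_steps`` of Langevin velocity-Verlet dynamics.

    Clamp members (clamp_member ≥ 0) move kinematically at the prescribed
    axial speed of their group and are excluded from the thermostat.  With
    ``streaming`` set (steered pulling), the axial component is damped
    relative to the mean axial velocity of each bonded chain
    (profile-unbiased thermostat), so rigid chain advection with the clamps
    incurs no spurious friction load.
    Returns a status code; ``steps_done[0]`` reports progress on early exit.
    """
    n = pos.shape[0]
    np.random.seed(seed)
    half = 0.5 * dt * ACCEL
    c1 = np.exp(-gamma * dt * thermostat_interval)
    c2 = np.sqrt(1.0 - c1 * c1)
    half_skin2 = (0.5 * skin) ** 2
    check_interval = 8

    for step in range(n_steps):
        # kick (half) + drift
        for i in range(n):
            g = clamp_member[i]
            if g < 0:
                inv = half / masses[i]
                vel[i, 0] += forces[i, 0] * inv
                vel[i, 1] += forces[i, 1] * inv
                vel[i, 2] += forces[i, 2] * inv
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
                pos[i, 2] += dt * vel[i, 2]
            else:
                vel[i, 0] = clamp_vx[g]
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                pos[i, 0] += dt * clamp_vx[g]

        # neighbor-list health: rebuild when displacement approaches the skin
        if step % check_interval == 0 or step == n_steps - 1:
            max_d2 = 0.0
            for i in range(n):
                dx = pos[i, 0] - ref_pos[i, 0]
                dy = pos[i, 1] - ref_pos[i, 1]
                dz = pos[i, 2] - ref_pos[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > max_d2:
                    max_d2 = d2
            if not np.isfinite(max_d2):
                steps_done[0] = step + 1
                return NONFINITE
            if max_d2 > 0.49 * half_skin2:
                cnt = build_neighbors(pos, rlist2, excl_keys, pair_i, pair_j)
                if cnt < 0:
                    steps_done[0] = step
                    return NEIGHBOR_OVERFLOW
                n_pairs_arr[0] = cnt
                for i in range(n):
                    ref_pos[i, 0] = pos[i, 0]
                    ref_pos[i, 1] = pos[i, 1]
                    ref_pos[i, 2] = pos[i, 2]

        compute_forces(
            pos, forces, bonds, bspec, bstate,
            b_r0, b_r1, b_rb, b_k0, b_k1, b_a,
            angles, phi0_rad, kb_eff,
            eps, sig, r_core, f_core, e_core, rc2, e_shift,
            pair_i, pair_j, n_pairs_arr[0],
            step0 + step, ev_step, ev_bond, ev_r, ev_n,
        )

        # kick (half); track the fastest bead for the timestep guard
        vmax2 = 0.0
        for i in range(n):
            if clamp_member[i] < 0:
                inv = half / masses[i]
                vel[i, 0] += forces[i, 0] * inv
                vel[i, 1] += forces[i, 1] * inv
                vel[i, 2] += forces[i, 2] * inv
                v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                if v2 > vmax2:
                    vmax2 = v2
        if vmax2 * dt * dt > half_skin2:
            steps_done[0] = step + 1
            return STEP_TOO_LARGE

        if gamma > 0.0 and (step % thermostat_interval) == (thermostat_interval - 1):
            if streaming:
                mean_vx = np.zeros(n_chains)
                cnt_c = np.zeros(n_chains)
                for i in range(n):
                    c = chain_id[i]
                    mean_vx[c] += vel[i, 0]
                    cnt_c[c] += 1.0
                for c in range(n_chains):
                    if cnt_c[c] > 0.0:
                        mean_vx[c] /= cnt_c[c]
            for i in range(n):
                if clamp_member[i] < 0:
                    sd = np.sqrt(kbt_u / masses[i])
                    if streaming:
                        u = mean_vx[chain_id[i]]
                        vel[i, 0] = u + c1 * (vel[i, 0] - u) + c2 * sd * np.random.standard_normal()
                    else:
                        vel[i, 0] = c1 * vel[i, 0] + c2 * sd * np.random.standard_normal()
                    vel[i, 1] = c1 * vel[i, 1] + c2 * sd * np.random.standard_normal()
                    vel[i, 2] = c1 * vel[i, 2] + c2 * sd * np.random.standard_normal()

    steps_done[0] = n_steps
    return OK
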