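"""Numba kernels: potentials, BAOAB Langevin loops, path-CV evaluation.

Everything here works on plain float64 arrays in package units
(kcal mol⁻¹, Å, ps, amu).  Masses entering the equations of motion are the
*effective* masses ``m_amu * MASS_TO_KCAL`` so that forces in
kcal mol⁻¹ Å⁻¹ directly give accelerations in Å ps⁻².

All stochastic kernels draw noise through the shared numba RNG state, one
``(N, 3)`` block per step in a fixed order, so that any two kernels given
the same seed and step count consume identical streams (this is what makes
the zero-rate metadynamics run bit-identical to the plain Langevin run).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# RNG helpers (shared numba-global stream)
# ---------------------------------------------------------------------------


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def draw_normal_block(n):
    out = np.empty((n, 3))
    for i in range(n):
        for j in range(3):
            out[i, j] = np.random.normal(0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Smooth switching primitives
# ---------------------------------------------------------------------------


@njit(cache=False, inline="always")
def _sstep(u):
    """Cubic smoothstep and its derivative; 0 below 0, 1 above 1."""
    if u <= 0.0:
        return 0.0, 0.0
    if u >= 1.0:
        return 1.0, 0.0
    return u * u * (3.0 - 2.0 * u), 6.0 * u * (1.0 - u)


@njit(cache=False, inline="always")
def _smax(u, w):
    """Smooth max(u, 0) with width w, and its derivative."""
    r = math.sqrt(u * u + w * w)
    return 0.5 * (u + r), 0.5 * (1.0 + u / r)


# ---------------------------------------------------------------------------
# Potential kernels: signature (coords, fargs, iargs, grad_out) -> energy
# ---------------------------------------------------------------------------


@njit(cache=False)
def dw1d_eg(coords, fargs, iargs, grad):
    """Quartic double well in x of atom 0; harmonic confinement in y, z.

    fargs = [barrier, separation, k_transverse]
    """
    b = fargs[0]
    sep = fargs[1]
    kt_ = fargs[2]
    grad[:] = 0.0
    x = coords[0, 0]
    y = coords[0, 1]
    z = coords[0, 2]
    u = (2.0 * x / sep) ** 2 - 1.0
    e = b * u * u + 0.5 * kt_ * (y * y + z * z)
    grad[0, 0] = b * 2.0 * u * (8.0 * x / (sep * sep))
    grad[0, 1] = kt_ * y
    grad[0, 2] = kt_ * z
    return e


@njit(cache=False)
def harmonic_eg(coords, fargs, iargs, grad):
    """Isotropic harmonic wells: fargs = [k, x0,y0,z0 per atom...]."""
    k = fargs[0]
    e = 0.0
    for i in range(coords.shape[0]):
        for c in range(3):
            d = coords[i, c] - fargs[1 + 3 * i + c]
            e += 0.5 * k * d * d
            grad[i, c] = k * d
    return e


@njit(cache=False)
def linear_eg(coords, fargs, iargs, grad):
    """Constant slope g along x of atom 0, transverse confinement k_t."""
    g = fargs[0]
    kt_ = fargs[1]
    grad[:] = 0.0
    y = coords[0, 1]
    z = coords[0, 2]
    e = g * coords[0, 0] + 0.5 * kt_ * (y * y + z * z)
    grad[0, 0] = g
    grad[0, 1] = kt_ * y
    grad[0, 2] = kt_ * z
    return e


# fargs layout for the funnel-pocket kernel (scalar block):
_POCKET_SCALARS = 21  # then 3*n_ref tether sites, then ligand bond lengths


@njit(cache=False)
def pocket_eg(coords, fargs, iargs, grad):
    """Funnel-pocket many-body potential.

    Atom ordering: [ligand (n_lig) | reference cage (n_ref) | solvent].
    iargs = [n_lig, n_ref, n_sol, backdoor]
    fargs = [k_int, depth, sigma_well, R_shell, wall_w, k_wall,
             cos_mouth, cos_back, dcos, eps_wca, sigma_wca, R_cont,
             k_funnel, rho_cyl, z_cap, z_cone, k_tether, rho_pocket,
             z_floor, rho_bulk, tether sites (3*n_ref), ligand pair rest
             lengths]

    The ligand is confined to a cleft-shaped region: lateral radius
    rho_pocket inside the pocket, narrowing smoothly to rho_cyl at the
    mouth (z = z_cone), re-widening to rho_bulk in the solvent vestibule
    beyond it, with a floor at z_floor and a cap at z_cap.
    """
    n = coords.shape[0]
    n_lig = iargs[0]
    n_ref = iargs[1]
    backdoor = iargs[3]
    k_int = fargs[0]
    depth = fargs[1]
    sw = fargs[2]
    r_shell = fargs[3]
    wall_w = fargs[4]
    k_wall = fargs[5]
    cos_m = fargs[6]
    cos_b = fargs[7]
    dcos = fargs[8]
    eps = fargs[9]
    sig = fargs[10]
    r_cont = fargs[11]
    k_fun = fargs[12]
    rho_cyl = fargs[13]
    z_cap = fargs[14]
    z_cone = fargs[15]
    k_teth = fargs[16]
    rho_pocket = fargs[17]
    z_floor = fargs[18]
    rho_bulk = fargs[19]
    cos_m_sol = fargs[20]  # solvent sees a narrower mouth than the ligand
    off_teth = _POCKET_SCALARS
    off_bond = off_teth + 3 * n_ref

    grad[:] = 0.0
    e = 0.0

    # --- rigid-ish ligand: stiff harmonic bonds between all ligand pairs
    b = 0
    for i in range(n_lig):
        for j in range(i + 1, n_lig):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            r0 = fargs[off_bond + b]
            b += 1
            e += 0.5 * k_int * (r - r0) ** 2
            f = k_int * (r - r0) / r
            grad[i, 0] += f * dx
            grad[i, 1] += f * dy
            grad[i, 2] += f * dz
            grad[j, 0] -= f * dx
            grad[j, 1] -= f * dy
            grad[j, 2] -= f * dz

    # --- Gaussian binding well acting on the ligand centroid
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(n_lig):
        cx += coords[i, 0]
        cy += coords[i, 1]
        cz += coords[i, 2]
    cx /= n_lig
    cy /= n_lig
    cz /= n_lig
    q = (cx * cx + cy * cy + cz * cz) / (2.0 * sw * sw)
    gauss = math.exp(-q)
    e += -depth * gauss
    pref = depth * gauss / (sw * sw) / n_lig
    for i in range(n_lig):
        grad[i, 0] += pref * cx
        grad[i, 1] += pref * cy
        grad[i, 2] += pref * cz

    # --- per-atom walls
    for i in range(n):
        is_lig = i < n_lig
        is_ref = (i >= n_lig) and (i < n_lig + n_ref)
        is_sol = i >= n_lig + n_ref
        x = coords[i, 0]
        y = coords[i, 1]
        z = coords[i, 2]
        if is_ref:
            k = i - n_lig
            dx = x - fargs[off_teth + 3 * k]
            dy = y - fargs[off_teth + 3 * k + 1]
            dz = z - fargs[off_teth + 3 * k + 2]
            e += 0.5 * k_teth * (dx * dx + dy * dy + dz * dz)
            grad[i, 0] += k_teth * dx
            grad[i, 1] += k_teth * dy
            grad[i, 2] += k_teth * dz
            continue
        r = math.sqrt(x * x + y * y + z * z)
        # spherical shell wall with cone openings
        d = r - r_shell
        ad = abs(d)
        if ad < wall_w and r > 1e-9:
            base = k_wall * (wall_w - ad) ** 2
            dbase_dr = -2.0 * k_wall * (wall_w - ad) * (1.0 if d > 0.0 else -1.0)
            c = z / r
            cm_eff = cos_m if is_lig else cos_m_sol
            mm, dmm_du = _sstep((cm_eff - c) / dcos)
            dmm_dc = -dmm_du / dcos
            if backdoor == 1 and is_sol:
                mb, dmb_du = _sstep((c + cos_b) / dcos)
                dmb_dc = dmb_du / dcos
            else:
                mb = 1.0
                dmb_dc = 0.0
            mask = mm * mb
            dmask_dc = dmm_dc * mb + mm * dmb_dc
            e += base * mask
            for cc in range(3):
                xc = coords[i, cc]
                dr_dx = xc / r
                dc_dx = ((1.0 if cc == 2 else 0.0) - c * dr_dx) / r
                grad[i, cc] += dbase_dr * mask * dr_dx + base * dmask_dc * dc_dx
        if is_sol and r > r_cont:
            e += 0.5 * k_wall * (r - r_cont) ** 2
            f = k_wall * (r - r_cont) / r
            grad[i, 0] += f * x
            grad[i, 1] += f * y
            grad[i, 2] += f * z
        if is_lig:
            # cleft: allowed lateral radius widens from rho_cyl at the
            # mouth (z >= z_cone) to rho_pocket inside the pocket
            u = (z_cone - z) / z_cone
            su, dsu_du = _sstep(u)
            u2 = (z - z_cone) / 1.5
            su2, dsu2_du = _sstep(u2)
            rho_max = (
                rho_cyl
                + (rho_pocket - rho_cyl) * su
                + (rho_bulk - rho_cyl) * su2
            )
            drho_max_dz = (
                -(rho_pocket - rho_cyl) * dsu_du / z_cone
                + (rho_bulk - rho_cyl) * dsu2_du / 1.5
            )
            rho = math.sqrt(x * x + y * y)
            p, dp = _smax(rho - rho_max, 0.3)
            e += 0.5 * k_fun * p * p
            fp = k_fun * p * dp
            if rho > 1e-9:
                grad[i, 0] += fp * x / rho
                grad[i, 1] += fp * y / rho
            grad[i, 2] += -fp * drho_max_dz
            if z > z_cap:
                e += 0.5 * k_wall * (z - z_cap) ** 2
                grad[i, 2] += k_wall * (z - z_cap)
            if z < z_floor:
                e += 0.5 * k_wall * (z - z_floor) ** 2
                grad[i, 2] += k_wall * (z - z_floor)

    # --- WCA repulsion: solvent-solvent and solvent-ligand
    rc2 = 2.0 ** (1.0 / 3.0) * sig * sig
    for i in range(n_lig + n_ref, n):
        for j in range(i):
            if n_lig <= j < n_lig + n_ref:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 1e-12:
                sr2 = sig * sig / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                e += 4.0 * eps * (sr12 - sr6) + eps
                f = 24.0 * eps * (2.0 * sr12 - sr6) / r2  # repulsive magnitude / r
                grad[i, 0] -= f * dx
                grad[i, 1] -= f * dy
                grad[i, 2] -= f * dz
                grad[j, 0] += f * dx
                grad[j, 1] += f * dy
                grad[j, 2] += f * dz
    return e


# ---------------------------------------------------------------------------
# BAOAB Langevin integrator pieces
# ---------------------------------------------------------------------------


@njit(cache=False, inline="always")
def _kick(v, g, meff, half_dt):
    for i in range(v.shape[0]):
        for c in range(3):
            v[i, c] -= half_dt * g[i, c] / meff[i]


@njit(cache=False, inline="always")
def _drift(x, v, half_dt):
    for i in range(x.shape[0]):
        for c in range(3):
            x[i, c] += half_dt * v[i, c]


@njit(cache=False, inline="always")
def _ou(v, meff, kT, c1, c2):
    noise = draw_normal_block(v.shape[0])
    for i in range(v.shape[0]):
        sd = math.sqrt(kT / meff[i])
        for c in range(3):
            v[i, c] = c1 * v[i, c] + c2 * sd * noise[i, c]


@njit(cache=False)
def baoab_run(
    grad_fn,
    fargs,
    iargs,
    x,
    v,
    meff,
    kT,
    gamma,
    dt,
    nsteps,
    save_stride,
    xs_out,
):
    """Plain BAOAB run; x, v updated in place, frames saved every stride.

    Returns the number of saved frames, or -(step+1) on non-finite energy.
    """
    n = x.shape[0]
    g = np.zeros((n, 3))
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    e = grad_fn(x, fargs, iargs, g)
    nsaved = 0
    for step in range(nsteps):
        _kick(v, g, meff, 0.5 * dt)
        _drift(x, v, 0.5 * dt)
        _ou(v, meff, kT, c1, c2)
        _drift(x, v, 0.5 * dt)
        e = grad_fn(x, fargs, iargs, g)
        if not math.isfinite(e):
            return -(step + 1)
        _kick(v, g, meff, 0.5 * dt)
        if (step + 1) % save_stride == 0:
            for i in range(n):
                for c in range(3):
                    xs_out[nsaved, i, c] = x[i, c]
            nsaved += 1
    return nsaved


@njit(cache=False)
def potential_energy_series(grad_fn, fargs, iargs, xs):
    out = np.empty(xs.shape[0])
    g = np.zeros((xs.shape[1], 3))
    for k in range(xs.shape[0]):
        out[k] = grad_fn(xs[k], fargs, iargs, g)
    return out


# ---------------------------------------------------------------------------
# Steered runs: moving harmonic restraint on a COM-COM distance
# ---------------------------------------------------------------------------


@njit(cache=False, inline="always")
def _com(x, meff, idx):
    cx = 0.0
    cy = 0.0
    cz = 0.0
    m = 0.0
    for k in range(idx.shape[0]):
        i = idx[k]
        cx += meff[i] * x[i, 0]
        cy += meff[i] * x[i, 1]
        cz += meff[i] * x[i, 2]
        m += meff[i]
    return cx / m, cy / m, cz / m, m


@njit(cache=False)
def smd_run(
    grad_fn,
    fargs,
    iargs,
    x,
    v,
    meff,
    kT,
    gamma,
    dt,
    nsteps,
    ga,
    gb,
    anchor,
    kspring,
    speed,
    xi0_in,
    record_stride,
    t_out,
    xi_out,
    center_out,
    force_out,
    work_out,
    xs_out,
    save_stride,
):
    """Constant-velocity steered BAOAB run.

    The guide is U = 0.5*k*(xi - xi0 - v*t)^2 with xi the mass-weighted
    COM distance between groups ga and gb.  Work is accumulated by the
    trapezoid rule on the integration grid (stride 1).  Records are taken
    every ``record_stride`` steps (plus the initial state in row 0).
    Returns (n_records, n_saved_frames) or (-(step+1), 0) on divergence.
    """
    n = x.shape[0]
    g = np.zeros((n, 3))
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))

    ax, ay, az, ma = _com(x, meff, ga)
    if gb.shape[0] > 0:
        bx, by, bz, mb = _com(x, meff, gb)
    else:
        bx, by, bz, mb = anchor[0], anchor[1], anchor[2], 1.0
    xi_meas = math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)
    if xi_meas < 1e-9:
        return -1, 0
    xi0 = xi0_in if xi0_in >= 0.0 else xi_meas

    e = grad_fn(x, fargs, iargs, g)
    f_prev = kspring * (xi0 - xi_meas)
    # fold the t=0 restraint force into the startup gradient
    ux0 = (ax - bx) / xi_meas
    uy0 = (ay - by) / xi_meas
    uz0 = (az - bz) / xi_meas
    for k in range(ga.shape[0]):
        i = ga[k]
        w = meff[i] / ma
        g[i, 0] -= f_prev * w * ux0
        g[i, 1] -= f_prev * w * uy0
        g[i, 2] -= f_prev * w * uz0
    for k in range(gb.shape[0]):
        i = gb[k]
        w = meff[i] / mb
        g[i, 0] += f_prev * w * ux0
        g[i, 1] += f_prev * w * uy0
        g[i, 2] += f_prev * w * uz0
    t_out[0] = 0.0
    xi_out[0] = xi_meas
    center_out[0] = xi0
    force_out[0] = f_prev
    work_out[0] = 0.0
    nrec = 1
    nsaved = 0
    work = 0.0
    for step in range(nsteps):
        _kick(v, g, meff, 0.5 * dt)
        _drift(x, v, 0.5 * dt)
        _ou(v, meff, kT, c1, c2)
        _drift(x, v, 0.5 * dt)
        e = grad_fn(x, fargs, iargs, g)
        if not math.isfinite(e):
            return -(step + 1), nsaved
        t = (step + 1) * dt
        center = xi0 + speed * t
        ax, ay, az, ma = _com(x, meff, ga)
        if gb.shape[0] > 0:
            bx, by, bz, mb = _com(x, meff, gb)
        else:
            bx, by, bz, mb = anchor[0], anchor[1], anchor[2], 1.0
        ux = ax - bx
        uy = ay - by
        uz = az - bz
        xi = math.sqrt(ux * ux + uy * uy + uz * uz)
        if xi < 1e-9:
            return -(step + 1), nsaved
        ux /= xi
        uy /= xi
        uz /= xi
        fmag = kspring * (center - xi)  # applied force along +xi on group a
        for k in range(ga.shape[0]):
            i = ga[k]
            w = meff[i] / ma
            g[i, 0] -= fmag * w * ux
            g[i, 1] -= fmag * w * uy
            g[i, 2] -= fmag * w * uz
        for k in range(gb.shape[0]):
            i = gb[k]
            w = meff[i] / mb
            g[i, 0] += fmag * w * ux
            g[i, 1] += fmag * w * uy
            g[i, 2] += fmag * w * uz
        work += 0.5 * (f_prev + fmag) * speed * dt
        f_prev = fmag
        _kick(v, g, meff, 0.5 * dt)
        if (step + 1) % record_stride == 0:
            t_out[nrec] = t
            xi_out[nrec] = xi
            center_out[nrec] = center
            force_out[nrec] = fmag
            work_out[nrec] = work
            nrec += 1
        if save_stride > 0 and (step + 1) % save_stride == 0:
            for i in range(n):
                for c in range(3):
                    xs_out[nsaved, i, c] = x[i, c]
            nsaved += 1
    return nrec, nsaved


# ---------------------------------------------------------------------------
# Kearsley superposition (fixed-size Jacobi eigensolver, jit-friendly)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _jacobi4_min_eigvec(a):
    """Eigenvector of the smallest eigenvalue of a symmetric 4x4 matrix."""
    v = np.eye(4)
    for _ in range(16):
        off = 0.0
        for p in range(3):
            for q in range(p + 1, 4):
                off += abs(a[p, q])
        if off < 1e-15:
            break
        for p in range(3):
            for q in range(p + 1, 4):
                apq = a[p, q]
                if abs(apq) < 1e-18:
                    continue
                theta = (a[q, q] - a[p, p]) / (2.0 * apq)
                t = (1.0 if theta >= 0.0 else -1.0) / (
                    abs(theta) + math.sqrt(theta * theta + 1.0)
                )
                c = 1.0 / math.sqrt(t * t + 1.0)
                s = t * c
                for k in range(4):
                    akp = a[k, p]
                    akq = a[k, q]
                    a[k, p] = c * akp - s * akq
                    a[k, q] = s * akp + c * akq
                for k in range(4):
                    apk = a[p, k]
                    aqk = a[q, k]
                    a[p, k] = c * apk - s * aqk
                    a[q, k] = s * apk + c * aqk
                for k in range(4):
                    vkp = v[k, p]
                    vkq = v[k, q]
                    v[k, p] = c * vkp - s * vkq
                    v[k, q] = s * vkp + c * vkq
    imin = 0
    emin = a[0, 0]
    for k in range(1, 4):
        if a[k, k] < emin:
            emin = a[k, k]
            imin = k
    out = np.empty(4)
    for k in range(4):
        out[k] = v[k, imin]
    return out


@njit(cache=False)
def kearsley_build(mob, ref, kmat):
    """Fill the 4x4 Kearsley matrix for centered coordinate sets."""
    kmat[:] = 0.0
    for i in range(mob.shape[0]):
        dx = mob[i, 0] - ref[i, 0]
        dy = mob[i, 1] - ref[i, 1]
        dz = mob[i, 2] - ref[i, 2]
        sx = mob[i, 0] + ref[i, 0]
        sy = mob[i, 1] + ref[i, 1]
        sz = mob[i, 2] + ref[i, 2]
        kmat[0, 0] += dx * dx + dy * dy + dz * dz
        kmat[1, 1] += dx * dx + sy * sy + sz * sz
        kmat[2, 2] += sx * sx + dy * dy + sz * sz
        kmat[3, 3] += sx * sx + sy * sy + dz * dz
        kmat[0, 1] += sy * dz - sz * dy
        kmat[0, 2] += sz * dx - sx * dz
        kmat[0, 3] += sx * dy - sy * dx
        kmat[1, 2] += dx * dy - sx * sy
        kmat[1, 3] += dx * dz - sx * sz
        kmat[2, 3] += dy * dz - sy * sz
    kmat[1, 0] = kmat[0, 1]
    kmat[2, 0] = kmat[0, 2]
    kmat[3, 0] = kmat[0, 3]
    kmat[2, 1] = kmat[1, 2]
    kmat[3, 1] = kmat[1, 3]
    kmat[3, 2] = kmat[2, 3]


@njit(cache=False)
def quat_to_rot(q, rot):
    """Kearsley rotation matrix: rot @ centered_mobile ≈ centered_reference."""
    q1, q2, q3, q4 = q[0], q[1], q[2], q[3]
    rot[0, 0] = q1 * q1 + q2 * q2 - q3 * q3 - q4 * q4
    rot[1, 0] = 2.0 * (q2 * q3 + q1 * q4)
    rot[2, 0] = 2.0 * (q2 * q4 - q1 * q3)
    rot[0, 1] = 2.0 * (q2 * q3 - q1 * q4)
    rot[1, 1] = q1 * q1 + q3 * q3 - q2 * q2 - q4 * q4
    rot[2, 1] = 2.0 * (q3 * q4 + q1 * q2)
    rot[0, 2] = 2.0 * (q2 * q4 + q1 * q3)
    rot[1, 2] = 2.0 * (q3 * q4 - q1 * q2)
    rot[2, 2] = q1 * q1 + q4 * q4 - q2 * q2 - q3 * q3


@njit(cache=False)
def superpose_transform(x, ref, align_idx):
    """Optimal rigid transform of x onto ref over align_idx.

    Returns (rot, cm, cr): rot @ (p - cm) + cr maps mobile points onto the
    reference frame.
    """
    na = align_idx.shape[0]
    mob = np.empty((na, 3))
    rfa = np.empty((na, 3))
    cm = np.zeros(3)
    cr = np.zeros(3)
    for k in range(na):
        i = align_idx[k]
        for c in range(3):
            mob[k, c] = x[i, c]
            rfa[k, c] = ref[i, c]
            cm[c] += x[i, c]
            cr[c] += ref[i, c]
    for c in range(3):
        cm[c] /= na
        cr[c] /= na
    for k in range(na):
        for c in range(3):
            mob[k, c] -= cm[c]
            rfa[k, c] -= cr[c]
    kmat = np.empty((4, 4))
    kearsley_build(mob, rfa, kmat)
    q = _jacobi4_min_eigvec(kmat)
    rot = np.empty((3, 3))
    quat_to_rot(q, rot)
    return rot, cm, cr


@njit(cache=False)
def msd_after_fit(x, ref, align_idx, disp_idx):
    """MSD (Å²) over disp_idx after least-squares fit on align_idx."""
    rot, cm, cr = superpose_transform(x, ref, align_idx)
    nd = disp_idx.shape[0]
    acc = 0.0
    for k in range(nd):
        i = disp_idx[k]
        for c in range(3):
            r = (
                rot[c, 0] * (x[i, 0] - cm[0])
                + rot[c, 1] * (x[i, 1] - cm[1])
                + rot[c, 2] * (x[i, 2] - cm[2])
                + cr[c]
                - ref[i, c]
            )
            acc += r * r
    return acc / nd


@njit(cache=False)
def pathcv_eval(x, frames, align_idx, disp_idx, lam, ds_dx, dz_dx):
    """Path collective variables S, Z of configuration x w.r.t. a frameset.

    S is 1-indexed (S in [1, P]); Z in Å².  Gradients (w.r.t. the
    displacement atoms, optimal rotations treated as fixed) are written
    into ds_dx / dz_dx, which must be zeroed (N, 3) arrays.
    Evaluated in log-sum-exp form; never under/overflows.
    """
    p_tot = frames.shape[0]
    nd = disp_idx.shape[0]
    d_arr = np.empty(p_tot)
    resid = np.empty((p_tot, nd, 3))  # rot^T (fitted - ref), in mobile frame
    for p in range(p_tot):
        rot, cm, cr = superpose_transform(x, frames[p], align_idx)
        acc = 0.0
        for k in range(nd):
            i = disp_idx[k]
            r0 = 0.0
            r1 = 0.0
            r2 = 0.0
            for c in range(3):
                r = (
                    rot[c, 0] * (x[i, 0] - cm[0])
                    + rot[c, 1] * (x[i, 1] - cm[1])
                    + rot[c, 2] * (x[i, 2] - cm[2])
                    + cr[c]
                    - frames[p, i, c]
                )
                acc += r * r
                r0 += rot[c, 0] * r
                r1 += rot[c, 1] * r
                r2 += rot[c, 2] * r
            resid[p, k, 0] = r0
            resid[p, k, 1] = r1
            resid[p, k, 2] = r2
        d_arr[p] = acc / nd
    dmin = d_arr[0]
    for p in range(1, p_tot):
        if d_arr[p] < dmin:
            dmin = d_arr[p]
    wsum = 0.0
    swsum = 0.0
    for p in range(p_tot):
        w = math.exp(-lam * (d_arr[p] - dmin))
        wsum += w
        swsum += (p + 1) * w
    s = swsum / wsum
    z = dmin - math.log(wsum) / lam
    ds_dx[:] = 0.0
    dz_dx[:] = 0.0
    for p in range(p_tot):
        w = math.exp(-lam * (d_arr[p] - dmin)) / wsum
        cs = -lam * w * ((p + 1) - s) * (2.0 / nd)
        cz = w * (2.0 / nd)
        for k in range(nd):
            i = disp_idx[k]
            for c in range(3):
                ds_dx[i, c] += cs * resid[p, k, c]
                dz_dx[i, c] += cz * resid[p, k, c]
    return s, z


# ---------------------------------------------------------------------------
# Metadynamics: grid-accumulated bias forces + hill bookkeeping
# ---------------------------------------------------------------------------


@njit(cache=False)
def deposit_hill_grid(fs_grid, fz_grid, s0, z0, h, sig_s, sig_z, smin, ds, zmin, dz):
    """Accumulate the bias *force* (-dV/ds, -dV/dz) of one Gaussian hill."""
    ns = fs_grid.shape[0]
    nz = fs_grid.shape[1]
    i_lo = max(0, int((s0 - 5.0 * sig_s - smin) / ds))
    i_hi = min(ns, int((s0 + 5.0 * sig_s - smin) / ds) + 2)
    j_lo = max(0, int((z0 - 5.0 * sig_z - zmin) / dz))
    j_hi = min(nz, int((z0 + 5.0 * sig_z - zmin) / dz) + 2)
    for i in range(i_lo, i_hi):
        s = smin + i * ds
        es = math.exp(-((s - s0) ** 2) / (2.0 * sig_s * sig_s))
        for j in range(j_lo, j_hi):
            z = zmin + j * dz
            ez = math.exp(-((z - z0) ** 2) / (2.0 * sig_z * sig_z))
            g = h * es * ez
            fs_grid[i, j] += g * (s - s0) / (sig_s * sig_s)
            fz_grid[i, j] += g * (z - z0) / (sig_z * sig_z)


@njit(cache=False, inline="always")
def _bilinear(grid, smin, ds, zmin, dz, s, z):
    ns = grid.shape[0]
    nz = grid.shape[1]
    fi = (s - smin) / ds
    fj = (z - zmin) / dz
    if fi < 0.0 or fj < 0.0 or fi > ns - 1.001 or fj > nz - 1.001:
        return 0.0
    i = int(fi)
    j = int(fj)
    wi = fi - i
    wj = fj - j
    return (
        grid[i, j] * (1.0 - wi) * (1.0 - wj)
        + grid[i + 1, j] * wi * (1.0 - wj)
        + grid[i, j + 1] * (1.0 - wi) * wj
        + grid[i + 1, j + 1] * wi * wj
    )


@njit(cache=False)
def metad_run(
    grad_fn,
    fargs,
    iargs,
    x,
    v,
    meff,
    kT,
    gamma,
    dt,
    nsteps,
    step0,
    # CV definition: mode 0 = cartesian pair, mode 1 = path CV
    cv_mode,
    cv_atoms,  # int64[2]: atoms for cartesian (s_atom, z_atom)
    cv_axes,  # int64[2]: axes for cartesian
    frames,
    align_idx,
    disp_idx,
    lam,
    # hill parameters
    hill_h,
    stride_steps,
    sig_s,
    sig_z,
    # bias force grids (updated in place)
    smin,
    ds,
    zmin,
    dz,
    fs_grid,
    fz_grid,
    # optional harmonic upper wall on z (k <= 0 disables)
    z_wall_k,
    z_wall_at,
    # outputs
    hills_t,
    hills_s,
    hills_z,
    n_hills0,
    save_stride,
    xs_out,
    s_out,
    z_out,
):
    """One chunk of metadynamics; state (x, v, grids, hills) carried along.

    Returns (n_hills, n_saved) or (-(step+1), 0) on non-finite energy.
    The RNG stream is the shared module stream: chunking does not change
    the trajectory.
    """
    n = x.shape[0]
    g = np.zeros((n, 3))
    ds_dx = np.zeros((n, 3))
    dz_dx = np.zeros((n, 3))
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    e = grad_fn(x, fargs, iargs, g)
    n_hills = n_hills0
    nsaved = 0

    # fold the current bias into the startup force so chunking is seamless
    if cv_mode == 0:
        s = x[cv_atoms[0], cv_axes[0]]
        z = x[cv_atoms[1], cv_axes[1]]
    else:
        s, z = pathcv_eval(x, frames, align_idx, disp_idx, lam, ds_dx, dz_dx)
    fs = _bilinear(fs_grid, smin, ds, zmin, dz, s, z)
    fz = _bilinear(fz_grid, smin, ds, zmin, dz, s, z)
    if z_wall_k > 0.0 and z > z_wall_at:
        fz -= z_wall_k * (z - z_wall_at)
    if cv_mode == 0:
        g[cv_atoms[0], cv_axes[0]] -= fs
        g[cv_atoms[1], cv_axes[1]] -= fz
    else:
        for k in range(disp_idx.shape[0]):
            i = disp_idx[k]
            for c in range(3):
                g[i, c] -= fs * ds_dx[i, c] + fz * dz_dx[i, c]

    for step in range(nsteps):
        gstep = step0 + step
        _kick(v, g, meff, 0.5 * dt)
        _drift(x, v, 0.5 * dt)
        _ou(v, meff, kT, c1, c2)
        _drift(x, v, 0.5 * dt)
        e = grad_fn(x, fargs, iargs, g)
        if not math.isfinite(e):
            return -(gstep + 1), nsaved
        if cv_mode == 0:
            s = x[cv_atoms[0], cv_axes[0]]
            z = x[cv_atoms[1], cv_axes[1]]
        else:
            s, z = pathcv_eval(x, frames, align_idx, disp_idx, lam, ds_dx, dz_dx)
        # deposit first: the new hill acts from this step on, which keeps
        # the dynamics independent of how the run is chunked
        if (gstep + 1) % stride_steps == 0:
            hills_t[n_hills] = (gstep + 1) * dt
            hills_s[n_hills] = s
            hills_z[n_hills] = z
            n_hills += 1
            deposit_hill_grid(
                fs_grid, fz_grid, s, z, hill_h, sig_s, sig_z, smin, ds, zmin, dz
            )
        fs = _bilinear(fs_grid, smin, ds, zmin, dz, s, z)
        fz = _bilinear(fz_grid, smin, ds, zmin, dz, s, z)
        if z_wall_k > 0.0 and z > z_wall_at:
            fz -= z_wall_k * (z - z_wall_at)
        if cv_mode == 0:
            g[cv_atoms[0], cv_axes[0]] -= fs
            g[cv_atoms[1], cv_axes[1]] -= fz
        else:
            for k in range(disp_idx.shape[0]):
                i = disp_idx[k]
                for c in range(3):
                    g[i, c] -= fs * ds_dx[i, c] + fz * dz_dx[i, c]
        _kick(v, g, meff, 0.5 * dt)
        if (gstep + 1) % save_stride == 0:
            for i in range(n):
                for c in range(3):
                    xs_out[nsaved, i, c] = x[i, c]
            s_out[nsaved] = s
            z_out[nsaved] = z
            nsaved += 1
    return n_hills, nsaved
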