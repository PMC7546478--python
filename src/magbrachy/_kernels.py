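"""Numba transport kernels: condensed-history electrons in a uniform
magnetic field, analog Woodcock photon tracking, and the Ir-192 seed
emission/attenuation geometry.

Everything here is deliberately free of Python objects: scalar geometry,
flat arrays, and a hand-rolled splitmix64 RNG so that runs are
bit-reproducible for a given (seed, configuration) regardless of how
batches are scheduled.

Falls back to pure Python (slow, identical results) if numba is absent.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

ME = 0.51099895  # MeV
GYRO = 0.299792458  # k[1/mm] = GYRO * B[T] / pc[MeV]
RHO_VACUUM = 1e-6  # g/cm³ below which a voxel is treated as empty


# ---------------------------------------------------------------------------
# RNG: splitmix64 — small state, solid equidistribution for MC use
# ---------------------------------------------------------------------------

@njit(cache=True)
def rng_state(seed, stream):
    st = np.empty(1, dtype=np.uint64)
    z = (np.uint64(seed) + np.uint64(1)) * np.uint64(0x9E3779B97F4A7C15)
    z ^= (np.uint64(stream) + np.uint64(1)) * np.uint64(0xD1B54A32D192ED03)
    st[0] = z
    # warm up to decorrelate nearby (seed, stream) pairs
    for _ in range(4):
        _next_u64(st)
    return st


@njit(cache=True, inline="always")
def _next_u64(st):
    st[0] = st[0] + np.uint64(0x9E3779B97F4A7C15)
    z = st[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _uniform(st):
    return float(_next_u64(st) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _normal_pair(st):
    u1 = _uniform(st)
    if u1 < 1e-300:
        u1 = 1e-300
    u2 = _uniform(st)
    r = math.sqrt(-2.0 * math.log(u1))
    return r * math.cos(2.0 * math.pi * u2), r * math.sin(2.0 * math.pi * u2)


@njit(cache=True, inline="always")
def _isotropic(st):
    cz = 2.0 * _uniform(st) - 1.0
    sz = math.sqrt(max(0.0, 1.0 - cz * cz))
    phi = 2.0 * math.pi * _uniform(st)
    return sz * math.cos(phi), sz * math.sin(phi), cz


# ---------------------------------------------------------------------------
# Table interpolation (shared log-spaced energy grid)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _interp_m(table, m, loge, loge0, dloge):
    n = table.shape[1]
    f = (loge - loge0) / dloge
    if f <= 0.0:
        return table[m, 0]
    if f >= n - 1:
        return table[m, n - 1]
    i = int(f)
    w = f - i
    return table[m, i] * (1.0 - w) + table[m, i + 1] * w


@njit(cache=True, inline="always")
def _interp_1d(table, loge, loge0, dloge):
    n = table.shape[0]
    f = (loge - loge0) / dloge
    if f <= 0.0:
        return table[0]
    if f >= n - 1:
        return table[n - 1]
    i = int(f)
    w = f - i
    return table[i] * (1.0 - w) + table[i + 1] * w


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rotate_dir(dx, dy, dz, cth, phi):
    """Rotate unit vector by polar angle (cosine cth) about itself."""
    sth = math.sqrt(max(0.0, 1.0 - cth * cth))
    # orthonormal basis (e1, e2) perpendicular to d
    if abs(dz) < 0.99:
        e1x, e1y, e1z = -dy, dx, 0.0
    else:
        e1x, e1y, e1z = 0.0, -dz, dy
    norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / norm, e1y / norm, e1z / norm
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    cp = math.cos(phi)
    sp = math.sin(phi)
    nx = cth * dx + sth * (cp * e1x + sp * e2x)
    ny = cth * dy + sth * (cp * e1y + sp * e2y)
    nz = cth * dz + sth * (cp * e1z + sp * e2z)
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _helix_advance(px, py, pz, dx, dy, dz, s, kx, ky, kz, kmag):
    """Advance arc length s [mm] along the exact helix.

    (kx,ky,kz) is the signed rotation vector k*b̂ with k = q B / p c in
    1/mm (for an electron the sign is such that du/ds = k b̂ × u).
    Returns new position and direction.
    """
    if kmag == 0.0:
        return px + dx * s, py + dy * s, pz + dz * s, dx, dy, dz
    bx, by, bz = kx / kmag, ky / kmag, kz / kmag
    upar = dx * bx + dy * by + dz * bz
    ux, uy, uz = upar * bx, upar * by, upar * bz  # parallel component
    wx, wy, wz = dx - ux, dy - uy, dz - uz  # perpendicular component
    # v = b̂ × w
    vx = by * wz - bz * wy
    vy = bz * wx - bx * wz
    vz = bx * wy - by * wx
    phi = kmag * s
    c = math.cos(phi)
    si = math.sin(phi)
    ndx = ux + c * wx + si * vx
    ndy = uy + c * wy + si * vy
    ndz = uz + c * wz + si * vz
    # position: ∫ u(s') ds'
    a1 = si / kmag
    a2 = (1.0 - c) / kmag
    npx = px + upar * bx * s + a1 * wx + a2 * vx
    npy = py + upar * by * s + a1 * wy + a2 * vy
    npz = pz + upar * bz * s + a1 * wz + a2 * vz
    norm = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    return npx, npy, npz, ndx / norm, ndy / norm, ndz / norm


# ---------------------------------------------------------------------------
# Electron condensed-history transport
# ---------------------------------------------------------------------------

@njit(cache=True)
def _deposit_local(px, py, pz, e, ox, oy, oz, sx, sy, sz, edep):
    nx, ny, nz = edep.shape
    i = int(math.floor((px - ox) / sx))
    j = int(math.floor((py - oy) / sy))
    k = int(math.floor((pz - oz) / sz))
    if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
        edep[i, j, k] += e
        return e, 0.0
    return 0.0, e


@njit(cache=True)
def _dda_deposit(p0x, p0y, p0z, p1x, p1y, p1z, energy, loge0, dloge,
                 scol, matidx, density, ox, oy, oz, sx, sy, sz, edep):
    """March the straight chord p0→p1 across voxels depositing continuous
    energy loss by exact per-voxel path length.

    Returns (remaining_E, deposited, escaped, grammage, alive, inside).
    ``inside`` False means the chord left the grid; remaining energy is
    reported via ``escaped`` only when the particle is still alive.
    """
    nx, ny, nz = edep.shape
    ddx = p1x - p0x
    ddy = p1y - p0y
    ddz = p1z - p0z
    L = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
    deposited = 0.0
    grammage = 0.0
    if L <= 0.0:
        return energy, 0.0, 0.0, 0.0, True, True
    ux, uy, uz = ddx / L, ddy / L, ddz / L
    # current voxel
    fx = (p0x - ox) / sx
    fy = (p0y - oy) / sy
    fz = (p0z - oz) / sz
    i = int(math.floor(fx))
    j = int(math.floor(fy))
    k = int(math.floor(fz))
    stepi = 1 if ux > 0 else (-1 if ux < 0 else 0)
    stepj = 1 if uy > 0 else (-1 if uy < 0 else 0)
    stepk = 1 if uz > 0 else (-1 if uz < 0 else 0)
    BIG = 1e30
    tmaxx = ((i + (1 if stepi > 0 else 0)) * sx + ox - p0x) / ux if ux != 0 else BIG
    tmaxy = ((j + (1 if stepj > 0 else 0)) * sy + oy - p0y) / uy if uy != 0 else BIG
    tmaxz = ((k + (1 if stepk > 0 else 0)) * sz + oz - p0z) / uz if uz != 0 else BIG
    tdx = sx / abs(ux) if ux != 0 else BIG
    tdy = sy / abs(uy) if uy != 0 else BIG
    tdz = sz / abs(uz) if uz != 0 else BIG
    t = 0.0
    while t < L:
        tnext = tmaxx
        axis = 0
        if tmaxy < tnext:
            tnext = tmaxy
            axis = 1
        if tmaxz < tnext:
            tnext = tmaxz
            axis = 2
        seg_end = tnext if tnext < L else L
        seg = seg_end - t
        if seg > 0.0:
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                # left the world: remaining energy escapes
                return 0.0, deposited, energy, grammage, True, False
            rho = density[i, j, k]
            if rho >= RHO_VACUUM:
                m = matidx[i, j, k]
                s_here = _interp_m(scol, m, math.log(energy), loge0, dloge)
                de = s_here * rho * seg * 0.1  # mm→cm
                if de >= energy:
                    edep[i, j, k] += energy
                    deposited += energy
                    grammage += rho * seg * 0.1
                    return 0.0, deposited, 0.0, grammage, False, True
                edep[i, j, k] += de
                deposited += de
                energy -= de
                grammage += rho * seg * 0.1
        t = seg_end
        if tnext >= L:
            break
        if axis == 0:
            i += stepi
            tmaxx += tdx
        elif axis == 1:
            j += stepj
            tmaxy += tdy
        else:
            k += stepk
            tmaxz += tdz
    return energy, deposited, 0.0, grammage, True, True


@njit(cache=True, inline="always")
def _sample_moller_eps(energy, dcut, st):
    """Fractional δ-ray energy ε ∈ [Δ/T, 1/2] from the Møller DCS
    (1/ε² majorant with rejection on the full factor)."""
    eta = dcut / energy
    if eta >= 0.5:
        return 0.0
    tau = energy / ME
    gamma = tau + 1.0
    g1 = (tau / gamma) * (tau / gamma)
    g2 = (2.0 * tau + 1.0) / (gamma * gamma)
    while True:
        u = _uniform(st)
        eps = eta / (1.0 - u * (1.0 - 2.0 * eta))
        m = (1.0 / (eps * eps) + 1.0 / ((1.0 - eps) * (1.0 - eps)) + g1
             - g2 / (eps * (1.0 - eps)))
        if _uniform(st) * 2.5 <= m * eps * eps:
            return eps


@njit(cache=True)
def electron_history(px, py, pz, dx, dy, dz, energy,
                     matidx, density, ox, oy, oz, sx, sy, sz,
                     bx, by, bz,
                     scol, range_g, inv_x0, loge0, dloge,
                     drover, final_range_mm, e_cutoff, max_step_mm,
                     chord_tol, scatter_on,
                     delta_on, n_hard, delta_cut_e, straggle_on, zoa,
                     edep, st):
    """Transport one electron and its δ-ray cascade to completion.

    ``scol`` must be the restricted stopping power table when
    ``delta_on`` is 1. Returns (deposited, escaped).
    """
    nx, ny, nz = edep.shape
    deposited = 0.0
    escaped = 0.0
    bmag = math.sqrt(bx * bx + by * by + bz * bz)
    # secondary stack: x, y, z, dx, dy, dz, E
    stack = np.empty((64, 7))
    sp = 0
    stack[0, 0] = px
    stack[0, 1] = py
    stack[0, 2] = pz
    stack[0, 3] = dx
    stack[0, 4] = dy
    stack[0, 5] = dz
    stack[0, 6] = energy
    sp = 1
    while sp > 0:
        sp -= 1
        px = stack[sp, 0]
        py = stack[sp, 1]
        pz = stack[sp, 2]
        dx = stack[sp, 3]
        dy = stack[sp, 4]
        dz = stack[sp, 5]
        energy = stack[sp, 6]
        d, e = 0.0, 0.0
        drift_steps = 0
        alive_track = True
        while alive_track:
            if energy <= e_cutoff:
                d, e = _deposit_local(px, py, pz, energy, ox, oy, oz,
                                      sx, sy, sz, edep)
                deposited += d
                escaped += e
                break
            i = int(math.floor((px - ox) / sx))
            j = int(math.floor((py - oy) / sy))
            k = int(math.floor((pz - oz) / sz))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                escaped += energy
                break
            rho = density[i, j, k]
            m = matidx[i, j, k]
            loge = math.log(energy)
            pc = math.sqrt(energy * (energy + 2.0 * ME))
            kmag = GYRO * bmag / pc if bmag > 0.0 else 0.0
            # electrons: charge -e, field b̂ → du/ds = k (b̂ × u), k > 0
            kx = kmag * bx / bmag if bmag > 0.0 else 0.0
            ky = kmag * by / bmag if bmag > 0.0 else 0.0
            kz = kmag * bz / bmag if bmag > 0.0 else 0.0
            if rho < RHO_VACUUM:
                # drift through empty voxels; a field-trapped orbit that
                # never re-enters matter is abandoned as escaped
                drift_steps += 1
                if drift_steps > 100000:
                    escaped += energy
                    break
                px, py, pz, dx, dy, dz = _helix_advance(
                    px, py, pz, dx, dy, dz, max_step_mm, kx, ky, kz, kmag)
                continue
            rg = _interp_m(range_g, m, loge, loge0, dloge)
            rgeo = rg / rho * 10.0  # mm
            if rgeo <= final_range_mm:
                d, e = _deposit_local(px, py, pz, energy, ox, oy, oz,
                                      sx, sy, sz, edep)
                deposited += d
                escaped += e
                break
            step = drover * rgeo
            if step > max_step_mm:
                step = max_step_mm
            # δ production: distance to the next hard Møller collision
            do_hard = False
            if delta_on == 1:
                lam = _interp_m(n_hard, m, loge, loge0, dloge)  # per g/cm²
                if lam > 0.0:
                    s_hard = -math.log(max(_uniform(st), 1e-300)) / (
                        lam * rho * 0.1)  # mm
                    if s_hard < step:
                        step = s_hard
                        do_hard = True
            # chord sub-stepping: sagitta ≈ s²·k/8 ≤ chord_tol
            if kmag > 0.0:
                smax = math.sqrt(8.0 * chord_tol / kmag)
                nsub = int(math.ceil(step / smax))
            else:
                nsub = 1
            ssub = step / nsub
            grammage = 0.0
            alive = True
            inside = True
            for _ in range(nsub):
                q0x, q0y, q0z = px, py, pz
                px, py, pz, dx, dy, dz = _helix_advance(
                    px, py, pz, dx, dy, dz, ssub, kx, ky, kz, kmag)
                energy, dep, esc, gr, alive, inside = _dda_deposit(
                    q0x, q0y, q0z, px, py, pz, energy, loge0, dloge,
                    scol, matidx, density, ox, oy, oz, sx, sy, sz, edep)
                deposited += dep
                escaped += esc
                grammage += gr
                if not alive or not inside:
                    break
            if not alive or not inside:
                break
            if straggle_on == 1 and grammage > 0.0:
                # Bohr energy-loss straggling on the soft/continuous loss
                beta2 = 1.0 - (ME / (energy + ME)) ** 2
                omega2 = 0.1569 * zoa[m] * grammage * (
                    1.0 - 0.5 * beta2) / beta2
                g1, _ = _normal_pair(st)
                de_s = math.sqrt(omega2) * g1
                if de_s > energy:
                    de_s = energy
                elif de_s < -0.5 * energy:
                    de_s = -0.5 * energy
                d, e = _deposit_local(px, py, pz, de_s, ox, oy, oz,
                                      sx, sy, sz, edep)
                deposited += d
                escaped += e
                energy -= de_s
                if energy <= 0.0:
                    break
            if do_hard and energy > 2.0 * delta_cut_e[m]:
                eps = _sample_moller_eps(energy, delta_cut_e[m], st)
                if eps > 0.0:
                    e_delta = eps * energy
                    t_prim = energy
                    energy -= e_delta
                    # δ polar angle from binary-collision kinematics
                    arg = e_delta * (t_prim + 2.0 * ME) / (
                        t_prim * (e_delta + 2.0 * ME))
                    cdel = math.sqrt(min(arg, 1.0))
                    phi = 2.0 * math.pi * _uniform(st)
                    ddx, ddy, ddz = _rotate_dir(dx, dy, dz, cdel, phi)
                    if e_delta <= e_cutoff or sp >= 63:
                        d, e = _deposit_local(px, py, pz, e_delta,
                                              ox, oy, oz, sx, sy, sz, edep)
                        deposited += d
                        escaped += e
                    else:
                        stack[sp, 0] = px
                        stack[sp, 1] = py
                        stack[sp, 2] = pz
                        stack[sp, 3] = ddx
                        stack[sp, 4] = ddy
                        stack[sp, 5] = ddz
                        stack[sp, 6] = e_delta
                        sp += 1
            if scatter_on == 1 and grammage > 0.0 and inv_x0[m] > 0.0:
                t = grammage * inv_x0[m]
                if t > 0.0:
                    pc = math.sqrt(energy * (energy + 2.0 * ME))
                    beta = pc / (energy + ME)
                    corr = 1.0 + 0.038 * math.log(t)
                    if corr < 0.0:
                        corr = 0.0
                    theta0 = 13.6 / (beta * pc) * math.sqrt(t) * corr
                    g1, g2 = _normal_pair(st)
                    theta = theta0 * math.sqrt(g1 * g1 + g2 * g2)
                    phi = 2.0 * math.pi * _uniform(st)
                    dx, dy, dz = _rotate_dir(dx, dy, dz, math.cos(theta),
                                             phi)
    return deposited, escaped


# ---------------------------------------------------------------------------
# Compton sampling (kernel mirror of materials.sample_compton)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sample_compton(energy, st):
    """Returns (eps, cos_theta_photon, cos_theta_electron)."""
    kk = energy / ME
    eps_min = 1.0 / (1.0 + 2.0 * kk)
    a1 = math.log(1.0 / eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    eps = 1.0
    t = 0.0
    while True:
        if _uniform(st) * (a1 + a2) < a1:
            eps = math.exp(-a1 * _uniform(st))
        else:
            eps = math.sqrt(eps_min * eps_min +
                            _uniform(st) * (1.0 - eps_min * eps_min))
        t = (1.0 - eps) / (kk * eps)
        sin2 = t * (2.0 - t)
        if _uniform(st) <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            break
    cth = 1.0 - t
    e_el = energy * (1.0 - eps)
    if e_el > 0.0:
        p_el = math.sqrt(e_el * (e_el + 2.0 * ME))
        cel = (energy - eps * energy * cth) / p_el
        if cel > 1.0:
            cel = 1.0
        elif cel < -1.0:
            cel = -1.0
    else:
        cel = 1.0
    return eps, cth, cel


# ---------------------------------------------------------------------------
# Photon transport (Woodcock tracking through the voxel grid)
# ---------------------------------------------------------------------------

@njit(cache=True)
def photon_history(px, py, pz, dx, dy, dz, energy,
                   matidx, density, ox, oy, oz, sx, sy, sz,
                   bx, by, bz,
                   scol, range_g, inv_x0,
                   sig_total, sig_pe, mu_majorant,
                   loge0, dloge,
                   drover, final_range_mm, e_cutoff, max_step_mm,
                   chord_tol, scatter_on,
                   delta_on, n_hard, delta_cut_e, straggle_on, zoa,
                   photon_cutoff,
                   edep, st):
    """Transport one photon (and its secondary electrons).

    Photons are insensitive to the field; their secondaries are not.
    Returns (deposited, escaped).
    """
    nx, ny, nz = edep.shape
    deposited = 0.0
    escaped = 0.0
    while True:
        if energy < photon_cutoff:
            d, e = _deposit_local(px, py, pz, energy, ox, oy, oz,
                                  sx, sy, sz, edep)
            return deposited + d, escaped + e
        loge = math.log(energy)
        mu_maj = _interp_1d(mu_majorant, loge, loge0, dloge)  # 1/cm
        if mu_maj <= 0.0:
            return deposited, escaped + energy
        flight_mm = -math.log(max(_uniform(st), 1e-300)) / mu_maj * 10.0
        px += dx * flight_mm
        py += dy * flight_mm
        pz += dz * flight_mm
        i = int(math.floor((px - ox) / sx))
        j = int(math.floor((py - oy) / sy))
        k = int(math.floor((pz - oz) / sz))
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            return deposited, escaped + energy
        rho = density[i, j, k]
        if rho < RHO_VACUUM:
            continue
        m = matidx[i, j, k]
        mu_real = _interp_m(sig_total, m, loge, loge0, dloge) * rho
        if _uniform(st) * mu_maj > mu_real:
            continue  # null collision
        pe = _interp_m(sig_pe, m, loge, loge0, dloge) * rho
        if _uniform(st) * mu_real < pe:
            # photoelectric: full energy to a forward electron
            d, e = electron_history(
                px, py, pz, dx, dy, dz, energy,
                matidx, density, ox, oy, oz, sx, sy, sz,
                bx, by, bz, scol, range_g, inv_x0, loge0, dloge,
                drover, final_range_mm, e_cutoff, max_step_mm,
                chord_tol, scatter_on,
                delta_on, n_hard, delta_cut_e, straggle_on, zoa,
                edep, st)
            return deposited + d, escaped + e
        eps, cth, cel = _sample_compton(energy, st)
        phi = 2.0 * math.pi * _uniform(st)
        e_el = energy * (1.0 - eps)
        if e_el > 0.0:
            edx, edy, edz = _rotate_dir(dx, dy, dz, cel, phi + math.pi)
            d, e = electron_history(
                px, py, pz, edx, edy, edz, e_el,
                matidx, density, ox, oy, oz, sx, sy, sz,
                bx, by, bz, scol, range_g, inv_x0, loge0, dloge,
                drover, final_range_mm, e_cutoff, max_step_mm,
                chord_tol, scatter_on,
                delta_on, n_hard, delta_cut_e, straggle_on, zoa,
                edep, st)
            deposited += d
            escaped += e
        dx, dy, dz = _rotate_dir(dx, dy, dz, cth, phi)
        energy *= eps


# ---------------------------------------------------------------------------
# Batch drivers
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_point_electron_batch(n, srcx, srcy, srcz, mono_e,
                             spec_edges, spec_cdf, use_spectrum,
                             matidx, density, ox, oy, oz, sx, sy, sz,
                             bx, by, bz,
                             scol, range_g, inv_x0, loge0, dloge,
                             drover, final_range_mm, e_cutoff, max_step_mm,
                             chord_tol, scatter_on,
                             delta_on, n_hard, delta_cut_e, straggle_on, zoa,
                             edep, seed, stream):
    """Run n isotropic point-electron histories; returns conservation tallies
    (emitted, deposited, escaped, max per-history residual)."""
    st = rng_state(seed, stream)
    emitted = 0.0
    deposited = 0.0
    escaped = 0.0
    max_resid = 0.0
    for _ in range(n):
        dx, dy, dz = _isotropic(st)
        if use_spectrum == 1:
            u = _uniform(st)
            nb = spec_cdf.shape[0]
            lo = 0
            hi = nb - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if spec_cdf[mid] < u:
                    lo = mid + 1
                else:
                    hi = mid
            e_lo = spec_edges[lo]
            e_hi = spec_edges[lo + 1]
            e0 = e_lo + _uniform(st) * (e_hi - e_lo)
        else:
            e0 = mono_e
        emitted += e0
        d, e = electron_history(
            srcx, srcy, srcz, dx, dy, dz, e0,
            matidx, density, ox, oy, oz, sx, sy, sz,
            bx, by, bz, scol, range_g, inv_x0, loge0, dloge,
            drover, final_range_mm, e_cutoff, max_step_mm,
            chord_tol, scatter_on,
            delta_on, n_hard, delta_cut_e, straggle_on, zoa,
            edep, st)
        deposited += d
        escaped += e
        resid = abs(e0 - d - e)
        if resid > max_resid:
            max_resid = resid
    return emitted, deposited, escaped, max_resid


@njit(cache=True, inline="always")
def _cyl_interval(lx, ly, lz, dx, dy, dz, radius, zmin, zmax):
    """Parametric interval [t0, t1] of a ray inside a finite z-cylinder
    (local frame). Returns t1 < t0 when empty; clipped to t >= 0."""
    BIG = 1e30
    a = dx * dx + dy * dy
    if a > 1e-16:
        b = lx * dx + ly * dy
        c = lx * lx + ly * ly - radius * radius
        disc = b * b - a * c
        if disc <= 0.0:
            return 0.0, -1.0
        sq = math.sqrt(disc)
        r0 = (-b - sq) / a
        r1 = (-b + sq) / a
    else:
        if lx * lx + ly * ly > radius * radius:
            return 0.0, -1.0
        r0, r1 = -BIG, BIG
    if abs(dz) > 1e-16:
        z0 = (zmin - lz) / dz
        z1 = (zmax - lz) / dz
        if z0 > z1:
            z0, z1 = z1, z0
    else:
        if lz < zmin or lz > zmax:
            return 0.0, -1.0
        z0, z1 = -BIG, BIG
    t0 = r0 if r0 > z0 else z0
    t1 = r1 if r1 < z1 else z1
    if t0 < 0.0:
        t0 = 0.0
    return t0, t1


@njit(cache=True)
def sample_seed_photon(cx, cy, cz, ax, ay, az,
                       core_r, core_hl, case_r, case_hl, stub_len,
                       line_e, line_cdf,
                       sig_ir, sig_tini, rho_ir, rho_tini,
                       loge0, dloge, casing_on, st):
    """Sample one photon from the encapsulated seed.

    Emission point uniform in the iridium core, isotropic direction,
    energy from the gamma-line table; first-flight attenuation through
    core + casing + wire stub by analytic ray tracing. Returns
    (alive, x, y, z, dx, dy, dz, E) with the position at the casing
    exit; alive=0 means absorbed in the seed (counts as emitted).
    """
    # local orthonormal frame (e1, e2, axis)
    if abs(az) < 0.99:
        e1x, e1y, e1z = -ay, ax, 0.0
    else:
        e1x, e1y, e1z = 0.0, -az, ay
    norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / norm, e1y / norm, e1z / norm
    e2x = ay * e1z - az * e1y
    e2y = az * e1x - ax * e1z
    e2z = ax * e1y - ay * e1x
    # emission point uniform over the core cylinder volume
    rr = core_r * math.sqrt(_uniform(st))
    ph = 2.0 * math.pi * _uniform(st)
    zz = (2.0 * _uniform(st) - 1.0) * core_hl
    lx = rr * math.cos(ph)
    ly = rr * math.sin(ph)
    lz = zz
    # direction isotropic (local frame)
    ddx, ddy, ddz = _isotropic(st)
    # energy from the line spectrum
    u = _uniform(st)
    nl = line_cdf.shape[0]
    lo = 0
    hi = nl - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if line_cdf[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    energy = line_e[lo]
    loge = math.log(energy)
    # chord lengths [mm]
    t0, t1 = _cyl_interval(lx, ly, lz, ddx, ddy, ddz, core_r, -core_hl, core_hl)
    l_core = t1 - t0 if t1 > t0 else 0.0
    t0, t1 = _cyl_interval(lx, ly, lz, ddx, ddy, ddz, case_r, -case_hl, case_hl)
    l_case_total = t1 - t0 if t1 > t0 else 0.0
    t_exit = t1
    l_tini = l_case_total - l_core
    if l_tini < 0.0:
        l_tini = 0.0
    # drive-wire stub behind the seed (-axis side)
    s0, s1 = _cyl_interval(lx, ly, lz, ddx, ddy, ddz, case_r,
                           -case_hl - stub_len, -case_hl)
    l_stub = s1 - s0 if s1 > s0 else 0.0
    if l_stub > 0.0 and s1 > t_exit:
        t_exit = s1
    alive = 1
    if casing_on == 1:
        mu_ir = _interp_m(sig_ir, 0, loge, loge0, dloge) * rho_ir
        mu_tn = _interp_m(sig_tini, 0, loge, loge0, dloge) * rho_tini
        tau = (mu_ir * l_core + mu_tn * (l_tini + l_stub)) * 0.1  # mm→cm
        if _uniform(st) > math.exp(-tau):
            alive = 0
    # exit point (global frame), just past the casing
    te = t_exit + 1e-6
    gx = cx + (lx + te * ddx) * e1x + (ly + te * ddy) * e2x + (lz + te * ddz) * ax
    gy = cy + (lx + te * ddx) * e1y + (ly + te * ddy) * e2y + (lz + te * ddz) * ay
    gz = cz + (lx + te * ddx) * e1z + (ly + te * ddy) * e2z + (lz + te * ddz) * az
    gdx = ddx * e1x + ddy * e2x + ddz * ax
    gdy = ddx * e1y + ddy * e2y + ddz * ay
    gdz = ddx * e1z + ddy * e2z + ddz * az
    return alive, gx, gy, gz, gdx, gdy, gdz, energy


@njit(cache=True)
def run_seed_plan_batch(n, pos, axes, pos_cdf,
                        core_r, core_hl, case_r, case_hl, stub_len,
                        line_e, line_cdf,
                        sig_ir, sig_tini, rho_ir, rho_tini, casing_on,
                        matidx, density, ox, oy, oz, sx, sy, sz,
                        bx, by, bz,
                        scol, range_g, inv_x0,
                        sig_total, sig_pe, mu_majorant,
                        loge0, dloge,
                        drover, final_range_mm, e_cutoff, max_step_mm,
                        chord_tol, scatter_on,
                        delta_on, n_hard, delta_cut_e, straggle_on, zoa,
                        photon_cutoff,
                        edep, seed, stream):
    """Run n seed-plan photon histories (dwell position chosen from the
    weight CDF). Returns (emitted, deposited, escaped, absorbed_in_seed)."""
    st = rng_state(seed, stream)
    emitted = 0.0
    deposited = 0.0
    escaped = 0.0
    absorbed = 0.0
    npos = pos_cdf.shape[0]
    for _ in range(n):
        u = _uniform(st)
        lo = 0
        hi = npos - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if pos_cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        alive, px, py, pz, dx, dy, dz, energy = sample_seed_photon(
            pos[lo, 0], pos[lo, 1], pos[lo, 2],
            axes[lo, 0], axes[lo, 1], axes[lo, 2],
            core_r, core_hl, case_r, case_hl, stub_len,
            line_e, line_cdf, sig_ir, sig_tini, rho_ir, rho_tini,
            loge0, dloge, casing_on, st)
        emitted += energy
        if alive == 0:
            absorbed += energy
            continue
        d, e = photon_history(
            px, py, pz, dx, dy, dz, energy,
            matidx, density, ox, oy, oz, sx, sy, sz,
            bx, by, bz, scol, range_g, inv_x0,
            sig_total, sig_pe, mu_majorant, loge0, dloge,
            drover, final_range_mm, e_cutoff, max_step_mm,
            chord_tol, scatter_on,
            delta_on, n_hard, delta_cut_e, straggle_on, zoa,
            photon_cutoff, edep, st)
        deposited += d
        escaped += e
    return emitted, deposited, escaped, absorbed


# ---------------------------------------------------------------------------
# TG-43 estimators: homogeneous-water (r, z) dose table and in-vacuo fluence
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_seed_water_batch(n, core_r, core_hl, case_r, case_hl, stub_len,
                         line_e, line_cdf,
                         sig_ir, sig_tini, rho_ir, rho_tini, casing_on,
                         sig_water, pe_water, mu_tr_water, loge0, dloge,
                         world_r, world_hl,
                         score_rmax, score_zmax, bin_mm,
                         photon_cutoff, analog_mode,
                         dose_rz, seed, stream):
    """Seed photons in an unbounded water cylinder, scoring a cylindrical
    (r, z) kerma table about the seed center (axis along z).

    Default estimator: track-length collision kerma (E·μ_tr/ρ per unit
    path). ``analog_mode=1`` instead deposits the transferred energy at
    interaction sites. Returns (emitted, n_surviving).
    """
    st = rng_state(seed, stream)
    nr = dose_rz.shape[0]
    nz = dose_rz.shape[1]
    emitted = 0.0
    survived = 0
    substep = bin_mm * 0.5
    for _ in range(n):
        alive, px, py, pz, dx, dy, dz, energy = sample_seed_photon(
            0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
            core_r, core_hl, case_r, case_hl, stub_len,
            line_e, line_cdf, sig_ir, sig_tini, rho_ir, rho_tini,
            loge0, dloge, casing_on, st)
        emitted += energy
        if alive == 0:
            continue
        survived += 1
        while True:
            if energy < photon_cutoff:
                break
            loge = math.log(energy)
            mu = _interp_m(sig_water, 0, loge, loge0, dloge)  # ρ=1 → 1/cm
            flight = -math.log(max(_uniform(st), 1e-300)) / mu * 10.0  # mm
            # clip to world cylinder
            t0, t1 = _cyl_interval(px, py, pz, dx, dy, dz,
                                   world_r, -world_hl, world_hl)
            leave = flight >= t1
            seg_len = t1 if leave else flight
            if analog_mode == 0:
                w = energy * _interp_m(mu_tr_water, 0, loge, loge0, dloge)
                nsub = int(seg_len / substep) + 1
                ds = seg_len / nsub
                for q in range(nsub):
                    tmid = (q + 0.5) * ds
                    qx = px + dx * tmid
                    qy = py + dy * tmid
                    qz = pz + dz * tmid
                    rr = math.sqrt(qx * qx + qy * qy)
                    if rr < score_rmax and abs(qz) < score_zmax:
                        ir = int(rr / bin_mm)
                        iz = int((qz + score_zmax) / bin_mm)
                        if 0 <= ir < nr and 0 <= iz < nz:
                            dose_rz[ir, iz] += w * ds * 0.1  # MeV·cm³/g
            px += dx * seg_len
            py += dy * seg_len
            pz += dz * seg_len
            if leave:
                break
            pe = _interp_m(pe_water, 0, loge, loge0, dloge)
            if _uniform(st) * mu < pe:
                if analog_mode == 1:
                    rr = math.sqrt(px * px + py * py)
                    if rr < score_rmax and abs(pz) < score_zmax:
                        ir = int(rr / bin_mm)
                        iz = int((pz + score_zmax) / bin_mm)
                        if 0 <= ir < nr and 0 <= iz < nz:
                            dose_rz[ir, iz] += energy
                break
            eps, cth, cel = _sample_compton(energy, st)
            if analog_mode == 1:
                rr = math.sqrt(px * px + py * py)
                if rr < score_rmax and abs(pz) < score_zmax:
                    ir = int(rr / bin_mm)
                    iz = int((pz + score_zmax) / bin_mm)
                    if 0 <= ir < nr and 0 <= iz < nz:
                        dose_rz[ir, iz] += energy * (1.0 - eps)
            phi = 2.0 * math.pi * _uniform(st)
            dx, dy, dz = _rotate_dir(dx, dy, dz, cth, phi)
            energy *= eps
    return emitted, survived


@njit(cache=True)
def run_seed_vacuum_fluence_batch(n, core_r, core_hl, case_r, case_hl,
                                  stub_len, line_e, line_cdf,
                                  sig_ir, sig_tini, rho_ir, rho_tini,
                                  casing_on, loge0, dloge,
                                  sphere_r_mm, n_theta_bins,
                                  line_weight,
                                  theta_energy_acc, seed, stream):
    """In-vacuo fluence on a polar-binned sphere: accumulates
    Σ E·w(E) per polar bin, where w is a per-line weight (e.g. μ_en/ρ of
    air). Returns number of emitted histories that survived the seed."""
    st = rng_state(seed, stream)
    survived = 0
    for _ in range(n):
        alive, px, py, pz, dx, dy, dz, energy = sample_seed_photon(
            0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
            core_r, core_hl, case_r, case_hl, stub_len,
            line_e, line_cdf, sig_ir, sig_tini, rho_ir, rho_tini,
            loge0, dloge, casing_on, st)
        if alive == 0:
            continue
        survived += 1
        # intersect ray with the scoring sphere |p + t d| = R
        b = px * dx + py * dy + pz * dz
        c = px * px + py * py + pz * pz - sphere_r_mm * sphere_r_mm
        disc = b * b - c
        if disc <= 0.0:
            continue
        t = -b + math.sqrt(disc)
        hx = px + t * dx
        hy = py + t * dy
        hz = pz + t * dz
        cth = hz / sphere_r_mm
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        theta = math.acos(cth) * 180.0 / math.pi
        ib = int(theta / (180.0 / n_theta_bins))
        if ib >= n_theta_bins:
            ib = n_theta_bins - 1
        # identify the line index for the weight
        wl = 0.0
        for li in range(line_e.shape[0]):
            if abs(line_e[li] - energy) < 1e-12:
                wl = line_weight[li]
                break
        theta_energy_acc[ib] += energy * wl
    return survived
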