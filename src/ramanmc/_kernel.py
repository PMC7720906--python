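"""Numba-compiled batch engine.

This module re-implements the scalar event loop of ``transport`` as a
compiled per-photon loop over whole batches.  The uniform draw order and
every floating-point expression mirror the reference implementation so
that, driven by the same recorded variate stream, the two engines
produce identical records (the equivalence oracle in the test suite).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ABSORBED = 0
ESCAPED = 1
ITERATION_CAP = 2

_NUDGE = 1e-9
_LAUNCH_STANDOFF = 1e-6  # keep equal to transport._LAUNCH_STANDOFF
_VOID_STEP = 1e30
_EPS = 1e-9  # keep equal to geometry._EPS

GEOM_LAYERED = 0
GEOM_VOXEL = 1


_U64_11 = np.uint64(11)
_TO_UNIT = 1.1102230246251565e-16  # 2^-53


@njit(cache=True, inline="always")
def _rotl(x, k):
    return np.uint64((x << k) | (x >> (np.uint64(64) - k)))


@njit(cache=True)
def _seed_state(seed, state):
    """Expand a small integer seed into xoshiro256++ state via splitmix64."""
    z = np.uint64(seed)
    for i in range(4):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1E4357B7)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = w ^ (w >> np.uint64(31))


@njit(cache=True, inline="always")
def _next_unit(state):
    """xoshiro256++ draw mapped to [0, 1) with 53 random bits."""
    s0 = state[0]
    s1 = state[1]
    s2 = state[2]
    s3 = state[3]
    result = _rotl(s0 + s3, np.uint64(23)) + s0
    t = s1 << np.uint64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    state[0] = s0
    state[1] = s1
    state[2] = s2
    state[3] = _rotl(s3, np.uint64(45))
    return float(result >> _U64_11) * _TO_UNIT


@njit(cache=True, inline="always")
def _draw(stream, use_stream, cursor, s0, s1, s2, s3):
    """One uniform from either the recorded stream or xoshiro256++.

    RNG state is threaded through as scalars (kept in registers in the
    hot loop); returns (value, s0, s1, s2, s3).
    """
    if use_stream:
        c = cursor[0]
        if c >= stream.size:
            raise IndexError("recorded variate stream exhausted")
        cursor[0] = c + 1
        return stream[c], s0, s1, s2, s3
    result = _rotl(s0 + s3, np.uint64(23)) + s0
    t = s1 << np.uint64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, np.uint64(45))
    return float(result >> _U64_11) * _TO_UNIT, s0, s1, s2, s3


@njit(cache=True)
def _sincos(x):
    """sin/cos pair evaluated by the numba-linked libm.

    The scalar Python reference calls this too: CPython's math module and
    numba bind cos/sin implementations that differ by 1 ulp on ~0.1% of
    arguments, which would break byte-identical engine equivalence.
    """
    return math.sin(x), math.cos(x)


@njit(cache=True, inline="always")
def _hg_cos(xi, g):
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, ct, st, cp, sp):
    if abs(uz) > 1.0 - 1e-12:
        sign = 1.0 if uz >= 0.0 else -1.0
        ox = st * cp
        oy = sign * st * sp
        oz = sign * ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        inv_den = 1.0 / den
        ox = st * (ux * uz * cp - uy * sp) * inv_den + ux * ct
        oy = st * (uy * uz * cp + ux * sp) * inv_den + uy * ct
        oz = -st * cp * den + uz * ct
    inv_norm = 1.0 / math.sqrt(ox * ox + oy * oy + oz * oz)
    return ox * inv_norm, oy * inv_norm, oz * inv_norm


@njit(cache=True, inline="always")
def _fresnel_refract(dx, dy, dz, nx, ny, nz, n1, n2):
    """Returns (R, refracted dx, dy, dz); direction invalid when R == 1."""
    ci = -(dx * nx + dy * ny + dz * nz)
    eta = n1 / n2
    s2 = eta * eta * (1.0 - ci * ci)
    if s2 >= 1.0:
        return 1.0, 0.0, 0.0, 0.0
    ct = math.sqrt(1.0 - s2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    k = eta * ci - ct
    return 0.5 * (rs * rs + rp * rp), eta * dx + k * nx, eta * dy + k * ny, eta * dz + k * nz


# ---------------------------------------------------------------------------
# geometry queries (mirrors geometry.py)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _voxel_label(labels, ix, iy, iz):
    nz, ny, nx = labels.shape
    if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
        return labels[iz, iy, ix]
    return np.int64(0)


@njit(cache=True, inline="always")
def _voxel_material_at(labels, pitch, ox, oy, oz, x, y, z):
    ix = int(math.floor((x - ox) / pitch))
    iy = int(math.floor((y - oy) / pitch))
    iz = int(math.floor((z - oz) / pitch))
    return _voxel_label(labels, ix, iy, iz)


@njit(cache=True, inline="always")
def _voxel_first_interface(labels, uniform, z_runs, pitch, ox, oy, oz,
                           px, py, pz, dx, dy, dz, step):
    """DDA traversal; returns (found, t, nx, ny, nz, before, after)."""
    nzv, nyv, nxv = labels.shape
    hix = ox + nxv * pitch
    hiy = oy + nyv * pitch
    hiz = oz + nzv * pitch

    # exact fast path (mirrors geometry.VoxelGeometry.first_interface):
    # both endpoints inside the grid and provably in one material region
    if uniform or z_runs.size > 0:
        ex = px + step * dx
        ey = py + step * dy
        ez = pz + step * dz
        if (ox <= px < hix and oy <= py < hiy and oz <= pz < hiz
                and ox <= ex < hix and oy <= ey < hiy and oz <= ez < hiz):
            if uniform:
                return False, 0.0, 0.0, 0.0, 0.0, 0, 0
            iz0 = int(math.floor((pz - oz) / pitch))
            iz1 = int(math.floor((ez - oz) / pitch))
            if z_runs[iz0] == z_runs[iz1]:
                return False, 0.0, 0.0, 0.0, 0.0, 0, 0

    ix = int(math.floor((px - ox) / pitch))
    iy = int(math.floor((py - oy) / pitch))
    iz = int(math.floor((pz - oz) / pitch))
    inside = 0 <= ix < nxv and 0 <= iy < nyv and 0 <= iz < nzv

    if not inside:
        t_enter = -math.inf
        t_exit = math.inf
        entry_axis = -1
        # x axis
        if dx == 0.0:
            if px < ox or px >= hix:
                return False, 0.0, 0.0, 0.0, 0.0, 0, 0
        else:
            t1 = (ox - px) / dx
            t2 = (hix - px) / dx
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > t_enter:
                t_enter = t1
                entry_axis = 0
            if t2 < t_exit:
                t_exit = t2
        # y axis
        if dy == 0.0:
            if py < oy or py >= hiy:
                return False, 0.0, 0.0, 0.0, 0.0, 0, 0
        else:
            t1 = (oy - py) / dy
            t2 = (hiy - py) / dy
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > t_enter:
                t_enter = t1
                entry_axis = 1
            if t2 < t_exit:
                t_exit = t2
        # z axis
        if dz == 0.0:
            if pz < oz or pz >= hiz:
                return False, 0.0, 0.0, 0.0, 0.0, 0, 0
        else:
            t1 = (oz - pz) / dz
            t2 = (hiz - pz) / dz
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > t_enter:
                t_enter = t1
                entry_axis = 2
            if t2 < t_exit:
                t_exit = t2
        if t_enter >= t_exit or t_enter > step or t_exit <= 0.0:
            return False, 0.0, 0.0, 0.0, 0.0, 0, 0
        t0 = max(t_enter, 0.0)
        qx = px + (t0 + _EPS) * dx
        qy = py + (t0 + _EPS) * dy
        qz = pz + (t0 + _EPS) * dz
        ix = int(math.floor((qx - ox) / pitch))
        iy = int(math.floor((qy - oy) / pitch))
        iz = int(math.floor((qz - oz) / pitch))
        lab = _voxel_label(labels, ix, iy, iz)
        if lab != 0 and t_enter > 0.0:
            nxn = nyn = nzn = 0.0
            if entry_axis == 0:
                nxn = -1.0 if dx > 0.0 else 1.0
            elif entry_axis == 1:
                nyn = -1.0 if dy > 0.0 else 1.0
            else:
                nzn = -1.0 if dz > 0.0 else 1.0
            return True, t0, nxn, nyn, nzn, 0, int(lab)
        cur = int(lab)
    else:
        cur = int(_voxel_label(labels, ix, iy, iz))

    # Amanatides-Woo traversal
    step_x = step_y = step_z = 0
    t_max_x = t_max_y = t_max_z = math.inf
    t_dx = t_dy = t_dz = math.inf
    if dx > 0.0:
        step_x = 1
        t_max_x = (ox + (ix + 1) * pitch - px) / dx
        t_dx = pitch / dx
    elif dx < 0.0:
        step_x = -1
        t_max_x = (ox + ix * pitch - px) / dx
        t_dx = -pitch / dx
    if dy > 0.0:
        step_y = 1
        t_max_y = (oy + (iy + 1) * pitch - py) / dy
        t_dy = pitch / dy
    elif dy < 0.0:
        step_y = -1
        t_max_y = (oy + iy * pitch - py) / dy
        t_dy = -pitch / dy
    if dz > 0.0:
        step_z = 1
        t_max_z = (oz + (iz + 1) * pitch - pz) / dz
        t_dz = pitch / dz
    elif dz < 0.0:
        step_z = -1
        t_max_z = (oz + iz * pitch - pz) / dz
        t_dz = -pitch / dz

    while True:
        if t_max_x <= t_max_y and t_max_x <= t_max_z:
            a = 0
            t = t_max_x
        elif t_max_y <= t_max_z:
            a = 1
            t = t_max_y
        else:
            a = 2
            t = t_max_z
        if t > step or not math.isfinite(t):
            return False, 0.0, 0.0, 0.0, 0.0, 0, 0
        if a == 0:
            ix += step_x
            outside = not (0 <= ix < nxv)
        elif a == 1:
            iy += step_y
            outside = not (0 <= iy < nyv)
        else:
            iz += step_z
            outside = not (0 <= iz < nzv)
        nxt = 0 if outside else int(labels[iz, iy, ix])
        if nxt != cur:
            nxn = nyn = nzn = 0.0
            if a == 0:
                nxn = -1.0 if dx > 0.0 else 1.0
            elif a == 1:
                nyn = -1.0 if dy > 0.0 else 1.0
            else:
                nzn = -1.0 if dz > 0.0 else 1.0
            return True, t, nxn, nyn, nzn, cur, nxt
        if outside:
            return False, 0.0, 0.0, 0.0, 0.0, 0, 0
        if a == 0:
            t_max_x += t_dx
        elif a == 1:
            t_max_y += t_dy
        else:
            t_max_z += t_dz


@njit(cache=True, inline="always")
def _layered_material_at(z_edges, layer_mats, hx, hy, x, y, z):
    if abs(x) > hx or abs(y) > hy:
        return 0
    if z < z_edges[0] or z >= z_edges[z_edges.size - 1]:
        return 0
    k = int(np.searchsorted(z_edges, z, side="right")) - 1
    return int(layer_mats[k])


@njit(cache=True, inline="always")
def _layered_first_interface(z_edges, layer_mats, hx, hy,
                             px, py, pz, dx, dy, dz, step):
    n_edges = z_edges.size
    max_c = n_edges + 4
    ts = np.empty(max_c)
    axes = np.empty(max_c, dtype=np.int64)
    nc = 0
    if dz != 0.0:
        for k in range(n_edges):
            t = (z_edges[k] - pz) / dz
            if _EPS < t <= step:
                ts[nc] = t
                axes[nc] = 2
                nc += 1
    if dx != 0.0 and math.isfinite(hx):
        for sgn in range(2):
            plane = -hx if sgn == 0 else hx
            t = (plane - px) / dx
            if _EPS < t <= step:
                ts[nc] = t
                axes[nc] = 0
                nc += 1
    if dy != 0.0 and math.isfinite(hy):
        for sgn in range(2):
            plane = -hy if sgn == 0 else hy
            t = (plane - py) / dy
            if _EPS < t <= step:
                ts[nc] = t
                axes[nc] = 1
                nc += 1
    # insertion sort by (t, axis)
    for i in range(1, nc):
        tv = ts[i]
        av = axes[i]
        j = i - 1
        while j >= 0 and (ts[j] > tv or (ts[j] == tv and axes[j] > av)):
            ts[j + 1] = ts[j]
            axes[j + 1] = axes[j]
            j -= 1
        ts[j + 1] = tv
        axes[j + 1] = av
    m_prev = _layered_material_at(z_edges, layer_mats, hx, hy,
                                  px + _EPS * dx, py + _EPS * dy, pz + _EPS * dz)
    for i in range(nc):
        t = ts[i]
        a = axes[i]
        qx = px + (t + _EPS) * dx
        qy = py + (t + _EPS) * dy
        qz = pz + (t + _EPS) * dz
        m_next = _layered_material_at(z_edges, layer_mats, hx, hy, qx, qy, qz)
        if m_next != m_prev:
            nxn = nyn = nzn = 0.0
            if a == 0:
                nxn = -1.0 if dx > 0.0 else 1.0
            elif a == 1:
                nyn = -1.0 if dy > 0.0 else 1.0
            else:
                nzn = -1.0 if dz > 0.0 else 1.0
            return True, t, nxn, nyn, nzn, m_prev, m_next
    return False, 0.0, 0.0, 0.0, 0.0, 0, 0


@njit(cache=True, inline="always")
def _first_interface(geom_kind, labels, uniform, z_runs, pitch, ox, oy, oz,
                     z_edges, layer_mats, hx, hy, px, py, pz, dx, dy, dz, step):
    if geom_kind == GEOM_VOXEL:
        return _voxel_first_interface(labels, uniform, z_runs, pitch,
                                      ox, oy, oz, px, py, pz, dx, dy, dz, step)
    return _layered_first_interface(z_edges, layer_mats, hx, hy,
                                    px, py, pz, dx, dy, dz, step)


@njit(cache=True, inline="always")
def _material_at(geom_kind, labels, pitch, ox, oy, oz, z_edges, layer_mats,
                 hx, hy, x, y, z):
    if geom_kind == GEOM_VOXEL:
        return int(_voxel_material_at(labels, pitch, ox, oy, oz, x, y, z))
    return _layered_material_at(z_edges, layer_mats, hx, hy, x, y, z)


# ---------------------------------------------------------------------------
# batch loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_batch(seed, n_photons,
               geom_kind, labels, uniform, z_runs, pitch, ox, oy, oz,
               z_edges, layer_mats, hx, hy,
               mu_s, mu_a, g_tab, n_tab, rho_R, rho_F,
               src_x, src_y, src_std, src_radius, cos_cone, has_cone,
               max_iterations, stream,
               out_state, out_x, out_y, out_z, out_ux, out_uy, out_uz,
               out_wl, out_raman, out_fluor, out_rdepth, out_iters):
    use_stream = stream.size > 0
    rng_state = np.empty(4, dtype=np.uint64)
    _seed_state(seed, rng_state)
    s0 = rng_state[0]
    s1 = rng_state[1]
    s2 = rng_state[2]
    s3 = rng_state[3]
    cursor = np.zeros(1, dtype=np.int64)
    W = mu_s.shape[1]

    for i in range(n_photons):
        # -- launch ---------------------------------------------------------
        gx = 0.0
        gy = 0.0
        if src_std > 0.0 and src_radius > 0.0:
            while True:
                ua, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                ub, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                r = src_std * math.sqrt(-2.0 * math.log1p(-ua))
                sb, cb = _sincos(2.0 * math.pi * ub)
                gx = r * cb
                gy = r * sb
                if gx * gx + gy * gy <= src_radius * src_radius:
                    break
        if has_cone:
            uc, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
            ud, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
            ct0 = 1.0 - uc * (1.0 - cos_cone)
            st0 = math.sqrt(max(0.0, 1.0 - ct0 * ct0))
            sp0, cp0 = _sincos(2.0 * math.pi * ud)
            dx = st0 * cp0
            dy = st0 * sp0
            dz = ct0
        else:
            dx = 0.0
            dy = 0.0
            dz = 1.0
        px = src_x + gx
        py = src_y + gy
        pz = -_LAUNCH_STANDOFF

        wl = 0
        mat = _material_at(geom_kind, labels, pitch, ox, oy, oz,
                           z_edges, layer_mats, hx, hy, px, py, pz)
        # cached properties of (mat, wl); refreshed on any change
        c_mus = 1.0
        c_g = 0.0
        c_mua = 0.0
        c_n = 1.0
        c_rho = 0.0
        if mat != 0:
            c_mus = mu_s[mat, wl]
            c_g = g_tab[mat, wl]
            c_mua = mu_a[mat, wl]
            c_n = n_tab[mat, wl]
            c_rho = rho_R[mat, W - 1]
        has_raman = False
        has_fluor = False
        raman_depth = np.nan
        state = ITERATION_CAP
        it = 0

        while it < max_iterations:
            it += 1
            if mat == 0:
                found, t, nxn, nyn, nzn, mb, m2 = _first_interface(
                    geom_kind, labels, uniform, z_runs, pitch, ox, oy, oz,
                    z_edges, layer_mats, hx, hy, px, py, pz, dx, dy, dz,
                    _VOID_STEP)
                if not found:
                    state = ESCAPED
                    break
                px = px + t * dx
                py = py + t * dy
                pz = pz + t * dz
                u7, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                R, rx, ry, rz = _fresnel_refract(dx, dy, dz, nxn, nyn, nzn,
                                                 1.0, n_tab[m2, wl])
                if u7 < R:
                    dot = dx * nxn + dy * nyn + dz * nzn
                    dx = dx - 2.0 * dot * nxn
                    dy = dy - 2.0 * dot * nyn
                    dz = dz - 2.0 * dot * nzn
                else:
                    dx = rx
                    dy = ry
                    dz = rz
                    mat = m2
                    c_mus = mu_s[mat, wl]
                    c_g = g_tab[mat, wl]
                    c_mua = mu_a[mat, wl]
                    c_n = n_tab[mat, wl]
                    c_rho = rho_R[mat, W - 1]
                px = px + _NUDGE * dx
                py = py + _NUDGE * dy
                pz = pz + _NUDGE * dz
                continue

            # (1) Raman check
            u6, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
            if u6 < c_rho:
                j = int(np.searchsorted(rho_R[mat], u6, side="right"))
                if not has_raman:
                    raman_depth = pz
                has_raman = True
                wl = j
                c_mus = mu_s[mat, wl]
                c_g = g_tab[mat, wl]
                c_mua = mu_a[mat, wl]
                c_n = n_tab[mat, wl]
                c_rho = rho_R[mat, W - 1]

            # (2) free path and angles
            u1, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
            u2, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
            u3, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
            l = -math.log1p(-u1) / c_mus
            phi = 2.0 * math.pi * u2
            ct0 = _hg_cos(u3, c_g)
            st0 = math.sqrt(1.0 - ct0 * ct0)
            sphi, cphi = _sincos(phi)
            dx, dy, dz = _rotate(dx, dy, dz, ct0, st0, cphi, sphi)

            # (3)/(4) travel, interfaces, roulette
            absorbed = False
            while True:
                found, t, nxn, nyn, nzn, mb, m2 = _first_interface(
                    geom_kind, labels, uniform, z_runs, pitch, ox, oy, oz,
                    z_edges, layer_mats, hx, hy, px, py, pz, dx, dy, dz, l)
                mua = c_mua
                if not found:
                    px = px + l * dx
                    py = py + l * dy
                    pz = pz + l * dz
                    u4, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                    # 1 - e^-x < x: skip expm1 whenever u4 >= mua*l
                    absorbed = u4 < mua * l and u4 < -math.expm1(-mua * l)
                    break
                px = px + t * dx
                py = py + t * dy
                pz = pz + t * dz
                u4, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                if u4 < mua * t and u4 < -math.expm1(-mua * t):
                    absorbed = True
                    break
                n2 = 1.0 if m2 == 0 else n_tab[m2, wl]
                u7, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                R, rx, ry, rz = _fresnel_refract(dx, dy, dz, nxn, nyn, nzn,
                                                 c_n, n2)
                if u7 < R:
                    dot = dx * nxn + dy * nyn + dz * nzn
                    dx = dx - 2.0 * dot * nxn
                    dy = dy - 2.0 * dot * nyn
                    dz = dz - 2.0 * dot * nzn
                    px = px + _NUDGE * dx
                    py = py + _NUDGE * dy
                    pz = pz + _NUDGE * dz
                else:
                    dx = rx
                    dy = ry
                    dz = rz
                    px = px + _NUDGE * dx
                    py = py + _NUDGE * dy
                    pz = pz + _NUDGE * dz
                    if m2 == 0:
                        mat = 0
                        break
                    mat = m2
                    c_mus = mu_s[mat, wl]
                    c_g = g_tab[mat, wl]
                    c_mua = mu_a[mat, wl]
                    c_n = n_tab[mat, wl]
                    c_rho = rho_R[mat, W - 1]
                u1, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                l = -math.log1p(-u1) / c_mus

            if absorbed:
                # (5) fluorescence branch
                u5, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                if u5 >= rho_F[mat, W - 1]:
                    state = ABSORBED
                    break
                wl = int(np.searchsorted(rho_F[mat], u5, side="right"))
                c_mus = mu_s[mat, wl]
                c_g = g_tab[mat, wl]
                c_mua = mu_a[mat, wl]
                c_n = n_tab[mat, wl]
                c_rho = rho_R[mat, W - 1]
                has_fluor = True
                ua, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                ub, s0, s1, s2, s3 = _draw(stream, use_stream, cursor, s0, s1, s2, s3)
                ct = 2.0 * ua - 1.0
                st = math.sqrt(max(0.0, 1.0 - ct * ct))
                sf, cf = _sincos(2.0 * math.pi * ub)
                dx = st * cf
                dy = st * sf
                dz = ct

        out_state[i] = state
        out_x[i] = px
        out_y[i] = py
        out_z[i] = pz
        out_ux[i] = dx
        out_uy[i] = dy
        out_uz[i] = dz
        out_wl[i] = wl
        out_raman[i] = has_raman
        out_fluor[i] = has_fluor
        out_rdepth[i] = raman_depth
        out_iters[i] = it
    return cursor[0]


_EMPTY_LABELS = np.zeros((1, 1, 1), dtype=np.int64)
_EMPTY_EDGES = np.zeros(2, dtype=np.float64)
_EMPTY_MATS = np.zeros(1, dtype=np.int64)


def run_batch(geometry, table, source, n_photons, max_iterations, seed,
              stream=None):
    """Python-facing wrapper: marshal geometry/table/source into the kernel."""
    from .geometry import LayeredGeometry, VoxelGeometry

    if isinstance(geometry, VoxelGeometry):
        geom_kind = GEOM_VOXEL
        labels = geometry.labels
        uniform = geometry.uniform
        z_runs = (geometry.z_runs if geometry.z_runs is not None
                  else np.empty(0, dtype=np.int64))
        pitch = geometry.pitch
        ox, oy, oz = geometry.origin
        z_edges, layer_mats = _EMPTY_EDGES, _EMPTY_MATS
        hx = hy = math.inf
    elif isinstance(geometry, LayeredGeometry):
        geom_kind = GEOM_LAYERED
        labels, pitch = _EMPTY_LABELS, 1.0
        uniform = False
        z_runs = np.empty(0, dtype=np.int64)
        ox = oy = oz = 0.0
        z_edges = geometry.z_edges
        layer_mats = geometry.layer_materials
        hx, hy = geometry.half_x, geometry.half_y
    else:
        raise TypeError(f"unsupported geometry {type(geometry)!r}")

    out = {
        "state": np.empty(n_photons, dtype=np.int64),
        "x": np.empty(n_photons), "y": np.empty(n_photons), "z": np.empty(n_photons),
        "ux": np.empty(n_photons), "uy": np.empty(n_photons), "uz": np.empty(n_photons),
        "wl_index": np.empty(n_photons, dtype=np.int64),
        "has_raman": np.empty(n_photons, dtype=np.bool_),
        "has_fluoresced": np.empty(n_photons, dtype=np.bool_),
        "raman_depth_mm": np.empty(n_photons),
        "n_iterations": np.empty(n_photons, dtype=np.int64),
    }
    stream_arr = (np.asarray(stream, dtype=np.float64) if stream is not None
                  else np.empty(0, dtype=np.float64))
    cos_cone = math.cos(math.radians(source.half_angle_deg))
    _run_batch(
        int(seed), int(n_photons),
        geom_kind, labels, uniform, z_runs,
        float(pitch), float(ox), float(oy), float(oz),
        np.ascontiguousarray(z_edges, dtype=np.float64),
        np.ascontiguousarray(layer_mats, dtype=np.int64),
        float(hx), float(hy),
        table.mu_s, table.mu_a, table.g, table.n, table.rho_R, table.rho_F,
        float(source.center_xy[0]), float(source.center_xy[1]),
        float(source.std_mm), float(source.radius_mm),
        cos_cone, source.half_angle_deg > 0.0,
        int(max_iterations), stream_arr,
        out["state"], out["x"], out["y"], out["z"],
        out["ux"], out["uy"], out["uz"], out["wl_index"],
        out["has_raman"], out["has_fluoresced"], out["raman_depth_mm"],
        out["n_iterations"],
    )
    return out
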