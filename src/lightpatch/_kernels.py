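"""Accelerated per-ray tracing kernels (numba).

These kernels implement exactly the same physics as the pure-Python paths in
:mod:`lightpatch.engine` (which remain the reference for pluggable taper
profiles); the power-law taper profile is inlined here for speed.

All positions in micrometres, directions are unit vectors, weights are power
fractions.  Splitting is deterministic two-branch: at every interface the
transmitted branch terminates (it is recorded or sent to a loss ledger) and
the reflected branch continues, so each ray is a single weighted path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# marching constants: floor step (um) and bracket-refinement iterations
_STEP_FLOOR = 0.02
_BISECT_ITERS = 48


@njit(cache=False)
def _radius(s, tip, base, length, p):
    if s <= 0.0:
        return tip
    if s >= length:
        return base
    return tip + (base - tip) * (s / length) ** p


@njit(cache=False)
def _slope(s, tip, base, length, p):
    if s <= 0.0 or s >= length:
        return 0.0
    return p * (base - tip) / length * (s / length) ** (p - 1.0)


@njit(cache=False)
def _fresnel_T(cos_i, n1, n2):
    """Unpolarized power transmittance; 0 at/beyond the critical angle."""
    sin_i2 = 1.0 - cos_i * cos_i
    if sin_i2 < 0.0:
        sin_i2 = 0.0
    s2 = (n1 / n2) * (n1 / n2) * sin_i2
    if s2 >= 1.0:
        return 0.0
    cos_t = np.sqrt(1.0 - s2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n2 * cos_i - n1 * cos_t) / (n2 * cos_i + n1 * cos_t)
    return 1.0 - 0.5 * (rs * rs + rp * rp)


@njit(cache=False)
def _g_cavity(x, y, z, tip, base, length, p):
    rho = np.sqrt(x * x + y * y)
    return rho - _radius(-z, tip, base, length, p)


@njit(cache=False)
def _g_fiber(x, y, z, d, tip, base, length, p):
    rho = np.sqrt(x * x + y * y)
    return _radius(-(z + d), tip, base, length, p) - rho


@njit(cache=False)
def trace_gap_kernel(
    dirs,
    weights,
    d,
    tip,
    base,
    length,
    p,
    n_air,
    n_patch,
    n_clad,
    max_depth,
    weight_cutoff,
):
    """Trace every emitted ray through the air cavity until it enters the patch.

    Emission origin is the retracted fiber tip apex (0, 0, -d).  Returns
    (n_exit, exit_pos, exit_dir, exit_w, ledger) where ledger holds
    [entered, fiber_return, escaped, pruned, depth_terminated].
    """
    n = dirs.shape[0]
    cap = n * max_depth
    exit_pos = np.empty((cap, 3))
    exit_dir = np.empty((cap, 3))
    exit_w = np.empty(cap)
    ledger = np.zeros(5)
    z_min = -(length + d)
    t_max = 4.0 * (length + d + 100.0)
    m = 0

    for i in range(n):
        px = 0.0
        py = 0.0
        pz = -d
        ux = dirs[i, 0]
        uy = dirs[i, 1]
        uz = dirs[i, 2]
        w = weights[i]
        cut = weight_cutoff * w  # cutoff is relative to the ray's initial weight
        depth = 0

        while True:
            # ---- march to the next surface --------------------------------
            t = 1e-7
            gx = px + t * ux
            gy = py + t * uy
            gz = pz + t * uz
            g_c_prev = _g_cavity(gx, gy, gz, tip, base, length, p)
            if gz <= -d:
                g_f_prev = _g_fiber(gx, gy, gz, d, tip, base, length, p)
            else:
                g_f_prev = -1.0e30
            z_prev = gz
            kind = -2  # -2: still marching
            hx = hy = hz = 0.0

            while t < t_max:
                ag_f = abs(g_f_prev) if g_f_prev > -1.0e29 else abs(g_c_prev)
                step = 0.3 * min(abs(g_c_prev), ag_f)
                if step < _STEP_FLOOR:
                    step = _STEP_FLOOR
                t_new = t + step
                x = px + t_new * ux
                y = py + t_new * uy
                z = pz + t_new * uz

                # exact plane crossings first
                if z >= 0.0 and uz > 0.0:
                    t_plane = (0.0 - pz) / uz
                    cx = px + t_plane * ux
                    cy = py + t_plane * uy
                    if np.sqrt(cx * cx + cy * cy) <= tip + 1e-9:
                        kind = 1  # cavity apex cap
                        hx, hy, hz = cx, cy, 0.0
                        break
                if d > 0.0 and z_prev > -d and z <= -d and uz < 0.0:
                    t_plane = (-d - pz) / uz
                    cx = px + t_plane * ux
                    cy = py + t_plane * uy
                    if np.sqrt(cx * cx + cy * cy) <= tip + 1e-9:
                        kind = 3  # retracted fiber tip cap
                        hx, hy, hz = cx, cy, -d
                        break
                if z <= z_min:
                    kind = -1  # escaped through the closed shaft annulus
                    break

                g_c = _g_cavity(x, y, z, tip, base, length, p)
                if z <= -d:
                    g_f = _g_fiber(x, y, z, d, tip, base, length, p)
                else:
                    g_f = -1.0e30

                if g_c >= 0.0:
                    lo = t
                    hi = t_new
                    for _ in range(_BISECT_ITERS):
                        mid = 0.5 * (lo + hi)
                        if (
                            _g_cavity(px + mid * ux, py + mid * uy, pz + mid * uz, tip, base, length, p)
                            >= 0.0
                        ):
                            hi = mid
                        else:
                            lo = mid
                    kind = 0  # cavity wall
                    hx = px + hi * ux
                    hy = py + hi * uy
                    hz = pz + hi * uz
                    break
                if g_f >= 0.0:
                    lo = t if g_f_prev > -1.0e29 else (-d - pz) / uz
                    hi = t_new
                    for _ in range(_BISECT_ITERS):
                        mid = 0.5 * (lo + hi)
                        zz = pz + mid * uz
                        if zz <= -d and (
                            _g_fiber(px + mid * ux, py + mid * uy, zz, d, tip, base, length, p) >= 0.0
                        ):
                            hi = mid
                        else:
                            lo = mid
                    kind = 2  # retracted fiber wall
                    hx = px + hi * ux
                    hy = py + hi * uy
                    hz = pz + hi * uz
                    break

                t = t_new
                g_c_prev = g_c
                g_f_prev = g_f
                z_prev = z

            if kind == -2 or kind == -1:
                ledger[2] += w
                break

            # ---- interface normal, pointing into the air region -----------
            if kind == 0:
                rho = np.sqrt(hx * hx + hy * hy)
                slope = _slope(-hz, tip, base, length, p)
                nx = -hx / rho
                ny = -hy / rho
                nz = -slope
            elif kind == 1:
                nx, ny, nz = 0.0, 0.0, -1.0
            elif kind == 2:
                rho = np.sqrt(hx * hx + hy * hy)
                slope = _slope(-(hz + d), tip, base, length, p)
                nx = hx / rho
                ny = hy / rho
                nz = slope
            else:  # kind == 3
                nx, ny, nz = 0.0, 0.0, 1.0
            norm = np.sqrt(nx * nx + ny * ny + nz * nz)
            nx /= norm
            ny /= norm
            nz /= norm

            cos_i = -(ux * nx + uy * ny + uz * nz)
            if cos_i < 0.0:
                # grazing numerical corner: flip to keep the normal incident-side
                nx, ny, nz = -nx, -ny, -nz
                cos_i = -cos_i
            if cos_i > 1.0:
                cos_i = 1.0

            n2 = n_patch if kind <= 1 else n_clad
            T = _fresnel_T(cos_i, n_air, n2)

            if T > 0.0:
                eta = n_air / n2
                k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
                sq = np.sqrt(k)
                tx = eta * ux + (eta * cos_i - sq) * nx
                ty = eta * uy + (eta * cos_i - sq) * ny
                tz = eta * uz + (eta * cos_i - sq) * nz
                tn = np.sqrt(tx * tx + ty * ty + tz * tz)
                if kind <= 1:
                    exit_pos[m, 0] = hx
                    exit_pos[m, 1] = hy
                    exit_pos[m, 2] = hz
                    exit_dir[m, 0] = tx / tn
                    exit_dir[m, 1] = ty / tn
                    exit_dir[m, 2] = tz / tn
                    exit_w[m] = w * T
                    ledger[0] += w * T
                    m += 1
                else:
                    # power re-entering the retracted fiber is not re-guided
                    ledger[1] += w * T

            w *= 1.0 - T
            depth += 1
            if w <= cut:
                ledger[3] += w
                break
            if depth >= max_depth:
                ledger[4] += w
                break
            # reflected branch continues; restart a hair inside the air region
            ux = ux + 2.0 * cos_i * nx
            uy = uy + 2.0 * cos_i * ny
            uz = uz + 2.0 * cos_i * nz
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= un
            uy /= un
            uz /= un
            px = hx + 1e-6 * nx
            py = hy + 1e-6 * ny
            pz = hz + 1e-6 * nz

    return m, exit_pos, exit_dir, exit_w, ledger


@njit(cache=False)
def transport_slab_kernel(
    pos,
    dirs,
    weights,
    half_t,
    r_edge,
    n_patch,
    n_top,
    n_bottom,
    max_depth,
    weight_cutoff,
    ideal_interfaces,
    single_pass,
):
    """Straight-line slab transport with Fresnel/TIR at top, bottom and edge.

    Slab: |y| <= half_t, cylindrical edge x^2 + z^2 <= r_edge^2 (all um).
    Top (+y) faces ``n_top`` (air), bottom (-y) faces ``n_bottom`` (tissue),
    the edge faces ``n_top``.  Returns (n_exit, side, exit_pos, exit_angle,
    exit_w, ledger) with side codes 0=tissue, 1=air, 2=edge and ledger
    [exited, pruned, depth_terminated, stopped_single_pass].

    ``ideal_interfaces`` replaces Fresnel with T=1 below the critical angle
    and 0 beyond; ``single_pass`` terminates each path after its first
    surface event.  Both are oracle/test modes.
    """
    n = pos.shape[0]
    cap = n * max_depth
    out_side = np.empty(cap, dtype=np.int8)
    out_pos = np.empty((cap, 3))
    out_ang = np.empty(cap)
    out_w = np.empty(cap)
    ledger = np.zeros(4)
    m = 0

    for i in range(n):
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        ux, uy, uz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        w = weights[i]
        cut = weight_cutoff * w
        depth = 0
        while True:
            # nearest surface
            t_best = 1.0e30
            surf = -1
            if uy > 0.0:
                t_try = (half_t - py) / uy
                if 1e-9 < t_try < t_best:
                    t_best = t_try
                    surf = 1
            elif uy < 0.0:
                t_try = (-half_t - py) / uy
                if 1e-9 < t_try < t_best:
                    t_best = t_try
                    surf = 0
            a = ux * ux + uz * uz
            if a > 1e-16:
                b = 2.0 * (px * ux + pz * uz)
                c = px * px + pz * pz - r_edge * r_edge
                disc = b * b - 4.0 * a * c
                if disc > 0.0:
                    t_try = (-b + np.sqrt(disc)) / (2.0 * a)
                    if 1e-9 < t_try < t_best:
                        t_best = t_try
                        surf = 2
            if surf < 0:
                ledger[1] += w  # degenerate axial ray; treat as pruned
                break

            hx = px + t_best * ux
            hy = py + t_best * uy
            hz = pz + t_best * uz

            if surf == 0:
                nx, ny, nz = 0.0, 1.0, 0.0  # into the patch
                n_out = n_bottom
            elif surf == 1:
                nx, ny, nz = 0.0, -1.0, 0.0
                n_out = n_top
            else:
                rho = np.sqrt(hx * hx + hz * hz)
                nx, ny, nz = -hx / rho, 0.0, -hz / rho
                n_out = n_top

            cos_i = -(ux * nx + uy * ny + uz * nz)
            if cos_i < 0.0:
                cos_i = 0.0
            if cos_i > 1.0:
                cos_i = 1.0

            sin_t = n_patch * np.sqrt(max(0.0, 1.0 - cos_i * cos_i)) / n_out
            if ideal_interfaces:
                T = 1.0 if sin_t < 1.0 else 0.0
            else:
                T = _fresnel_T(cos_i, n_patch, n_out)

            if T > 0.0:
                out_side[m] = surf
                out_pos[m, 0] = hx
                out_pos[m, 1] = hy
                out_pos[m, 2] = hz
                out_ang[m] = np.degrees(np.arcsin(min(sin_t, 1.0)))
                out_w[m] = w * T
                ledger[0] += w * T
                m += 1

            w *= 1.0 - T
            depth += 1
            if single_pass:
                ledger[3] += w
                break
            if w <= cut:
                ledger[1] += w
                break
            if depth >= max_depth:
                ledger[2] += w
                break
            ux = ux + 2.0 * cos_i * nx
            uy = uy + 2.0 * cos_i * ny
            uz = uz + 2.0 * cos_i * nz
            px, py, pz = hx, hy, hz

    return m, out_side, out_pos, out_ang, out_w, ledger
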