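"""Numba-compiled photon transport kernel.

Implements the same weighted-packet walk as
:func:`widefield_mc.transport.propagate` (exponential free paths,
Henyey-Greenstein deflections, MCML-style weight deposition, Russian
roulette, boundary sub-stepping, index-matched interfaces) over arrays of
launch states, with optional track-length recorders:

* a depth (z) fluence profile with direction-cosine sums, restricted to a
  central cylinder where the illumination beam is uniform;
* a (d, z) histogram in the plane perpendicular to a vessel axis, for
  under-vessel intensity columns;
* an (r, z) cylindrical histogram for radial fluence maps.

Geometry codes: 0 grey matter, 1 coverslip glass, 2 skull, 3 vessel
absorber; negative codes are exits (-1 top, -2 lateral, -3 bottom).
The kernel is deterministic for a given seed (single-threaded, Numba's
internal RNG).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# medium / status codes
M_GREY = 0
M_GLASS = 1
M_SKULL = 2
M_VESSEL = 3
OUT_TOP = -1
OUT_LAT = -2
OUT_BOT = -3

ST_ABSORBED = 1
ST_EXIT_TOP = 2
ST_EXIT_LAT = 3
ST_EXIT_BOT = 4
ST_KILLED = 5

# tally slots
T_LAUNCHED = 0
T_DEPOSITED = 1
T_EXIT_TOP = 2
T_EXIT_LAT = 3
T_EXIT_BOT = 4
T_ROULETTE = 5
T_CAP_KILLED = 6
T_CAP_COUNT = 7
N_TALLIES = 8

_EPS = 1e-12
_NUDGE = 1e-7
_BIG = 1e30


@njit(cache=True, inline="always")
def _ray_circle(px, py, ux, uy, r):
    a = ux * ux + uy * uy
    if a < 1e-20:
        return _BIG
    b = 2.0 * (px * ux + py * uy)
    c = px * px + py * py - r * r
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return _BIG
    sq = math.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    if t1 > _EPS:
        return t1
    t2 = (-b + sq) / (2.0 * a)
    if t2 > _EPS:
        return t2
    return _BIG


@njit(cache=True, inline="always")
def _medium(x, y, z, R, zmax, cs_r, cs_t, sk_t, v_nx, v_ny, v_off, v_r):
    rho = math.sqrt(x * x + y * y)
    if rho >= R:
        return OUT_LAT
    if z > zmax:
        return OUT_BOT
    if z < 0.0:
        if rho < cs_r:
            if z >= -cs_t:
                return M_GLASS
            return OUT_TOP
        if sk_t > 0.0 and z >= -sk_t:
            return M_SKULL
        return OUT_TOP
    for k in range(v_r.shape[0]):
        d = v_nx[k] * x + v_ny[k] * y - v_off[k]
        h = z - v_r[k]
        if d * d + h * h < v_r[k] * v_r[k]:
            return M_VESSEL
    return M_GREY


@njit(cache=True, inline="always")
def _boundary(x, y, z, ux, uy, uz, med,
              R, zmax, cs_r, cs_t, sk_t, v_nx, v_ny, v_off, v_r):
    d = _ray_circle(x, y, ux, uy, R)
    if med == M_GREY:
        if uz > _EPS:
            t = (zmax - z) / uz
            if t > _EPS and t < d:
                d = t
        elif uz < -_EPS:
            t = -z / uz
            if t > _EPS and t < d:
                d = t
        for k in range(v_r.shape[0]):
            pd = v_nx[k] * x + v_ny[k] * y - v_off[k]
            ph = z - v_r[k]
            ud = v_nx[k] * ux + v_ny[k] * uy
            t = _ray_circle(pd, ph, ud, uz, v_r[k])
            if t < d:
                d = t
    elif med == M_GLASS:
        if uz > _EPS:
            t = -z / uz
            if t > _EPS and t < d:
                d = t
        elif uz < -_EPS:
            t = (-cs_t - z) / uz
            if t > _EPS and t < d:
                d = t
        t = _ray_circle(x, y, ux, uy, cs_r)
        if t < d:
            d = t
    elif med == M_SKULL:
        if uz > _EPS:
            t = -z / uz
            if t > _EPS and t < d:
                d = t
        elif uz < -_EPS:
            t = (-sk_t - z) / uz
            if t > _EPS and t < d:
                d = t
        if cs_r > 0.0:
            t = _ray_circle(x, y, ux, uy, cs_r)
            if t < d:
                d = t
    return d


@njit(cache=True)
def run_kernel(
    seed,
    x0, y0, z0, ux0, uy0, uz0, w0,
    # geometry
    R, zmax, cs_r, cs_t, sk_t,
    # optics: grey matter (selected wavelength) and skull
    gm_mua, gm_mus, gm_g, sk_mua, sk_mus, sk_g,
    # vessels (normal to axis, offset, radius)
    v_nx, v_ny, v_off, v_r,
    # z-profile recorder (track length within rho < prof_rmax)
    pitch, prof_rmax, fl_z, fl_z_cos,
    # (d, z) recorder about an axis through the origin
    rec_dz, dz_ax, dz_ay, dz_dmax, dz_yhalf, fl_dz,
    # (r, z) recorder
    rec_rz, rz_rmax, fl_rz,
    # termination
    w_min, p_surv, max_steps,
    # per-photon outputs
    status, exit_x, exit_y, exit_ux, exit_uy, exit_uz, exit_w,
    tallies,
):
    np.random.seed(seed)
    n = x0.shape[0]
    nz = fl_z.shape[0]
    dz_nx = -dz_ay  # in-plane normal to the (d,z) recorder axis
    dz_ny = dz_ax
    nd = fl_dz.shape[0]
    nr = fl_rz.shape[0]

    for i in range(n):
        x = x0[i]; y = y0[i]; z = z0[i]
        ux = ux0[i]; uy = uy0[i]; uz = uz0[i]
        w = w0[i]
        tallies[T_LAUNCHED] += w
        ex = x; ey = y  # last upward crossing of z = 0
        tau = -math.log(np.random.random())
        st = 0
        steps = 0

        while st == 0:
            steps += 1
            if steps > max_steps:
                st = ST_KILLED
                tallies[T_CAP_KILLED] += w
                tallies[T_CAP_COUNT] += 1.0
                break
            med = _medium(x, y, z, R, zmax, cs_r, cs_t, sk_t,
                          v_nx, v_ny, v_off, v_r)
            if med < 0:
                if med == OUT_TOP:
                    st = ST_EXIT_TOP
                    tallies[T_EXIT_TOP] += w
                elif med == OUT_LAT:
                    st = ST_EXIT_LAT
                    tallies[T_EXIT_LAT] += w
                else:
                    st = ST_EXIT_BOT
                    tallies[T_EXIT_BOT] += w
                break
            if med == M_VESSEL:
                tallies[T_DEPOSITED] += w
                w = 0.0
                st = ST_ABSORBED
                break

            if med == M_GREY:
                mua = gm_mua; mus = gm_mus; g = gm_g
            elif med == M_SKULL:
                mua = sk_mua; mus = sk_mus; g = sk_g
            else:
                mua = 0.0; mus = 0.0; g = 0.0
            mut = mua + mus

            db = _boundary(x, y, z, ux, uy, uz, med,
                           R, zmax, cs_r, cs_t, sk_t,
                           v_nx, v_ny, v_off, v_r) + _NUDGE
            if mut > 0.0:
                s = tau / mut
            else:
                s = _BIG
            interact = s < db
            step = s if interact else db

            if med == M_GREY:
                # depth-profile recorder: walk the z bins this segment
                # crosses, iterating bin indices so progress is guaranteed
                if -_EPS < uz < _EPS:
                    iz = int(math.floor(z / pitch))
                    tm = 0.5 * step
                    xm = x + ux * tm
                    ym = y + uy * tm
                    if 0 <= iz < nz and xm * xm + ym * ym < prof_rmax * prof_rmax:
                        fl_z[iz] += w * step
                        fl_z_cos[iz] += w * step * uz
                else:
                    inv = 1.0 / uz
                    iz = int(math.floor(z / pitch))
                    t = 0.0
                    while True:
                        if uz > 0.0:
                            tb = ((iz + 1) * pitch - z) * inv
                        else:
                            tb = (iz * pitch - z) * inv
                        tn = tb if tb < step else step
                        seg = tn - t
                        if seg > 0.0:
                            tm = 0.5 * (t + tn)
                            xm = x + ux * tm
                            ym = y + uy * tm
                            if 0 <= iz < nz and xm * xm + ym * ym < prof_rmax * prof_rmax:
                                fl_z[iz] += w * seg
                                fl_z_cos[iz] += w * seg * uz
                        if tn >= step:
                            break
                        t = tn
                        iz += 1 if uz > 0.0 else -1
                # auxiliary recorders: midpoint sub-steps of length <= pitch
                if rec_dz or rec_rz:
                    nseg = int(step / pitch) + 1
                    ds = step / nseg
                    for k2 in range(nseg):
                        tm = (k2 + 0.5) * ds
                        xm = x + ux * tm
                        ym = y + uy * tm
                        zm = z + uz * tm
                        iz = int(math.floor(zm / pitch))
                        if iz < 0 or iz >= nz:
                            continue
                        if rec_dz:
                            along = dz_ax * xm + dz_ay * ym
                            if -dz_yhalf <= along <= dz_yhalf:
                                dd = dz_nx * xm + dz_ny * ym
                                # bins are centred on d = 0 (central bin = the
                                # one-voxel column under the axis)
                                idd = int(math.floor((dd + dz_dmax + 0.5 * pitch) / pitch))
                                if 0 <= idd < nd:
                                    fl_dz[idd, iz] += w * ds
                        if rec_rz:
                            rr = math.sqrt(xm * xm + ym * ym)
                            ir = int(rr / pitch)
                            if ir < nr:
                                fl_rz[ir, iz] += w * ds

            # track last upward surface crossing for the exit position
            if uz < 0.0 and z > 0.0 and z + uz * step <= 0.0:
                tt = -z / uz
                ex = x + ux * tt
                ey = y + uy * tt

            x += ux * step
            y += uy * step
            z += uz * step

            if interact:
                tallies[T_DEPOSITED] += w * mua / mut
                w *= mus / mut
                if w <= 0.0:  # fully absorbing medium
                    st = ST_ABSORBED
                    break
                # Henyey-Greenstein deflection
                u = np.random.random()
                if abs(g) < 1e-12:
                    ct = 2.0 * u - 1.0
                else:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                stheta = math.sqrt(1.0 - ct * ct)
                phi = 2.0 * math.pi * np.random.random()
                cp = math.cos(phi)
                sp = math.sin(phi)
                if abs(uz) > 0.99999:
                    nx_ = stheta * cp
                    ny_ = stheta * sp
                    nz_ = ct if uz > 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nx_ = stheta * (ux * uz * cp - uy * sp) / den + ux * ct
                    ny_ = stheta * (uy * uz * cp + ux * sp) / den + uy * ct
                    nz_ = -stheta * cp * den + uz * ct
                inv = 1.0 / math.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
                ux = nx_ * inv
                uy = ny_ * inv
                uz = nz_ * inv
                tau = -math.log(np.random.random())
                if w < w_min:
                    if np.random.random() < p_surv:
                        boosted = w / p_surv
                        tallies[T_ROULETTE] += w - boosted
                        w = boosted
                    else:
                        tallies[T_ROULETTE] += w
                        w = 0.0
                        st = ST_ABSORBED
                        break
            else:
                tau -= step * mut
                if tau <= 0.0:
                    tau = 1e-12

        status[i] = st
        exit_x[i] = ex
        exit_y[i] = ey
        exit_ux[i] = ux
        exit_uy[i] = uy
        exit_uz[i] = uz
        exit_w[i] = w
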