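"""Compiled (numba) production transport kernel.

This module re-implements the photon walk of ``optomc.reference`` as a
single njit-compiled loop over photons.  The floating-point expressions and
the per-photon deviate order are kept textually identical to the reference
engine and to the primitives in ``optomc.optics`` — the engine-equivalence
oracle asserts bit-for-bit agreement, so any edit here must be mirrored
there (and vice versa).

Layout notes
------------
* Geometry arrives as the flat arrays produced by
  ``LayeredGeometry.as_arrays()`` (region r_hi already clamped to the
  domain radius).
* ``src_params`` encodes the source: disc -> [diameter, cx, cy, cz];
  fiber -> [core_radius, sigma, tx, ty, tz, cos_max].  Emission axis is +z.
* Tallies are returned in a flat float64 vector, absorbed weight per medium
  in a second vector, fate and step count per photon in int64 vectors.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .rng import next_state, photon_state, state_to_unit

SRC_DISC = 0
SRC_FIBER = 1

# tally vector layout
T_ESCAPED = 0
T_BACK = 1
T_EDGE = 2
T_ROULETTE = 3
T_CAPPED_W = 4
T_CLIPPED = 5
T_CAPPED_N = 6
N_TALLY = 7

TWO_PI = 2.0 * math.pi


@njit(cache=False)
def _cos_sin(phi):
    """Mirror of optics.cos_sin_azimuth (avoids sincos fusion)."""
    c = math.cos(phi)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    if phi > math.pi:
        s = -s
    return c, s


@njit(cache=False)
def _rotate(ux, uy, uz, cos_theta, phi):
    """Mirror of optics.rotate_direction (same branch, same normalisation)."""
    sin_theta = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cos_phi, sin_phi = _cos_sin(phi)
    tmp = (1.0 - uz) * (1.0 + uz)
    if tmp <= 0.0:
        sign = 1.0 if uz >= 0.0 else -1.0
        nx = sin_theta * cos_phi
        ny = sign * sin_theta * sin_phi
        nz = sign * cos_theta
    else:
        denom = math.sqrt(tmp)
        nx = sin_theta * (ux * uz * cos_phi - uy * sin_phi) / denom + ux * cos_theta
        ny = sin_theta * (uy * uz * cos_phi + ux * sin_phi) / denom + uy * cos_theta
        nz = -sin_theta * cos_phi * denom + uz * cos_theta
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=False)
def _hg_cos(g, u):
    """Mirror of optics.sample_hg_cos."""
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cos_t > 1.0:
        cos_t = 1.0
    elif cos_t < -1.0:
        cos_t = -1.0
    return cos_t


@njit(cache=False)
def _fresnel(n1, n2, cos_incident):
    """Mirror of optics.fresnel_unpolarized (callers guarantee cos > 0)."""
    if n1 == n2:
        return 0.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_incident * cos_incident))
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_incident - n2 * cos_t) / (n1 * cos_incident + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_incident) / (n1 * cos_t + n2 * cos_incident)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=False)
def _ray_exit(x, y, z, dx, dy, dz, z_lo, z_hi, r_lo, r_hi):
    """Mirror of geometry._ray_region_exit."""
    best = math.inf
    surf = 0
    if dz > 0.0:
        t = (z_hi - z) / dz
        if t < best:
            best = t
            surf = 0
    elif dz < 0.0:
        t = (z_lo - z) / dz
        if t < best:
            best = t
            surf = 1
    a = dx * dx + dy * dy
    if a > 0.0:
        b = 2.0 * (x * dx + y * dy)
        c = x * x + y * y
        if math.isfinite(r_hi):
            disc = b * b - 4.0 * a * (c - r_hi * r_hi)
            if disc > 0.0:
                t = (-b + math.sqrt(disc)) / (2.0 * a)
                if 0.0 < t < best:
                    best = t
                    surf = 2
        if r_lo > 0.0 and b < 0.0:
            disc = b * b - 4.0 * a * (c - r_lo * r_lo)
            if disc > 0.0:
                t = (-b - math.sqrt(disc)) / (2.0 * a)
                if 0.0 < t < best:
                    best = t
                    surf = 3
    if best < 0.0:
        best = 0.0
    return best, surf


@njit(cache=False)
def _locate(
    x, y, z, reg_z_lo, reg_z_hi, reg_r_lo, reg_r_hi, domain_radius, z_min, z_max
):
    """Mirror of LayeredGeometry.locate (domain-bounded)."""
    r2 = x * x + y * y
    if r2 >= domain_radius * domain_radius or z < z_min or z >= z_max:
        return -1
    for k in range(reg_z_lo.shape[0]):
        if reg_z_lo[k] <= z < reg_z_hi[k]:
            if reg_r_lo[k] * reg_r_lo[k] <= r2 < reg_r_hi[k] * reg_r_hi[k]:
                return k
    return -1


@njit(cache=False)
def _deposit(values, dr, nr, z0, dz, nz, x0, y0, zz0, x1, y1, zz1, w, cuts):
    """Mirror of reference._deposit_uniform with a preallocated cut buffer."""
    dx = x1 - x0
    dy = y1 - y0
    dzz = zz1 - zz0
    length = math.sqrt(dx * dx + dy * dy + dzz * dzz)
    if length == 0.0 or w == 0.0:
        return 0.0
    n = 2
    cuts[0] = 0.0
    cuts[1] = 1.0
    if dzz != 0.0:
        zmin = zz0 if zz0 < zz1 else zz1
        zmax = zz0 if zz0 > zz1 else zz1
        k_lo = int(math.floor((zmin - z0) / dz)) + 1
        k_hi = int(math.floor((zmax - z0) / dz))
        if k_lo < 0:
            k_lo = 0
        if k_hi > nz:
            k_hi = nz
        for k in range(k_lo, k_hi + 1):
            t = (z0 + k * dz - zz0) / dzz
            if 0.0 < t < 1.0:
                cuts[n] = t
                n += 1
    a = dx * dx + dy * dy
    if a > 0.0:
        b = 2.0 * (x0 * dx + y0 * dy)
        c = x0 * x0 + y0 * y0
        r0sq = c
        r1sq = c + b + a
        rmaxsq = r0sq if r0sq > r1sq else r1sq
        tstar = -b / (2.0 * a)
        if 0.0 < tstar < 1.0:
            rminsq = c - (b * b) / (4.0 * a)
            if rminsq < 0.0:
                rminsq = 0.0
        else:
            rminsq = r0sq if r0sq < r1sq else r1sq
        j_lo = int(math.floor(math.sqrt(rminsq) / dr)) + 1
        j_hi = int(math.floor(math.sqrt(rmaxsq) / dr))
        if j_lo < 1:
            j_lo = 1
        if j_hi > nr:
            j_hi = nr
        for j in range(j_lo, j_hi + 1):
            re = j * dr
            disc = b * b - 4.0 * a * (c - re * re)
            if disc > 0.0:
                sq = math.sqrt(disc)
                t1 = (-b - sq) / (2.0 * a)
                t2 = (-b + sq) / (2.0 * a)
                if 0.0 < t1 < 1.0:
                    cuts[n] = t1
                    n += 1
                if 0.0 < t2 < 1.0:
                    cuts[n] = t2
                    n += 1
    # insertion sort (n is small; already mostly ordered)
    for i in range(1, n):
        key = cuts[i]
        j = i - 1
        while j >= 0 and cuts[j] > key:
            cuts[j + 1] = cuts[j]
            j -= 1
        cuts[j + 1] = key
    clipped = 0.0
    for i in range(n - 1):
        t_lo = cuts[i]
        t_hi = cuts[i + 1]
        if t_hi <= t_lo:
            continue
        tm = 0.5 * (t_lo + t_hi)
        xm = x0 + tm * dx
        ym = y0 + tm * dy
        zm = zz0 + tm * dzz
        sub = (t_hi - t_lo) * length
        rm = math.sqrt(xm * xm + ym * ym)
        ir = int(math.floor(rm / dr))
        iz = int(math.floor((zm - z0) / dz))
        if 0 <= ir < nr and 0 <= iz < nz:
            values[iz, ir] += w * sub
        else:
            clipped += w * sub
    return clipped


@njit(cache=False)
def run_kernel(
    n_photons,
    seed,
    src_type,
    src_params,
    med_n,
    med_mua,
    med_mus,
    med_g,
    reg_z_lo,
    reg_z_hi,
    reg_r_lo,
    reg_r_hi,
    reg_med,
    domain_radius,
    z_min,
    z_max,
    back_r,
    back_policy,
    back_refl,
    values,
    dr,
    nr,
    gz0,
    dz,
    nz,
    w_min,
    p_survive,
    step_cap,
    strict_terminate,
    tally,
    absorbed,
    fates,
    steps_out,
):
    cuts = np.empty(nz + 2 * nr + 8, dtype=np.float64)
    for i in range(n_photons):
        state = photon_state(seed, i)
        # ---- launch (deviate order mirrors sources.sample_*_launch) ----
        if src_type == SRC_DISC:
            state = next_state(state)
            u1 = state_to_unit(state)
            state = next_state(state)
            u2 = state_to_unit(state)
            r = 0.5 * src_params[0] * math.sqrt(u1)
            cphi, sphi = _cos_sin(TWO_PI * u2)
            x = src_params[1] + r * cphi
            y = src_params[2] + r * sphi
            z = src_params[3]
            if src_params[4] != 0.0:  # collimated pencil beam (oracle scenarios)
                ux, uy, uz = 0.0, 0.0, 1.0
            else:
                state = next_state(state)
                u3 = state_to_unit(state)
                state = next_state(state)
                u4 = state_to_unit(state)
                ux, uy, uz = _rotate(0.0, 0.0, 1.0, math.sqrt(1.0 - u3), TWO_PI * u4)
        else:
            rcore = src_params[0]
            sigma = src_params[1]
            while True:
                state = next_state(state)
                u1 = 1.0 - state_to_unit(state)
                state = next_state(state)
                u2 = state_to_unit(state)
                amp = sigma * math.sqrt(-2.0 * math.log(u1))
                cphi, sphi = _cos_sin(TWO_PI * u2)
                gx = amp * cphi
                gy = amp * sphi
                if gx * gx + gy * gy <= rcore * rcore:
                    break
            x = src_params[2] + gx
            y = src_params[3] + gy
            z = src_params[4]
            cos_max = src_params[5]
            state = next_state(state)
            u3 = state_to_unit(state)
            state = next_state(state)
            u4 = state_to_unit(state)
            ux, uy, uz = _rotate(0.0, 0.0, 1.0, 1.0 - u3 * (1.0 - cos_max), TWO_PI * u4)

        region = _locate(
            x, y, z, reg_z_lo, reg_z_hi, reg_r_lo, reg_r_hi, domain_radius, z_min, z_max
        )
        w = 1.0
        steps = 0
        fate = -1
        while True:
            if steps >= step_cap:
                tally[T_CAPPED_W] += w
                tally[T_CAPPED_N] += 1.0
                fate = 4
                break
            steps += 1
            m = reg_med[region]
            mu_a = med_mua[m]
            mu_s = med_mus[m]
            mu_t = mu_a + mu_s
            if mu_t > 0.0:
                state = next_state(state)
                s = -math.log(1.0 - state_to_unit(state)) / mu_t
            else:
                s = math.inf
            db, surf = _ray_exit(
                x, y, z, ux, uy, uz, reg_z_lo[region], reg_z_hi[region],
                reg_r_lo[region], reg_r_hi[region],
            )
            if s < db:
                nxp = x + s * ux
                nyp = y + s * uy
                nzp = z + s * uz
                tally[T_CLIPPED] += _deposit(
                    values, dr, nr, gz0, dz, nz, x, y, z, nxp, nyp, nzp, w, cuts
                )
                x, y, z = nxp, nyp, nzp
                ab = w * (mu_a / mu_t)
                w = w - ab
                absorbed[m] += ab
                if mu_s > 0.0:
                    state = next_state(state)
                    cos_t = _hg_cos(med_g[m], state_to_unit(state))
                    state = next_state(state)
                    phi = TWO_PI * state_to_unit(state)
                    ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                if w <= 0.0:
                    fate = 5
                    break
                if w < w_min:
                    if strict_terminate:
                        tally[T_ROULETTE] += w
                        fate = 0
                        break
                    w_before = w
                    state = next_state(state)
                    if state_to_unit(state) < p_survive:
                        w = w / p_survive
                        tally[T_ROULETTE] += w_before - w
                    else:
                        tally[T_ROULETTE] += w_before
                        fate = 0
                        break
            else:
                nxp = x + db * ux
                nyp = y + db * uy
                nzp = z + db * uz
                tally[T_CLIPPED] += _deposit(
                    values, dr, nr, gz0, dz, nz, x, y, z, nxp, nyp, nzp, w, cuts
                )
                x, y, z = nxp, nyp, nzp
                if surf == 0:
                    nx_, ny_, nz_ = 0.0, 0.0, 1.0
                elif surf == 1:
                    nx_, ny_, nz_ = 0.0, 0.0, -1.0
                else:
                    rr = math.sqrt(x * x + y * y)
                    if surf == 2:
                        nx_, ny_, nz_ = x / rr, y / rr, 0.0
                    else:
                        nx_, ny_, nz_ = -x / rr, -y / rr, 0.0
                eps = 1.0e-7
                neighbor = _locate(
                    x + eps * nx_, y + eps * ny_, z + eps * nz_,
                    reg_z_lo, reg_z_hi, reg_r_lo, reg_r_hi,
                    domain_radius, z_min, z_max,
                )
                if neighbor >= 0:
                    n1 = med_n[m]
                    n2 = med_n[reg_med[neighbor]]
                    if n1 == n2:
                        region = neighbor
                        continue
                    cos_i = ux * nx_ + uy * ny_ + uz * nz_
                    if cos_i <= 0.0:
                        refl = 1.0
                    else:
                        refl = _fresnel(n1, n2, cos_i)
                    state = next_state(state)
                    if state_to_unit(state) < refl:
                        ux = ux - 2.0 * cos_i * nx_
                        uy = uy - 2.0 * cos_i * ny_
                        uz = uz - 2.0 * cos_i * nz_
                    else:
                        eta = n1 / n2
                        sin2_t = eta * eta * (1.0 - cos_i * cos_i)
                        cos_t = math.sqrt(1.0 - sin2_t)
                        tx = eta * ux + (cos_t - eta * cos_i) * nx_
                        ty = eta * uy + (cos_t - eta * cos_i) * ny_
                        tz = eta * uz + (cos_t - eta * cos_i) * nz_
                        norm = math.sqrt(tx * tx + ty * ty + tz * tz)
                        ux, uy, uz = tx / norm, ty / norm, tz / norm
                        region = neighbor
                else:
                    rr2 = x * x + y * y
                    rd = domain_radius - 1.0e-9
                    if surf == 1 and z <= z_min + 1.0e-9:
                        if rr2 <= back_r * back_r:
                            if back_policy == 1:
                                state = next_state(state)
                                if state_to_unit(state) < back_refl:
                                    uz = -uz
                                    continue
                            tally[T_BACK] += w
                            fate = 2
                        else:
                            tally[T_ESCAPED] += w
                            fate = 1
                    elif (surf == 0 and z >= z_max - 1.0e-9) or (surf == 2 and rr2 >= rd * rd):
                        tally[T_ESCAPED] += w
                        fate = 1
                    else:
                        tally[T_EDGE] += w
                        fate = 3
                    break
        fates[i] = fate
        steps_out[i] = steps
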