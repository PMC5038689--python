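"""Numba core of the photon-transport simulation.

One call simulates every photon of a single scan pixel: hyperboloid
(focused Gaussian) launch, exponential free paths through the layered
medium with an embedded tumour cylinder, absorption by weight
attenuation, HG / Gegenbauer scattering with Doppler accumulation on
blood events, importance splitting of high-shift photons, Russian
roulette, and the confocal acceptance gate at the top surface.

Geometry: z = 0 at the skin surface, positive downward; the beam axis is
the z-axis of the pixel frame (the tumour centre is passed relative to
the current scan position).  Lengths in mm, speeds in mm/s, Doppler
shifts in Hz.

Heterogeneity is handled with the optical-depth method: a free path is
sampled as an optical depth tau = -ln(u) and consumed region by region,
which is exact for piecewise-constant coefficients, so steps never need
to be truncated or re-sampled at layer or cylinder boundaries.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .phase_functions import hg_cos_from_u

# stack slot layout: x, y, z, dx, dy, dz, w, shift, split_factor
_STACK_CAP = 16384
_MAX_SUBSTEPS = 2_000_000


@njit(cache=True, fastmath=True)
def _scatter_dir(dx, dy, dz, mu, phi):
    """Rotate a unit direction by deflection cosine mu and azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - mu * mu))
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(dz) > 0.99999:
        ndx = sint * cosp
        ndy = sint * sinp
        ndz = mu if dz > 0.0 else -mu
    else:
        den = math.sqrt(1.0 - dz * dz)
        ndx = sint * (dx * dz * cosp - dy * sinp) / den + dx * mu
        ndy = sint * (dy * dz * cosp + dx * sinp) / den + dy * mu
        ndz = -sint * cosp * den + dz * mu
    inv = 1.0 / math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    return ndx * inv, ndy * inv, ndz * inv


@njit(cache=True, fastmath=True)
def _gk_cos_fast(u, inv_alpha, t_lo, t_span, one_plus_g2, inv_2g, alpha_is_one):
    """Gegenbauer deflection cosine with the normalisation constants
    precomputed; the alpha = 1 case avoids the pow call entirely."""
    tpow = t_lo + u * t_span
    if alpha_is_one:
        t = 1.0 / tpow
    else:
        t = tpow ** (-inv_alpha)
    mu = (one_plus_g2 - t) * inv_2g
    if mu > 1.0:
        mu = 1.0
    elif mu < -1.0:
        mu = -1.0
    return mu


@njit(cache=True, fastmath=True)
def _accept_ray(x, y, dx, dy, dz, na, lens_h, clear_r2, zf, ap_eff2):
    """Confocal gate for a ray exiting the surface at (x, y) with upward
    direction (dz < 0): NA cone, clear aperture at the lens plane, and
    apparent origin within the aperture-conjugate disc at the focal plane."""
    uz = -dz
    if uz <= 0.0:
        return False
    sin2 = dx * dx + dy * dy
    if sin2 > na * na:
        return False
    t = lens_h / uz
    xl = x + dx * t
    yl = y + dy * t
    if xl * xl + yl * yl > clear_r2:
        return False
    tb = zf / uz
    xo = x - dx * tb
    yo = y - dy * tb
    if xo * xo + yo * yo > ap_eff2:
        return False
    return True


@njit(cache=True, fastmath=True)
def run_pixel_kernel(
    seed,
    n_photons,
    # medium
    layer_bot,
    mua_h,
    mus_static_h,
    musb_h,
    speeds_h,
    mua_t,
    mus_static_t,
    musb_t,
    speeds_t,
    has_tumour,
    tum_x,
    tum_y,
    tum_r,
    tum_z0,
    tum_z1,
    hg_g,
    gk_alpha,
    gk_g,
    n_ref,
    wavelength_nm,
    # beam / detection
    zf,
    waist_sigma,
    lens_sigma,
    lens_h,
    na,
    clear_r,
    ap_eff,
    # transport config
    splitting_on,
    split_value,
    split_mult,
    max_split,
    class_bias,
    rl_thresh,
    rl_surv,
    imp_depth,
    imp_surv,
    escape_r,
    # outputs
    out_w,
    out_f,
):
    np.random.seed(seed)
    depth = layer_bot[len(layer_bot) - 1]
    # precomputed Gegenbauer sampling constants
    gk_t_lo = (1.0 + gk_g) ** (-2.0 * gk_alpha)
    gk_t_span = (1.0 - gk_g) ** (-2.0 * gk_alpha) - gk_t_lo
    gk_inv_alpha = 1.0 / gk_alpha
    gk_one_plus_g2 = 1.0 + gk_g * gk_g
    gk_inv_2g = 1.0 / (2.0 * gk_g)
    gk_alpha_is_one = abs(gk_alpha - 1.0) < 1.0e-12
    # per-layer interaction coefficients
    nlay = len(layer_bot)
    mut_h = np.empty(nlay)
    mut_t = np.empty(nlay)
    mustot_h = np.empty(nlay)
    mustot_t = np.empty(nlay)
    for i in range(nlay):
        mustot_h[i] = mus_static_h[i] + musb_h[i, 0] + musb_h[i, 1] + musb_h[i, 2]
        mustot_t[i] = mus_static_t[i] + musb_t[i, 0] + musb_t[i, 1] + musb_t[i, 2]
        mut_h[i] = mua_h[i] + mustot_h[i]
        mut_t[i] = mua_t[i] + mustot_t[i]
    clear_r2 = clear_r * clear_r
    ap_eff2 = ap_eff * ap_eff
    esc_r2 = escape_r * escape_r
    tum_r2 = tum_r * tum_r
    inv_lambda_mm = 1.0 / (wavelength_nm * 1.0e-6)
    cap = out_w.shape[0]

    stack = np.empty((_STACK_CAP, 9))
    n_out = 0
    detected_w = 0.0
    detected_moment = 0.0
    absorbed = 0.0
    escaped = 0.0
    rl_kill = 0.0
    rl_gain = 0.0
    bias_net = 0.0
    top_exit_w = 0.0

    for _ in range(n_photons):
        # --- launch: lens-disc point aimed at a Gaussian waist point ---
        while True:
            lx = np.random.normal() * lens_sigma
            ly = np.random.normal() * lens_sigma
            if lx * lx + ly * ly <= clear_r2:
                break
        wx = np.random.normal() * waist_sigma
        wy = np.random.normal() * waist_sigma
        vx = wx - lx
        vy = wy - ly
        vz = zf + lens_h
        inv = 1.0 / math.sqrt(vx * vx + vy * vy + vz * vz)
        d0x = vx * inv
        d0y = vy * inv
        d0z = vz * inv
        # intersect with the surface z = 0 (lens plane at z = -lens_h)
        t0 = lens_h / d0z
        sp = 0
        stack[0, 0] = lx + d0x * t0
        stack[0, 1] = ly + d0y * t0
        stack[0, 2] = 1.0e-12
        stack[0, 3] = d0x
        stack[0, 4] = d0y
        stack[0, 5] = d0z
        stack[0, 6] = 1.0
        stack[0, 7] = 0.0
        stack[0, 8] = 1.0
        sp = 1

        while sp > 0:
            sp -= 1
            x = stack[sp, 0]
            y = stack[sp, 1]
            z = stack[sp, 2]
            dx = stack[sp, 3]
            dy = stack[sp, 4]
            dz = stack[sp, 5]
            w = stack[sp, 6]
            shift = stack[sp, 7]
            factor = stack[sp, 8]
            alive = True
            was_deep = z >= imp_depth
            steps = 0

            while alive:
                tau = -math.log(max(np.random.random(), 1.0e-300))
                # --- consume optical depth across regions ---
                while True:
                    steps += 1
                    if steps > _MAX_SUBSTEPS:
                        escaped += w
                        alive = False
                        break
                    # region lookup
                    lay = 0
                    for i in range(len(layer_bot)):
                        if z < layer_bot[i]:
                            lay = i
                            break
                        lay = i
                    in_t = False
                    if has_tumour and tum_z0 <= z < tum_z1:
                        px = x - tum_x
                        py = y - tum_y
                        if px * px + py * py <= tum_r2:
                            in_t = True
                    if in_t:
                        mus_s = mus_static_t[lay]
                        mus_tot = mustot_t[lay]
                        mut = mut_t[lay]
                    else:
                        mus_s = mus_static_h[lay]
                        mus_tot = mustot_h[lay]
                        mut = mut_h[lay]
                    if mut <= 0.0:
                        # transparent region: fly to the nearest boundary
                        s_free = 1.0e30
                    else:
                        s_free = tau / mut

                    # distance to nearest region-change surface
                    s_geo = 1.0e30
                    top = 0.0 if lay == 0 else layer_bot[lay - 1]
                    if dz > 1.0e-12:
                        s = (layer_bot[lay] - z) / dz
                        if s < s_geo:
                            s_geo = s
                    elif dz < -1.0e-12:
                        s = (top - z) / dz
                        if s < s_geo:
                            s_geo = s
                    if has_tumour:
                        if dz > 1.0e-12:
                            s = (tum_z0 - z) / dz
                            if 1.0e-12 < s < s_geo:
                                s_geo = s
                            s = (tum_z1 - z) / dz
                            if 1.0e-12 < s < s_geo:
                                s_geo = s
                        elif dz < -1.0e-12:
                            s = (tum_z0 - z) / dz
                            if 1.0e-12 < s < s_geo:
                                s_geo = s
                            s = (tum_z1 - z) / dz
                            if 1.0e-12 < s < s_geo:
                                s_geo = s
                        a = dx * dx + dy * dy
                        if a > 1.0e-16:
                            px = x - tum_x
                            py = y - tum_y
                            b = px * dx + py * dy
                            c = px * px + py * py - tum_r2
                            disc = b * b - a * c
                            if disc > 0.0:
                                sq = math.sqrt(disc)
                                s = (-b - sq) / a
                                if 1.0e-12 < s < s_geo:
                                    s_geo = s
                                s = (-b + sq) / a
                                if 1.0e-12 < s < s_geo:
                                    s_geo = s

                    if s_free < s_geo:
                        x += dx * s_free
                        y += dy * s_free
                        z += dz * s_free
                        break  # interact
                    step = s_geo + 1.0e-9
                    x += dx * step
                    y += dy * step
                    z += dz * step
                    if mut > 0.0:
                        tau -= s_geo * mut
                        if tau < 0.0:
                            tau = 0.0
                    if z <= 0.0:
                        # project back onto the surface plane
                        tcorr = z / dz
                        x -= dx * tcorr
                        y -= dy * tcorr
                        top_exit_w += w
                        if _accept_ray(
                            x, y, dx, dy, dz, na, lens_h, clear_r2, zf, ap_eff2
                        ):
                            detected_w += w
                            detected_moment += w * abs(shift)
                            if n_out < cap:
                                out_w[n_out] = w
                                out_f[n_out] = shift
                                n_out += 1
                        else:
                            escaped += w
                        alive = False
                        break
                    if z >= depth:
                        escaped += w
                        alive = False
                        break
                    if x * x + y * y > esc_r2:
                        escaped += w
                        alive = False
                        break
                    # depth-importance roulette: photons entering the deep
                    # region rarely return through the confocal gate; an
                    # unbiased kill/boost keeps the estimator exact while
                    # cutting the long diffusive tails.
                    if z >= imp_depth and not was_deep:
                        was_deep = True
                        if np.random.random() < imp_surv:
                            rl_gain += w * (1.0 / imp_surv - 1.0)
                            w /= imp_surv
                        else:
                            rl_kill += w
                            alive = False
                            break
                    elif z < imp_depth:
                        was_deep = False
                if not alive:
                    break

                # --- interaction ---
                albedo = mus_tot / mut
                absorbed += w * (1.0 - albedo)
                w *= albedo

                r = np.random.random() * mus_tot
                odx = dx
                ody = dy
                odz = dz
                phi = 2.0 * math.pi * np.random.random()
                if r < mus_s:
                    mu = hg_cos_from_u(np.random.random(), hg_g)
                    dx, dy, dz = _scatter_dir(dx, dy, dz, mu, phi)
                else:
                    # blood event: speed class chosen by importance-biased
                    # partial scattering coefficients, weight-corrected
                    # (unbiased; oversamples the rare fast class so the
                    # high-shift tail of the spectrum is well populated)
                    if in_t:
                        mb0 = musb_t[lay, 0]
                        mb1 = musb_t[lay, 1]
                        mb2 = musb_t[lay, 2]
                        v0 = speeds_t[lay, 0]
                        v1 = speeds_t[lay, 1]
                        v2 = speeds_t[lay, 2]
                    else:
                        mb0 = musb_h[lay, 0]
                        mb1 = musb_h[lay, 1]
                        mb2 = musb_h[lay, 2]
                        v0 = speeds_h[lay, 0]
                        v1 = speeds_h[lay, 1]
                        v2 = speeds_h[lay, 2]
                    sb0 = mb0 * class_bias[0]
                    sb1 = mb1 * class_bias[1]
                    sb2 = mb2 * class_bias[2]
                    sb = sb0 + sb1 + sb2
                    musb_tot = mb0 + mb1 + mb2
                    r2 = np.random.random() * sb
                    w_old = w
                    if r2 < sb0:
                        mean_sp = v0
                        w *= sb / (musb_tot * class_bias[0])
                    elif r2 < sb0 + sb1:
                        mean_sp = v1
                        w *= sb / (musb_tot * class_bias[1])
                    else:
                        mean_sp = v2
                        w *= sb / (musb_tot * class_bias[2])
                    # importance reweighting is zero-mean but not pathwise
                    # neutral; ledger it so energy accounting stays exact
                    bias_net += w - w_old
                    mu = _gk_cos_fast(
                        np.random.random(),
                        gk_inv_alpha,
                        gk_t_lo,
                        gk_t_span,
                        gk_one_plus_g2,
                        gk_inv_2g,
                        gk_alpha_is_one,
                    )
                    dx, dy, dz = _scatter_dir(dx, dy, dz, mu, phi)
                    # RBC velocity: isotropic direction, speed ~ U(0, 2 v_mean)
                    cz = 2.0 * np.random.random() - 1.0
                    sz = math.sqrt(max(0.0, 1.0 - cz * cz))
                    vphi = 2.0 * math.pi * np.random.random()
                    speed = 2.0 * mean_sp * np.random.random()
                    velx = speed * sz * math.cos(vphi)
                    vely = speed * sz * math.sin(vphi)
                    velz = speed * cz
                    # Doppler: (1/2pi)(ks - ki).v with |k| = 2 pi n / lambda
                    shift += (
                        n_ref
                        * inv_lambda_mm
                        * (
                            (dx - odx) * velx
                            + (dy - ody) * vely
                            + (dz - odz) * velz
                        )
                    )
                    # value-based importance splitting: bound the
                    # prospective estimator contribution w * |shift| per
                    # photon by splitting geometrically (weight conserved)
                    if splitting_on:
                        while (
                            w * abs(shift) > split_value
                            and factor * split_mult <= max_split
                            and sp + split_mult - 1 < _STACK_CAP
                        ):
                            w /= split_mult
                            factor *= split_mult
                            for _k in range(split_mult - 1):
                                stack[sp, 0] = x
                                stack[sp, 1] = y
                                stack[sp, 2] = z
                                stack[sp, 3] = dx
                                stack[sp, 4] = dy
                                stack[sp, 5] = dz
                                stack[sp, 6] = w
                                stack[sp, 7] = shift
                                stack[sp, 8] = factor
                                sp += 1

                # Russian roulette
                if w < rl_thresh:
                    if np.random.random() < rl_surv:
                        rl_gain += w * (1.0 / rl_surv - 1.0)
                        w /= rl_surv
                    else:
                        rl_kill += w
                        alive = False

    return (
        n_out,
        detected_w,
        detected_moment,
        absorbed,
        escaped,
        rl_kill,
        rl_gain,
        bias_net,
        top_exit_w,
    )
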