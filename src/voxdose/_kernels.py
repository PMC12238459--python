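"""Numba transport kernels.

Electron transport is straight-line continuous-slowing-down stepping
(step <= half a voxel) driven by the water range-energy relation with
local density/stopping-power scaling.  Photon transport is analog
delta-tracking with photoelectric absorption and Klein-Nishina
(Kahn-sampled) incoherent scattering; recoil electrons deposit locally.
All randomness comes from numba's np.random state seeded once per batch,
so a (seed, n) pair fixes the output bit-identically on one platform.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KEV_TO_J = 1.602176634e-16
MEC2 = 510.998950

_BUF_CAP = 1024


@njit(cache=True, inline="always")
def _loginterp(x, logx, logy):
    """Piecewise-linear interpolation in log-log space (clamped)."""
    lx = np.log(x)
    if lx <= logx[0]:
        return np.exp(logy[0])
    if lx >= logx[-1]:
        return np.exp(logy[-1])
    i = np.searchsorted(logx, lx) - 1
    f = (lx - logx[i]) / (logx[i + 1] - logx[i])
    return np.exp(logy[i] * (1.0 - f) + logy[i + 1] * f)


@njit(cache=True, inline="always")
def _deposit(buf_idx, buf_val, buf_n, flat, e, edep):
    """Accumulate a deposit into the per-decay buffer (merging repeats)."""
    for j in range(buf_n):
        if buf_idx[j] == flat:
            buf_val[j] += e
            return buf_n
    if buf_n < _BUF_CAP:
        buf_idx[buf_n] = flat
        buf_val[buf_n] = e
        return buf_n + 1
    # overflow: bypass the per-decay square bookkeeping
    edep[flat] += e
    return buf_n


@njit(cache=True)
def _electron_track(
    e0, x, y, z, ux, uy, uz,
    nx, ny, nz, h_cm, rho, spsc,
    re_loge, re_logr, cut_kev, step_cm,
    buf_idx, buf_val, buf_n, edep,
):
    """Transport one electron; returns updated buffer count."""
    rres = _loginterp(e0, re_loge, re_logr)  # residual water range, g/cm2
    e = e0
    while True:
        ix = int(np.floor(x / h_cm + 0.5))
        iy = int(np.floor(y / h_cm + 0.5))
        iz = int(np.floor(z / h_cm + 0.5))
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            return buf_n  # escaped
        flat = (ix * ny + iy) * nz + iz
        rhoeff = rho[flat] * spsc[flat]
        if e <= cut_kev:
            buf_n = _deposit(buf_idx, buf_val, buf_n, flat, e, edep)
            return buf_n
        dr = step_cm * rhoeff
        if dr >= rres or rhoeff <= 0.0:
            if dr >= rres:
                buf_n = _deposit(buf_idx, buf_val, buf_n, flat, e, edep)
                return buf_n
            # vacuum-like voxel: drift without loss
            x += step_cm * ux
            y += step_cm * uy
            z += step_cm * uz
            continue
        rres -= dr
        enew = _loginterp(rres, re_logr, re_loge)
        if enew > e:
            enew = e
        buf_n = _deposit(buf_idx, buf_val, buf_n, flat, e - enew, edep)
        e = enew
        x += step_cm * ux
        y += step_cm * uy
        z += step_cm * uz


@njit(cache=True, inline="always")
def _kahn_scatter(e_kev):
    """Sample a Klein-Nishina scatter; returns (e_scattered, cos_theta)."""
    alpha = e_kev / MEC2
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * alpha) / (9.0 + 2.0 * alpha):
            xx = 1.0 + 2.0 * alpha * r2  # x = E/E'
            if r3 <= 4.0 * (1.0 / xx - 1.0 / (xx * xx)):
                break
        else:
            xx = (1.0 + 2.0 * alpha) / (1.0 + 2.0 * alpha * r2)
            ct = 1.0 - (xx - 1.0) / alpha
            if r3 <= 0.5 * (ct * ct + 1.0 / xx):
                break
    cos_t = 1.0 - (xx - 1.0) / alpha
    return e_kev / xx, cos_t


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz > 0.0 else -1.0
        return sin_t * cp, sin_t * sp, cos_t * sign
    a = np.sqrt(1.0 - uz * uz)
    vx = ux * cos_t + sin_t * (ux * uz * cp - uy * sp) / a
    vy = uy * cos_t + sin_t * (uy * uz * cp + ux * sp) / a
    vz = uz * cos_t - a * sin_t * cp
    return vx, vy, vz


@njit(cache=True)
def _photon_track(
    e0, x, y, z, ux, uy, uz,
    nx, ny, nz, h_cm, rho, mat,
    eg_log, pe_log, pe_scale, kn_log, epg, mumax_log,
    cut_kev,
    buf_idx, buf_val, buf_n, edep,
):
    """Analog delta-tracking photon transport; returns updated buffer count."""
    e = e0
    while e > cut_kev:
        mu_max = _loginterp(e, eg_log, mumax_log)
        s = -np.log(np.random.random()) / mu_max
        x += s * ux
        y += s * uy
        z += s * uz
        ix = int(np.floor(x / h_cm + 0.5))
        iy = int(np.floor(y / h_cm + 0.5))
        iz = int(np.floor(z / h_cm + 0.5))
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            return buf_n  # escaped
        flat = (ix * ny + iy) * nz + iz
        m = mat[flat]
        pe = _loginterp(e, eg_log, pe_log) * pe_scale[m] * rho[flat]
        inc = _loginterp(e, eg_log, kn_log) * epg[m] * rho[flat]
        if np.random.random() * mu_max > pe + inc:
            continue  # virtual collision
        if np.random.random() * (pe + inc) < pe:
            buf_n = _deposit(buf_idx, buf_val, buf_n, flat, e, edep)
            return buf_n
        enew, cos_t = _kahn_scatter(e)
        buf_n = _deposit(buf_idx, buf_val, buf_n, flat, e - enew, edep)
        phi = 2.0 * np.pi * np.random.random()
        ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
        e = enew
    # below cut: local absorption
    ix = int(np.floor(x / h_cm + 0.5))
    iy = int(np.floor(y / h_cm + 0.5))
    iz = int(np.floor(z / h_cm + 0.5))
    if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
        flat = (ix * ny + iy) * nz + iz
        buf_n = _deposit(buf_idx, buf_val, buf_n, flat, e, edep)
    return buf_n


@njit(cache=True)
def simulate_batch(
    seed, n_primaries,
    nx, ny, nz, h_cm,
    rho, mat, spsc,
    src_flat, src_cdf,
    beta_icdf, has_beta,
    line_e, line_yield, line_is_electron,
    re_loge, re_logr,
    eg_log, pe_log, pe_scale, kn_log, epg, mumax_log,
    e_cut_kev, p_cut_kev, step_cm,
):
    """Simulate one batch; returns (edep_kev, edep_sq_kev2) flat grids."""
    np.random.seed(seed)
    nvox = nx * ny * nz
    edep = np.zeros(nvox, dtype=np.float64)
    edep_sq = np.zeros(nvox, dtype=np.float64)
    buf_idx = np.empty(_BUF_CAP, dtype=np.int64)
    buf_val = np.empty(_BUF_CAP, dtype=np.float64)
    n_lines = line_e.shape[0]
    n_icdf = beta_icdf.shape[0]
    for _ in range(n_primaries):
        buf_n = 0
        # decay site: voxel from the activity CDF, uniform within the voxel
        u = np.random.random()
        k = np.searchsorted(src_cdf, u)
        if k >= src_flat.shape[0]:
            k = src_flat.shape[0] - 1
        flat = src_flat[k]
        iz = flat % nz
        iy = (flat // nz) % ny
        ix = flat // (ny * nz)
        x = (ix + np.random.random() - 0.5) * h_cm
        y = (iy + np.random.random() - 0.5) * h_cm
        z = (iz + np.random.random() - 0.5) * h_cm
        if has_beta:
            t = np.random.random() * (n_icdf - 1)
            i = int(t)
            if i >= n_icdf - 1:
                i = n_icdf - 2
            f = t - i
            e_beta = beta_icdf[i] * (1.0 - f) + beta_icdf[i + 1] * f
            ct = 2.0 * np.random.random() - 1.0
            st = np.sqrt(max(0.0, 1.0 - ct * ct))
            ph = 2.0 * np.pi * np.random.random()
            if e_beta > 0.0:
                buf_n = _electron_track(
                    e_beta, x, y, z, st * np.cos(ph), st * np.sin(ph), ct,
                    nx, ny, nz, h_cm, rho, spsc,
                    re_loge, re_logr, e_cut_kev, step_cm,
                    buf_idx, buf_val, buf_n, edep,
                )
        for j in range(n_lines):
            if np.random.random() >= line_yield[j]:
                continue
            ct = 2.0 * np.random.random() - 1.0
            st = np.sqrt(max(0.0, 1.0 - ct * ct))
            ph = 2.0 * np.pi * np.random.random()
            ux = st * np.cos(ph)
            uy = st * np.sin(ph)
            uz = ct
            if line_is_electron[j]:
                buf_n = _electron_track(
                    line_e[j], x, y, z, ux, uy, uz,
                    nx, ny, nz, h_cm, rho, spsc,
                    re_loge, re_logr, e_cut_kev, step_cm,
                    buf_idx, buf_val, buf_n, edep,
                )
            else:
                buf_n = _photon_track(
                    line_e[j], x, y, z, ux, uy, uz,
                    nx, ny, nz, h_cm, rho, mat,
                    eg_log, pe_log, pe_scale, kn_log, epg, mumax_log,
                    p_cut_kev,
                    buf_idx, buf_val, buf_n, edep,
                )
        for j in range(buf_n):
            edep[buf_idx[j]] += buf_val[j]
            edep_sq[buf_idx[j]] += buf_val[j] * buf_val[j]
    return edep, edep_sq


@njit(cache=True)
def electron_once(
    e0, x, y, z, ux, uy, uz,
    nx, ny, nz, h_cm, rho, spsc,
    re_loge, re_logr, cut_kev, step_cm, edep,
):
    """Single-electron transport into a flat deposit grid; returns total keV."""
    buf_idx = np.empty(_BUF_CAP, dtype=np.int64)
    buf_val = np.empty(_BUF_CAP, dtype=np.float64)
    before = edep.sum()
    n = _electron_track(
        e0, x, y, z, ux, uy, uz, nx, ny, nz, h_cm, rho, spsc,
        re_loge, re_logr, cut_kev, step_cm, buf_idx, buf_val, 0, edep,
    )
    for j in range(n):
        edep[buf_idx[j]] += buf_val[j]
    return edep.sum() - before


@njit(cache=True)
def photon_once(
    seed, e0, x, y, z, ux, uy, uz,
    nx, ny, nz, h_cm, rho, mat,
    eg_log, pe_log, pe_scale, kn_log, epg, mumax_log,
    cut_kev, edep,
):
    """Single-photon transport into a flat deposit grid; returns total keV."""
    np.random.seed(seed)
    buf_idx = np.empty(_BUF_CAP, dtype=np.int64)
    buf_val = np.empty(_BUF_CAP, dtype=np.float64)
    before = edep.sum()
    n = _photon_track(
        e0, x, y, z, ux, uy, uz, nx, ny, nz, h_cm, rho, mat,
        eg_log, pe_log, pe_scale, kn_log, epg, mumax_log, cut_kev,
        buf_idx, buf_val, 0, edep,
    )
    for j in range(n):
        edep[buf_idx[j]] += buf_val[j]
    return edep.sum() - before
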