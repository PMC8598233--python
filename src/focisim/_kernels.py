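"""Numba stepping kernels for the droplet (LPM) and binding-site (PBM) models.

These are internal: all user-facing entry points live in :mod:`focisim.lpm`
and :mod:`focisim.pbm`.  Everything is single-threaded and driven by
``np.random.seed`` inside the kernel, so a given seed reproduces the
trajectory bit-for-bit.

Performance note (PBM): advancing all ~200 binding sites every 1 μs step is
RNG-bound.  Sites are therefore advanced lazily with per-site timestamps:
the bound site and any site near the tracer are advanced exactly to the
current step before a collision test, idle sites are propagated in Gaussian
chunks with a radial reflection fold at the focus boundary, and a full sync
every ``sync_every`` steps bounds the staleness of the positions used in the
cheap prescan.  The prescan pad is six per-axis standard deviations of the
maximal stale displacement, so missing a true collision is a ~1e-7 per-step
event.  The dynamics of every site the tracer can interact with are exact.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# maximum chunk (in steps) for lazy site propagation; keeps the fold-reflected
# Gaussian a good approximation of reflected Brownian motion in the ball
_SITE_CHUNK = 5000


@njit(cache=True, inline="always")
def _sigmoid_scalar(arg):
    if arg > 35.0:
        return 1.0
    if arg < -35.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-arg))


@njit(cache=True, inline="always")
def _lpm_step_raw(x, y, z, dt, D0, Dn, A, b, rf, rn, use_milstein):
    """One Itô/Milstein update of the droplet-model Langevin equation."""
    r = math.sqrt(x * x + y * y + z * z)
    s = _sigmoid_scalar(b * (r - rf))
    D = D0 + (Dn - D0) * s
    sp = s * (1.0 - s)
    dDdr = (Dn - D0) * b * sp
    dUdr = A * b * sp
    # Itô drift: spurious ∇D term plus the force term −D·∇U (kBT ≡ 1)
    drift = (dDdr - D * dUdr) * dt
    if r > 1e-14:
        ux = x / r
        uy = y / r
        uz = z / r
    else:
        ux = 0.0
        uy = 0.0
        uz = 0.0
    g1 = np.random.normal()
    g2 = np.random.normal()
    g3 = np.random.normal()
    sig = math.sqrt(2.0 * D * dt)
    corr = 0.0
    if use_milstein == 1:
        # D varies only radially: Milstein correction along the radial axis,
        # ½·σσ'·(ΔW_r² − dt) with σ = sqrt(2D), σσ' = dD/dr
        gr = g1 * ux + g2 * uy + g3 * uz
        corr = 0.5 * dDdr * dt * (gr * gr - 1.0)
    x = x + drift * ux + sig * g1 + corr * ux
    y = y + drift * uy + sig * g2 + corr * uy
    z = z + drift * uz + sig * g3 + corr * uz
    # reflecting nucleus boundary: radial mirror fold
    rn_new = math.sqrt(x * x + y * y + z * z)
    while rn_new > rn:
        f = (2.0 * rn - rn_new) / rn_new
        x *= f
        y *= f
        z *= f
        rn_new = abs(2.0 * rn - rn_new)
    return x, y, z, rn_new


# boundary-layer refinement: a full-dt step outside the focus is longer than
# the 1/b profile width, which biases crossing statistics; steps starting
# within the layer are therefore integrated with _SUBSTEPS substeps.
_SUBSTEPS = 8


@njit(cache=True, inline="always")
def _lpm_step(x, y, z, dt, D0, Dn, A, b, rf, rn, use_milstein):
    r2 = x * x + y * y + z * z
    half_w = 5.0 / b + 3.5 * math.sqrt(2.0 * Dn * dt)
    lo = rf - half_w
    hi = rf + half_w
    if lo * lo < r2 < hi * hi:
        dts = dt / _SUBSTEPS
        r = 0.0
        for _ in range(_SUBSTEPS):
            x, y, z, r = _lpm_step_raw(x, y, z, dts, D0, Dn, A, b, rf, rn, use_milstein)
        return x, y, z, r
    return _lpm_step_raw(x, y, z, dt, D0, Dn, A, b, rf, rn, use_milstein)


@njit(cache=True)
def lpm_run(
    seed,
    n_steps,
    record_every,
    dt,
    x,
    y,
    z,
    D0,
    Dn,
    A,
    b,
    rf,
    rn,
    use_milstein,
    r0_abs,
    out_pos,
):
    """Integrate the LPM; returns the absorption step if ``r0_abs > 0`` was
    reached (first-passage mode), else -1.  Records into ``out_pos``."""
    np.random.seed(seed)
    out_pos[0, 0] = x
    out_pos[0, 1] = y
    out_pos[0, 2] = z
    rec = 1
    n_rec = out_pos.shape[0]
    for step in range(1, n_steps + 1):
        x, y, z, r = _lpm_step(x, y, z, dt, D0, Dn, A, b, rf, rn, use_milstein)
        if r0_abs > 0.0 and r <= r0_abs:
            return step
        if step % record_every == 0 and rec < n_rec:
            out_pos[rec, 0] = x
            out_pos[rec, 1] = y
            out_pos[rec, 2] = z
            rec += 1
    return -1


@njit(cache=True)
def lpm_fpt_batch(
    seed, starts, dt, D0, Dn, A, b, rf, rn, use_milstein, r0_abs, max_steps, out_steps
):
    """First-passage times (in steps) to the central target, one per start.

    ``out_steps[i]`` is the absorption step, or -1 if ``max_steps`` was hit
    (censored).
    """
    np.random.seed(seed)
    for i in range(starts.shape[0]):
        x = starts[i, 0]
        y = starts[i, 1]
        z = starts[i, 2]
        out_steps[i] = -1
        for step in range(1, max_steps + 1):
            x, y, z, r = _lpm_step(x, y, z, dt, D0, Dn, A, b, rf, rn, use_milstein)
            if r <= r0_abs:
                out_steps[i] = step
                break


@njit(cache=True, inline="always")
def _fold_ball(cx, cy, cz, R):
    r = math.sqrt(cx * cx + cy * cy + cz * cz)
    while r > R:
        f = (2.0 * R - r) / r
        cx *= f
        cy *= f
        cz *= f
        r = abs(2.0 * R - r)
    return cx, cy, cz


@njit(cache=True, inline="always")
def _wrap_box(v, box):
    return v - box * math.floor(v / box)


@njit(cache=True, inline="always")
def _min_image(d, box):
    return d - box * math.floor(d / box + 0.5)


@njit(cache=True, inline="always")
def _advance_site(sites, last, i, now, sig_s, rf, periodic, box):
    """Propagate site ``i`` from its last update to step ``now``.

    Chunked Gaussian displacements with a radial reflection fold at the focus
    boundary (confined mode) or a periodic wrap (bulk mode)."""
    dsteps = now - last[i]
    if dsteps <= 0:
        return
    cx = sites[i, 0]
    cy = sites[i, 1]
    cz = sites[i, 2]
    while dsteps > 0:
        m = dsteps
        if m > _SITE_CHUNK:
            m = _SITE_CHUNK
        s = sig_s * math.sqrt(m)
        cx += s * np.random.normal()
        cy += s * np.random.normal()
        cz += s * np.random.normal()
        if periodic == 1:
            cx = _wrap_box(cx, box)
            cy = _wrap_box(cy, box)
            cz = _wrap_box(cz, box)
        else:
            cx, cy, cz = _fold_ball(cx, cy, cz, rf)
        dsteps -= m
    sites[i, 0] = cx
    sites[i, 1] = cy
    sites[i, 2] = cz
    last[i] = now


@njit(cache=True)
def pbm_run(
    seed,
    n_steps,
    record_every,
    dt,
    x,
    y,
    z,
    sites,
    absorbing,
    Dn,
    Db,
    rb,
    pb,
    koff_dt,
    rf,
    rn,
    periodic,
    box,
    sync_every,
    r0_abs,
    out_pos,
    out_bound,
):
    """Event-resolved PBM stepping (confined focus or periodic bulk).

    Per step, an unbound tracer takes a free-diffusion step at ``Dn``; if the
    proposed position lies within ``rb`` of the nearest site it binds with
    probability ``pb``, otherwise it is reflected radially off that site to
    distance ``2·rb − Δr`` and re-tested.  A bound tracer rides its site
    (diffusing at ``Db``) at a fixed offset and unbinds with probability
    ``koff_dt``.  Returns the absorption step if ``r0_abs > 0`` was reached,
    else -1.
    """
    np.random.seed(seed)
    N = sites.shape[0]
    last = np.zeros(N, np.int64)
    sig_t = math.sqrt(2.0 * Dn * dt)
    sig_s = math.sqrt(2.0 * Db * dt)
    lazy = Db > 0.0 and N > 0
    pad = 0.0
    if lazy:
        pad = 6.0 * math.sqrt(2.0 * Db * dt * sync_every)
    scan2 = (rb + pad) * (rb + pad)
    reach = rf + rb + pad + 4.0 * sig_t
    bound_idx = -1
    ox = 0.0
    oy = 0.0
    oz = 0.0
    out_pos[0, 0] = x
    out_pos[0, 1] = y
    out_pos[0, 2] = z
    out_bound[0] = 0
    rec = 1
    n_rec = out_pos.shape[0]
    for step in range(1, n_steps + 1):
        if lazy and step % sync_every == 0:
            for i in range(N):
                if i != bound_idx:
                    _advance_site(sites, last, i, step, sig_s, rf, periodic, box)
        if bound_idx >= 0:
            # ---- bound: ride the binding site at a fixed offset ----
            i = bound_idx
            if Db > 0.0:
                dxs = sig_s * np.random.normal()
                dys = sig_s * np.random.normal()
                dzs = sig_s * np.random.normal()
                cx = sites[i, 0] + dxs
                cy = sites[i, 1] + dys
                cz = sites[i, 2] + dzs
                if periodic == 1:
                    # tracer stays in unwrapped coordinates: raw displacement
                    x += dxs
                    y += dys
                    z += dzs
                    cx = _wrap_box(cx, box)
                    cy = _wrap_box(cy, box)
                    cz = _wrap_box(cz, box)
                else:
                    # tracer inherits the (possibly folded) site displacement
                    cx, cy, cz = _fold_ball(cx, cy, cz, rf)
                    x = cx + ox
                    y = cy + oy
                    z = cz + oz
                sites[i, 0] = cx
                sites[i, 1] = cy
                sites[i, 2] = cz
            last[i] = step
            if np.random.uniform(0.0, 1.0) < koff_dt:
                bound_idx = -1
        else:
            # ---- unbound: free diffusion + collision tests ----
            px = x + sig_t * np.random.normal()
            py = y + sig_t * np.random.normal()
            pz = z + sig_t * np.random.normal()
            do_scan = N > 0
            if periodic == 0 and do_scan:
                pr2 = px * px + py * py + pz * pz
                do_scan = pr2 < reach * reach
            if do_scan:
                for _attempt in range(10):
                    # nearest site whose (advanced) position overlaps the proposal
                    best = -1
                    best_d2 = rb * rb
                    for i in range(N):
                        if periodic == 1:
                            dx = _min_image(px - sites[i, 0], box)
                            dy = _min_image(py - sites[i, 1], box)
                            dz = _min_image(pz - sites[i, 2], box)
                        else:
                            dx = px - sites[i, 0]
                            dy = py - sites[i, 1]
                            dz = pz - sites[i, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 > scan2:
                            continue
                        if lazy and last[i] < step:
                            _advance_site(sites, last, i, step, sig_s, rf, periodic, box)
                            if periodic == 1:
                                dx = _min_image(px - sites[i, 0], box)
                                dy = _min_image(py - sites[i, 1], box)
                                dz = _min_image(pz - sites[i, 2], box)
                            else:
                                dx = px - sites[i, 0]
                                dy = py - sites[i, 1]
                                dz = pz - sites[i, 2]
                            d2 = dx * dx + dy * dy + dz * dz
                        if d2 < best_d2:
                            best_d2 = d2
                            best = i
                    if best < 0:
                        break
                    d = math.sqrt(best_d2)
                    if periodic == 1:
                        dx = _min_image(px - sites[best, 0], box)
                        dy = _min_image(py - sites[best, 1], box)
                        dz = _min_image(pz - sites[best, 2], box)
                    else:
                        dx = px - sites[best, 0]
                        dy = py - sites[best, 1]
                        dz = pz - sites[best, 2]
                    # site centre in the tracer's (unwrapped) frame
                    sx = px - dx
                    sy = py - dy
                    sz = pz - dz
                    if d < 1e-14:
                        # degenerate: proposal at the site centre; exit along
                        # the incoming direction
                        ex = x - sx
                        ey = y - sy
                        ez = z - sz
                        d0 = math.sqrt(ex * ex + ey * ey + ez * ez)
                        if d0 < 1e-14:
                            ex = 1.0
                            ey = 0.0
                            ez = 0.0
                        else:
                            ex /= d0
                            ey /= d0
                            ez /= d0
                    else:
                        ex = dx / d
                        ey = dy / d
                        ez = dz / d
                    if absorbing[best] == 1 and np.random.uniform(0.0, 1.0) < pb:
                        # bind at the surface intersection point
                        bound_idx = best
                        ox = ex * rb
                        oy = ey * rb
                        oz = ez * rb
                        px = sx + ox
                        py = sy + oy
                        pz = sz + oz
                        break
                    # radial reflection off the site: new distance 2rb − Δr
                    px = sx + ex * (2.0 * rb - d)
                    py = sy + ey * (2.0 * rb - d)
                    pz = sz + ez * (2.0 * rb - d)
            if bound_idx < 0 and periodic == 0:
                rr = math.sqrt(px * px + py * py + pz * pz)
                while rr > rn:
                    f = (2.0 * rn - rr) / rr
                    px *= f
                    py *= f
                    pz *= f
                    rr = abs(2.0 * rn - rr)
            x = px
            y = py
            z = pz
        if r0_abs > 0.0:
            if periodic == 0:
                if x * x + y * y + z * z <= r0_abs * r0_abs:
                    return step
        if step % record_every == 0 and rec < n_rec:
            out_pos[rec, 0] = x
            out_pos[rec, 1] = y
            out_pos[rec, 2] = z
            out_bound[rec] = 1 if bound_idx >= 0 else 0
            rec += 1
    return -1
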