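"""Numba kernels for force evaluation and RK4 time integration.

These operate on flat arrays extracted from the id-indexed state (see
``mechanics.ArrayView``).  Interaction rules:

* grain/grain contact (stiffness ``egg``, Kelvin-Voigt damping ``cgg``,
  clamped so the total normal force is never attractive) applies to grain
  pairs of the *same* cell, and to *peripheral* grain pairs of different
  cells (membrane/membrane contact);
* grain/cable contact (stiffness ``egc``, Kelvin-Voigt damping ``cgc``,
  same non-attractive clamp) applies to a cell's internal grains against
  its own membrane cables, and to peripheral grains against *foreign*
  cables;
* cable tension (stiffness ``ec``) is tension-only on the elongation
  beyond rest length.

The spherical support constraint is enforced geometrically after every
full RK4 step: each grain centre is radially projected to support radius
plus its own grain radius and the radial velocity component is removed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_pairs", "build_gc_pairs", "compute_forces", "rk4_relax",
           "project_arrays"]


@njit(cache=True)
def _grid_bins(pos, h):
    n = pos.shape[0]
    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        lo[d] = pos[:, d].min() - 1e-9
        hi[d] = pos[:, d].max() + 1e-9
    nb = np.empty(3, np.int64)
    for d in range(3):
        nb[d] = max(1, int((hi[d] - lo[d]) / h) + 1)
    binid = np.empty(n, np.int64)
    for i in range(n):
        ix = int((pos[i, 0] - lo[0]) / h)
        iy = int((pos[i, 1] - lo[1]) / h)
        iz = int((pos[i, 2] - lo[2]) / h)
        binid[i] = (ix * nb[1] + iy) * nb[2] + iz
    nbins = nb[0] * nb[1] * nb[2]
    count = np.zeros(nbins + 1, np.int64)
    for i in range(n):
        count[binid[i] + 1] += 1
    for b in range(nbins):
        count[b + 1] += count[b]
    order = np.empty(n, np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        b = binid[i]
        order[fill[b]] = i
        fill[b] += 1
    return lo, nb, count, order


@njit(cache=True)
def build_pairs(pos, rad, cellid, peri, nb1, nb2, skin):
    """Candidate interacting grain pairs (same-cell, or peripheral/peripheral
    across cells) with centre distance below summed radii plus ``skin``.

    Cable-bonded ring neighbours (``nb1``/``nb2``) are excluded: the
    membrane chain's spacing is set by its cables, not by contact."""
    n = pos.shape[0]
    if n < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rmax = rad.max()
    h = 2.0 * rmax + skin
    lo, nb, start, order = _grid_bins(pos, h)

    npairs = 0
    for phase in range(2):
        if phase == 1:
            pi = np.empty(npairs, np.int64)
            pj = np.empty(npairs, np.int64)
            npairs = 0
        for i in range(n):
            ix = int((pos[i, 0] - lo[0]) / h)
            iy = int((pos[i, 1] - lo[1]) / h)
            iz = int((pos[i, 2] - lo[2]) / h)
            for dx in range(-1, 2):
                jx = ix + dx
                if jx < 0 or jx >= nb[0]:
                    continue
                for dy in range(-1, 2):
                    jy = iy + dy
                    if jy < 0 or jy >= nb[1]:
                        continue
                    for dz in range(-1, 2):
                        jz = iz + dz
                        if jz < 0 or jz >= nb[2]:
                            continue
                        b = (jx * nb[1] + jy) * nb[2] + jz
                        for q in range(start[b], start[b + 1]):
                            j = order[q]
                            if j <= i:
                                continue
                            if cellid[i] != cellid[j]:
                                if peri[i] == 0 or peri[j] == 0:
                                    continue
                            elif j == nb1[i] or j == nb2[i]:
                                continue
                            cut = rad[i] + rad[j] + skin
                            ddx = pos[i, 0] - pos[j, 0]
                            ddy = pos[i, 1] - pos[j, 1]
                            ddz = pos[i, 2] - pos[j, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz < cut * cut:
                                if phase == 1:
                                    pi[npairs] = i
                                    pj[npairs] = j
                                npairs += 1
    return pi, pj


@njit(cache=True)
def build_gc_pairs(pos, rad, cellid, peri, ca, cb, ccell, thick, skin):
    """Candidate (grain, cable) contacts: internal grains vs own cables,
    peripheral grains vs foreign cables; endpoints excluded."""
    n = pos.shape[0]
    m = ca.shape[0]
    if n == 0 or m == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rmax = rad.max()
    h = 2.0 * rmax + skin
    lo, nb, start, order = _grid_bins(pos, h)

    mid = np.empty((m, 3))
    half = np.empty(m)
    for k in range(m):
        a, b = ca[k], cb[k]
        for d in range(3):
            mid[k, d] = 0.5 * (pos[a, d] + pos[b, d])
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        half[k] = 0.5 * np.sqrt(dx * dx + dy * dy + dz * dz)

    npairs = 0
    gg = np.empty(0, np.int64)
    gk = np.empty(0, np.int64)
    for phase in range(2):
        if phase == 1:
            gg = np.empty(npairs, np.int64)
            gk = np.empty(npairs, np.int64)
            npairs = 0
        for k in range(m):
            rs = half[k] + 0.5 * thick + rmax + skin
            span = int(rs / h) + 1
            ix = int((mid[k, 0] - lo[0]) / h)
            iy = int((mid[k, 1] - lo[1]) / h)
            iz = int((mid[k, 2] - lo[2]) / h)
            a, b = ca[k], cb[k]
            ck = ccell[k]
            for dx in range(-span, span + 1):
                jx = ix + dx
                if jx < 0 or jx >= nb[0]:
                    continue
                for dy in range(-span, span + 1):
                    jy = iy + dy
                    if jy < 0 or jy >= nb[1]:
                        continue
                    for dz in range(-span, span + 1):
                        jz = iz + dz
                        if jz < 0 or jz >= nb[2]:
                            continue
                        bb = (jx * nb[1] + jy) * nb[2] + jz
                        for q in range(start[bb], start[bb + 1]):
                            g = order[q]
                            if g == a or g == b:
                                continue
                            same = cellid[g] == ck
                            if same and peri[g] == 1:
                                continue
                            if (not same) and peri[g] == 0:
                                continue
                            ddx = pos[g, 0] - mid[k, 0]
                            ddy = pos[g, 1] - mid[k, 1]
                            ddz = pos[g, 2] - mid[k, 2]
                            cut = half[k] + 0.5 * thick + rad[g] + skin
                            if ddx * ddx + ddy * ddy + ddz * ddz < cut * cut:
                                if phase == 1:
                                    gg[npairs] = g
                                    gk[npairs] = k
                                npairs += 1
    return gg, gk


@njit(cache=True, fastmath=True)
def compute_forces(pos, vel, rad, pi, pj, gg, gk, ca, cb, crest,
                   ja, jb, jrest, kadh, fadh_max,
                   egg, cgg, egc, cgc, ec, thick, F, tension):
    """Accumulate all contact, cable-contact and tension forces into ``F``.

    Every pairwise contribution is equal and opposite by construction.
    ``tension`` receives the current tension of each cable.
    """
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0

    # grain/grain unilateral contact with Kelvin-Voigt damping
    for idx in range(pi.shape[0]):
        i = pi[idx]
        j = pj[idx]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        delta = rad[i] + rad[j] - dist
        if delta <= 0.0 or dist < 1e-12:
            continue
        nx = dx / dist
        ny = dy / dist
        nz = dz / dist
        approach = ((vel[i, 0] - vel[j, 0]) * nx +
                    (vel[i, 1] - vel[j, 1]) * ny +
                    (vel[i, 2] - vel[j, 2]) * nz)
        mag = egg * delta + cgg * approach
        if mag < 0.0:  # never attractive
            mag = 0.0
        F[i, 0] -= mag * nx
        F[i, 1] -= mag * ny
        F[i, 2] -= mag * nz
        F[j, 0] += mag * nx
        F[j, 1] += mag * ny
        F[j, 2] += mag * nz

    # cable tension (traction only)
    for k in range(ca.shape[0]):
        a = ca[k]
        b = cb[k]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        e = length - crest[k]
        if e <= 0.0 or length < 1e-12:
            tension[k] = 0.0
            continue
        T = ec * e
        tension[k] = T
        nx = dx / length
        ny = dy / length
        nz = dz / length
        F[a, 0] += T * nx
        F[a, 1] += T * ny
        F[a, 2] += T * nz
        F[b, 0] -= T * nx
        F[b, 1] -= T * ny
        F[b, 2] -= T * nz

    # cadherin junction springs (attraction-only permanent bonds)
    for q in range(ja.shape[0]):
        a = ja[q]
        b = jb[q]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        ext = dist - jrest[q]
        if ext <= 0.0 or dist < 1e-12:
            continue  # compression is handled by the contact laws
        f = kadh * ext
        if f > fadh_max:  # a junction cannot out-pull the membrane tension
            f = fadh_max
        nx = dx / dist
        ny = dy / dist
        nz = dz / dist
        F[a, 0] += f * nx
        F[a, 1] += f * ny
        F[a, 2] += f * nz
        F[b, 0] -= f * nx
        F[b, 1] -= f * ny
        F[b, 2] -= f * nz

    # grain/cable compressive contact with damping, reaction to endpoints
    for idx in range(gg.shape[0]):
        g = gg[idx]
        k = gk[idx]
        a = ca[k]
        b = cb[k]
        sx = pos[b, 0] - pos[a, 0]
        sy = pos[b, 1] - pos[a, 1]
        sz = pos[b, 2] - pos[a, 2]
        L2 = sx * sx + sy * sy + sz * sz
        if L2 < 1e-12:
            continue
        wx = pos[g, 0] - pos[a, 0]
        wy = pos[g, 1] - pos[a, 1]
        wz = pos[g, 2] - pos[a, 2]
        t = (wx * sx + wy * sy + wz * sz) / L2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        cx = pos[a, 0] + t * sx
        cy = pos[a, 1] + t * sy
        cz = pos[a, 2] + t * sz
        dx = pos[g, 0] - cx
        dy = pos[g, 1] - cy
        dz = pos[g, 2] - cz
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        pen = rad[g] + 0.5 * thick - dist
        if pen <= 0.0 or dist < 1e-12:
            continue
        nx = dx / dist
        ny = dy / dist
        nz = dz / dist
        wa = 1.0 - t
        # approach rate of grain toward the cable contact point
        vcx = wa * vel[a, 0] + t * vel[b, 0]
        vcy = wa * vel[a, 1] + t * vel[b, 1]
        vcz = wa * vel[a, 2] + t * vel[b, 2]
        approach = -((vel[g, 0] - vcx) * nx + (vel[g, 1] - vcy) * ny +
                     (vel[g, 2] - vcz) * nz)
        f = egc * pen + cgc * approach
        if f < 0.0:  # never attractive
            f = 0.0
        F[g, 0] += f * nx
        F[g, 1] += f * ny
        F[g, 2] += f * nz
        F[a, 0] -= f * nx * wa
        F[a, 1] -= f * ny * wa
        F[a, 2] -= f * nz * wa
        F[b, 0] -= f * nx * t
        F[b, 1] -= f * ny * t
        F[b, 2] -= f * nz * t


@njit(cache=True, fastmath=True)
def project_arrays(pos, vel, shellr):
    """Radial projection to each grain's constraint radius (support centre at
    the origin); removes the radial velocity component.  Idempotent."""
    n = pos.shape[0]
    for i in range(n):
        r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if r < 1e-12:
            continue  # wrapper validates; kernel must not raise
        s = shellr[i] / r
        pos[i, 0] *= s
        pos[i, 1] *= s
        pos[i, 2] *= s
        ux = pos[i, 0] / shellr[i]
        uy = pos[i, 1] / shellr[i]
        uz = pos[i, 2] / shellr[i]
        vr = vel[i, 0] * ux + vel[i, 1] * uy + vel[i, 2] * uz
        vel[i, 0] -= vr * ux
        vel[i, 1] -= vr * uy
        vel[i, 2] -= vr * uz


@njit(cache=True, fastmath=True)
def rk4_relax(pos, vel, rad, mass, shellr, cellid, peri,
              ca, cb, crest, ccell, ja, jb, jrest, kadh, fadh_max,
              egg, cgg, egc, cgc, ec, thick, gdamp, dt,
              n_steps, rebuild_every, skin, speed_tol, tension):
    """Advance ``n_steps`` RK4 steps in place with the spherical constraint
    applied after each step.  Neighbour lists are rebuilt every
    ``rebuild_every`` steps with a ``skin`` margin.  Stops early when the
    maximum grain speed falls below ``speed_tol``.  Returns steps taken."""
    n = pos.shape[0]
    if n == 0:
        return 0
    F = np.empty((n, 3))
    xt = np.empty((n, 3))
    vt = np.empty((n, 3))
    k1x = np.empty((n, 3))
    k1v = np.empty((n, 3))
    k2x = np.empty((n, 3))
    k2v = np.empty((n, 3))
    k3x = np.empty((n, 3))
    k3v = np.empty((n, 3))
    k4x = np.empty((n, 3))
    k4v = np.empty((n, 3))

    pi = np.empty(0, np.int64)
    pj = np.empty(0, np.int64)
    gg = np.empty(0, np.int64)
    gk = np.empty(0, np.int64)

    # ring-neighbour (cable-bonded) exclusion table
    nb1 = np.full(n, -1, np.int64)
    nb2 = np.full(n, -1, np.int64)
    for k in range(ca.shape[0]):
        a, b = ca[k], cb[k]
        if nb1[a] == -1:
            nb1[a] = b
        else:
            nb2[a] = b
        if nb1[b] == -1:
            nb1[b] = a
        else:
            nb2[b] = a

    steps = 0
    for step in range(n_steps):
        if step % rebuild_every == 0:
            pi, pj = build_pairs(pos, rad, cellid, peri, nb1, nb2, skin)
            gg, gk = build_gc_pairs(pos, rad, cellid, peri, ca, cb, ccell,
                                    thick, skin)

        # k1
        compute_forces(pos, vel, rad, pi, pj, gg, gk, ca, cb, crest,
                       ja, jb, jrest, kadh, fadh_max,
                       egg, cgg, egc, cgc, ec, thick, F, tension)
        for i in range(n):
            for d in range(3):
                k1x[i, d] = vel[i, d]
                k1v[i, d] = F[i, d] / mass[i] - gdamp * vel[i, d]
        # k2
        for i in range(n):
            for d in range(3):
                xt[i, d] = pos[i, d] + 0.5 * dt * k1x[i, d]
                vt[i, d] = vel[i, d] + 0.5 * dt * k1v[i, d]
        compute_forces(xt, vt, rad, pi, pj, gg, gk, ca, cb, crest,
                       ja, jb, jrest, kadh, fadh_max,
                       egg, cgg, egc, cgc, ec, thick, F, tension)
        for i in range(n):
            for d in range(3):
                k2x[i, d] = vt[i, d]
                k2v[i, d] = F[i, d] / mass[i] - gdamp * vt[i, d]
        # k3
        for i in range(n):
            for d in range(3):
                xt[i, d] = pos[i, d] + 0.5 * dt * k2x[i, d]
                vt[i, d] = vel[i, d] + 0.5 * dt * k2v[i, d]
        compute_forces(xt, vt, rad, pi, pj, gg, gk, ca, cb, crest,
                       ja, jb, jrest, kadh, fadh_max,
                       egg, cgg, egc, cgc, ec, thick, F, tension)
        for i in range(n):
            for d in range(3):
                k3x[i, d] = vt[i, d]
                k3v[i, d] = F[i, d] / mass[i] - gdamp * vt[i, d]
        # k4
        for i in range(n):
            for d in range(3):
                xt[i, d] = pos[i, d] + dt * k3x[i, d]
                vt[i, d] = vel[i, d] + dt * k3v[i, d]
        compute_forces(xt, vt, rad, pi, pj, gg, gk, ca, cb, crest,
                       ja, jb, jrest, kadh, fadh_max,
                       egg, cgg, egc, cgc, ec, thick, F, tension)
        for i in range(n):
            for d in range(3):
                k4x[i, d] = vt[i, d]
                k4v[i, d] = F[i, d] / mass[i] - gdamp * vt[i, d]

        c = dt / 6.0
        for i in range(n):
            for d in range(3):
                pos[i, d] += c * (k1x[i, d] + 2.0 * k2x[i, d] +
                                  2.0 * k3x[i, d] + k4x[i, d])
                vel[i, d] += c * (k1v[i, d] + 2.0 * k2v[i, d] +
                                  2.0 * k3v[i, d] + k4v[i, d])
        project_arrays(pos, vel, shellr)
        steps += 1

        if speed_tol > 0.0 and step % 25 == 24:
            vmax2 = 0.0
            for i in range(n):
                v2 = (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
                if v2 > vmax2:
                    vmax2 = v2
            if vmax2 < speed_tol * speed_tol:
                break

    # leave tensions consistent with the final geometry
    compute_forces(pos, vel, rad, pi, pj, gg, gk, ca, cb, crest,
                   ja, jb, jrest, kadh, fadh_max,
                   egg, cgg, egc, cgc, ec, thick, F, tension)
    return steps
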