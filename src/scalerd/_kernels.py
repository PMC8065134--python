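"""Compiled inner loops for the explicit Euler updates.

The update is expressed voxel-by-voxel but is semantically identical to the
whole-grid vectorised reference implementations in :mod:`scalerd.solver3d`
and :mod:`scalerd.reduce2d` (asserted in the test suite); the kernels exist
only to make the many-step integrations affordable on one CPU.

Model ids: 0 = nakamasu (3 components), 1 = gray_scott, 2 = schnakenberg.
Parameter vectors follow ``KineticsSpec.packed_params``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_chunk_3d", "step_chunk_2d"]


@njit(cache=True, inline="always")
def _reaction(model_id, p, u, v, w):
    if model_id == 0:
        fu = p[0] * v + p[1] * w + p[2]
        if fu < 0.0:
            fu = 0.0
        elif fu > p[12]:
            fu = p[12]
        gv = p[3] * u + p[4] * w + p[5]
        if gv < 0.0:
            gv = 0.0
        elif gv > p[13]:
            gv = p[13]
        hw = p[6] * u + p[7] * v + p[8]
        if hw < 0.0:
            hw = 0.0
        elif hw > p[14]:
            hw = p[14]
        return fu - p[9] * u, gv - p[10] * v, hw - p[11] * w
    elif model_id == 1:
        uvv = u * v * v
        return -uvv + p[0] * (1.0 - u), uvv - (p[0] + p[1]) * v, 0.0
    else:
        uuv = u * u * v
        return p[2] * (p[0] - u + uuv), p[2] * (p[1] - uuv), 0.0


def build_neighbour_table(mask: np.ndarray, per_y: bool, per_x: bool):
    """Flat active-voxel list and per-voxel neighbour indices for the stencil.

    Returns ``(active, nb)``: ``active`` are the flat indices of occupied
    voxels; ``nb[p, 0:6]`` are the flat indices of the six stencil
    neighbours of active voxel p, with the voxel's own index substituted
    wherever the neighbour is unoccupied or across a no-flux boundary
    (mirror => zero flux).
    """
    nz, ny, nx = mask.shape
    kk, jj, ii = np.nonzero(mask)
    active = ((kk * ny + jj) * nx + ii).astype(np.int32)
    nb = np.empty((active.size, 6), dtype=np.int32)
    col = 0
    for axis, per in ((0, False), (1, per_y), (2, per_x)):
        size = mask.shape[axis]
        coords = (kk, jj, ii)[axis]
        for stp in (-1, 1):
            shifted = coords + stp
            if per:
                shifted = shifted % size
                valid = np.ones_like(shifted, dtype=bool)
            else:
                valid = (shifted >= 0) & (shifted < size)
                shifted = np.clip(shifted, 0, size - 1)
            nk, nj, ni = kk.copy(), jj.copy(), ii.copy()
            (nk, nj, ni)[axis][:] = shifted
            valid &= mask[nk, nj, ni]
            flat = (nk * ny + nj) * nx + ni
            nb[:, col] = np.where(valid, flat, active)
            col += 1
    return active, nb


@njit(cache=True, fastmath=True, inline="always")
def _sweep_3d(a, b, active, nb, D, inv_eps2, dt, model_id, p, track):
    """One Euler step over the active voxels; returns the tracked max change.

    ``a``/``b`` are voxel-major (n_grid, C) buffers, so each voxel's
    components and each gathered neighbour share a cache line.
    """
    C = a.shape[1]
    n = active.size
    maxchange = 0.0
    for q in range(n):
        i = active[q]
        n0 = nb[q, 0]
        n1 = nb[q, 1]
        n2 = nb[q, 2]
        n3 = nb[q, 3]
        n4 = nb[q, 4]
        n5 = nb[q, 5]
        u = a[i, 0]
        v = a[i, 1]
        w = a[i, 2] if C == 3 else 0.0
        du, dv, dw = _reaction(model_id, p, u, v, w)
        change = 0.0
        for c in range(C):
            cc = a[i, c]
            acc = (
                a[n0, c] + a[n1, c] + a[n2, c]
                + a[n3, c] + a[n4, c] + a[n5, c]
                - 6.0 * cc
            )
            if c == 0:
                r = du
            elif c == 1:
                r = dv
            else:
                r = dw
            newv = cc + dt * (r + D[c] * acc * inv_eps2)
            b[i, c] = newv
            change += abs(newv - cc)
        if track and change > maxchange:
            maxchange = change
    return maxchange


@njit(cache=True, fastmath=True)
def step_chunk_3d(cur, nxt, active, nb, D, inv_eps2, dt, model_id, p, nsteps):
    """Advance ``nsteps`` Euler steps on the active voxels.

    ``cur``/``nxt`` are voxel-major (n_grid, C) buffers; the result ends
    in ``cur``.  ``active``/``nb`` come from :func:`build_neighbour_table`.
    Returns the maximum over active voxels of the summed absolute
    per-component change during the final step.
    """
    a, b = cur, nxt
    for s in range(nsteps - 1):
        _sweep_3d(a, b, active, nb, D, inv_eps2, dt, model_id, p, False)
        a, b = b, a
    maxchange = _sweep_3d(a, b, active, nb, D, inv_eps2, dt, model_id, p, True)
    if nsteps % 2 == 1:
        cur[:, :] = nxt[:, :]
    return maxchange


@njit(cache=True, fastmath=True)
def step_chunk_2d(curQ, nxtQ, curc, nxtc, z, fxc, fyc, inv_eps2, dt, model_id, p, nsteps):
    """Advance ``nsteps`` flux-conservative Euler steps of the reduced system.

    ``curQ``/``nxtQ`` hold the integrated concentrations Q (C, ny, nx) and
    ``curc``/``nxtc`` the matching concentrations c = Q / z (kept in sync;
    results end in the ``cur`` buffers).  ``fxc``/``fyc`` are per-component
    face coefficients D*z, shaped (C, ny, nx+1) and (C, ny+1, nx); a zero
    coefficient encodes a no-flux boundary face, a shared wrap value a
    periodic one.  Returns the maximum summed per-component change of c
    during the final step.
    """
    aQ, bQ = curQ, nxtQ
    ac, bc = curc, nxtc
    for s in range(nsteps - 1):
        _sweep_2d(aQ, bQ, ac, bc, z, fxc, fyc, inv_eps2, dt, model_id, p, False)
        aQ, bQ = bQ, aQ
        ac, bc = bc, ac
    maxchange = _sweep_2d(aQ, bQ, ac, bc, z, fxc, fyc, inv_eps2, dt, model_id, p, True)
    if nsteps % 2 == 1:
        curQ[:, :, :] = nxtQ[:, :, :]
        curc[:, :, :] = nxtc[:, :, :]
    return maxchange


@njit(cache=True, fastmath=True, inline="always")
def _sweep_2d(aQ, bQ, ac, bc, z, fxc, fyc, inv_eps2, dt, model_id, p, track):
    """One flux-conservative Euler step of the reduced system."""
    C, ny, nx = aQ.shape
    maxchange = 0.0
    for j in range(ny):
        jm = j - 1 if j > 0 else ny - 1
        jp = j + 1 if j + 1 < ny else 0
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i + 1 < nx else 0
            zc = z[j, i]
            u = ac[0, j, i]
            v = ac[1, j, i]
            w = ac[2, j, i] if C == 3 else 0.0
            du, dv, dw = _reaction(model_id, p, u, v, w)
            change = 0.0
            for c in range(C):
                cc = ac[c, j, i]
                div = (
                    fxc[c, j, i + 1] * (ac[c, j, ip] - cc)
                    - fxc[c, j, i] * (cc - ac[c, j, im])
                    + fyc[c, j + 1, i] * (ac[c, jp, i] - cc)
                    - fyc[c, j, i] * (cc - ac[c, jm, i])
                ) * inv_eps2
                if c == 0:
                    r = du
                elif c == 1:
                    r = dv
                else:
                    r = dw
                newq = aQ[c, j, i] + dt * (div + r * zc)
                bQ[c, j, i] = newq
                newc = newq / zc
                bc[c, j, i] = newc
                change += abs(newc - cc)
            if track and change > maxchange:
                maxchange = change
    return maxchange
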