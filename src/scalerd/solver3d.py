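"""Explicit 3D finite-difference solver on masked voxel domains.

Euler forward time stepping with a 7-point stencil Laplacian,

    lap(u) ~ (u_N + u_S + u_W + u_E + u_T + u_B - 6 u) / eps^2,

periodic or no-flux boundaries in x/y, always no-flux at the irregular skin
surfaces (a neighbour outside the occupied mask contributes the centre
value, i.e. a mirror condition).  Integration stops when every node
satisfies sum_c |c(t) - c(t - dt)| < tol (default 1e-7), checked every
``check_every`` steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import VoxelDomain
from .models import FieldState, KineticsSpec, green_intensity

__all__ = ["SolverConfig", "laplacian7", "step", "run_to_steady", "project_plan_view"]


@dataclass
class SolverConfig:
    """Integrator settings; ``dt`` falls back to the kinetics' own step."""

    dt: float | None = None
    tol: float = 1e-7
    check_every: int = 100
    max_steps: int = 2_000_000
    allow_unstable_dt: bool = False

    def resolve_dt(self, kin: KineticsSpec, eps: float, n_dim: int = 3) -> float:
        dt = self.dt if self.dt is not None else kin.dt
        d_max = max(kin.diffusivities)
        if d_max > 0:
            limit = eps**2 / (2.0 * n_dim * d_max)
            if dt > limit:
                msg = (
                    f"dt={dt} exceeds the explicit-stability bound "
                    f"eps^2/(2*{n_dim}*D_max)={limit:.4g}"
                )
                if self.allow_unstable_dt:
                    warnings.warn(msg, RuntimeWarning, stacklevel=2)
                else:
                    raise ValueError(msg + "; reduce dt or set allow_unstable_dt")
        return dt


def _shift_with_bc(field: np.ndarray, mask: np.ndarray, axis: int, step_: int, periodic: bool) -> np.ndarray:
    """Neighbour values along one axis; invalid neighbours mirror the centre."""
    nb = np.roll(field, -step_, axis=axis)
    nb_mask = np.roll(mask, -step_, axis=axis)
    valid = nb_mask.copy()
    if not periodic:
        edge = [slice(None)] * field.ndim
        edge[axis] = -1 if step_ > 0 else 0
        valid[tuple(edge)] = False
    return np.where(valid, nb, field)


def laplacian7(field: np.ndarray, domain: VoxelDomain) -> np.ndarray:
    """7-point stencil Laplacian with mirror (zero-flux) masked boundaries.

    Reference vectorised implementation; values outside the occupancy mask
    are meaningless.
    """
    m = domain.mask
    per_y, per_x = domain.periodic_xy
    acc = np.zeros_like(field)
    for axis, per in ((0, False), (1, per_y), (2, per_x)):
        for s in (1, -1):
            acc += _shift_with_bc(field, m, axis, s, per)
    return (acc - 6.0 * field) / domain.spacing**2


def step(state: FieldState, kin: KineticsSpec, cfg: SolverConfig | None = None) -> FieldState:
    """One Euler forward step; all components update simultaneously."""
    cfg = cfg or SolverConfig()
    domain: VoxelDomain = state.domain
    dt = cfg.resolve_dt(kin, domain.spacing)
    comps = list(state.components.values())
    rates = kin.rates(*comps)
    D = kin.diffusivities
    new = {}
    for name, c, r, d in zip(state.names, comps, rates, D):
        nc = c + dt * (r + d * laplacian7(c, domain))
        if not np.all(np.isfinite(nc[domain.mask])):
            raise FloatingPointError(
                "non-finite concentration produced: the explicit scheme went unstable"
            )
        new[name] = nc
    return FieldState(components=new, domain=domain, t=state.t + dt)


def run_to_steady(
    state: FieldState,
    kin: KineticsSpec,
    cfg: SolverConfig | None = None,
) -> tuple[FieldState, int, bool]:
    """Integrate until the steady-state criterion holds or ``max_steps`` is hit.

    Returns ``(state, steps_taken, converged)``.  Convergence means the
    per-node sum of absolute single-step component changes is below
    ``cfg.tol`` at every occupied node.
    """
    cfg = cfg or SolverConfig()
    domain: VoxelDomain = state.domain
    dt = cfg.resolve_dt(kin, domain.spacing)
    per_y, per_x = domain.periodic_xy
    active, nb = _kernels.build_neighbour_table(domain.mask, per_y, per_x)
    shape = domain.shape
    flat = state.stacked().astype(np.float64).reshape(len(state.names), -1)
    occ = np.zeros(flat.shape[1], dtype=bool)
    occ[active] = True
    flat[:, ~occ] = 0.0
    cur = np.ascontiguousarray(flat.T)  # voxel-major for the kernel
    nxt = cur.copy()
    p = kin.packed_params()
    D = np.asarray(kin.diffusivities, dtype=np.float64)
    inv_eps2 = 1.0 / domain.spacing**2
    steps = 0
    converged = False
    while steps < cfg.max_steps:
        n = min(cfg.check_every, cfg.max_steps - steps)
        maxchange = _kernels.step_chunk_3d(
            cur, nxt, active, nb, D, inv_eps2, dt, kin.model_id, p, n
        )
        steps += n
        if not np.isfinite(maxchange) or not np.all(np.isfinite(cur[occ, :])):
            raise FloatingPointError(
                f"non-finite concentration after {steps} steps: instability"
            )
        if maxchange < cfg.tol:
            converged = True
            break
    comps = {name: np.ascontiguousarray(cur[:, idx]).reshape(shape) for idx, name in enumerate(state.names)}
    out = FieldState(components=comps, domain=domain, t=state.t + steps * dt)
    return out, steps, converged


def project_plan_view(state: FieldState, domain: VoxelDomain | None = None, mode: str = "mean") -> np.ndarray:
    """Plan-view green-intensity image of a 3D state.

    ``mean`` uses the z-average concentrations per column, ``top`` /
    ``bottom`` the highest / lowest occupied voxel.  Empty columns are NaN.
    """
    domain = domain or state.domain
    mask = domain.mask
    cols = mask.sum(axis=0)
    names = state.names
    if mode == "mean":
        vals = []
        for name in names[:2]:
            f = np.where(mask, state.components[name], 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals.append(f.sum(axis=0) / cols)
        g = green_intensity(vals[0], vals[1])
    elif mode in ("top", "bottom"):
        nz = mask.shape[0]
        kidx = np.arange(nz)[:, None, None]
        if mode == "top":
            sel = np.where(mask, kidx, -1).max(axis=0)
        else:
            sel = np.where(mask, kidx, nz).min(axis=0)
        sel_c = np.clip(sel, 0, nz - 1)
        jj, ii = np.indices(sel.shape)
        u = state.components[names[0]][sel_c, jj, ii]
        v = state.components[names[1]][sel_c, jj, ii]
        g = green_intensity(u, v)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    g = np.where(cols > 0, g, np.nan)
    return g
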