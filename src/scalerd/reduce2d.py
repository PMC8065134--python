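"""3D-to-2D thin-domain reduction with effective diffusivities.

For a thin domain bounded by z_bottom(x,y) and z_top(x,y) with thickness
z = z_top - z_bottom, the thickness-integrated concentration Q = c * z
evolves as

    dQ/dt = div( D z grad(Q / z) ) + f(Q / z) z.

With constant D this is the Fick-Jacobs form; the Bradley variant replaces
D by the regularised position-dependent effective diffusivity

    D(x) = D / (1 + (dz0/dx)^2 + (1/12) (dz/dx)^2),

per direction (z0 is the midline), assembled as a diagonal 2x2 diffusion
matrix -- anisotropy is only captured along the grid axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import HeightField, ScaleMap
from .models import FieldState, KineticsSpec
from .solver3d import SolverConfig

__all__ = [
    "ReducedDomain",
    "reduce_geometry",
    "state_to_integrated",
    "integrated_to_state",
    "step_reduced",
    "run_reduced_to_steady",
    "compare_to_3d",
]


@dataclass
class ReducedDomain:
    """2D reduced arena: thickness, midline and geometric diffusivity factors.

    ``gx``/``gy`` multiply a component's bulk diffusivity to give the
    effective diffusivity per direction (both 1 for Fick-Jacobs).
    """

    z: np.ndarray
    z0: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    spacing: float
    method: str
    periodic_xy: tuple[bool, bool] = (False, False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def diffusivity(self, D: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-direction effective diffusivity grids for bulk coefficient D."""
        return D * self.gx, D * self.gy


def _gradient(f: np.ndarray, axis: int, eps: float, periodic: bool) -> np.ndarray:
    """Central-difference slope; one-sided at non-periodic edges."""
    if periodic:
        return (np.roll(f, -1, axis=axis) - np.roll(f, 1, axis=axis)) / (2 * eps)
    return np.gradient(f, eps, axis=axis)


def reduce_geometry(hf: HeightField, method: str = "bradley", kin: KineticsSpec | None = None) -> ReducedDomain:
    """Build the reduced 2D domain from a height field.

    ``method`` is ``"fick_jacobs"`` (constant diffusivity) or ``"bradley"``
    (slope-penalised effective diffusivity).  The kinetics argument is
    accepted for interface symmetry; diffusivities enter only at stepping
    time.
    """
    z = hf.thickness
    if np.any(z <= 0):
        raise ValueError("reduction requires strictly positive thickness")
    z0 = hf.midline
    eps = hf.spacing
    per_y, per_x = hf.periodic_xy
    if method == "fick_jacobs":
        gx = np.ones_like(z)
        gy = np.ones_like(z)
    elif method == "bradley":
        dz0x = _gradient(z0, 1, eps, per_x)
        dzx = _gradient(z, 1, eps, per_x)
        dz0y = _gradient(z0, 0, eps, per_y)
        dzy = _gradient(z, 0, eps, per_y)
        gx = 1.0 / (1.0 + dz0x**2 + dzx**2 / 12.0)
        gy = 1.0 / (1.0 + dz0y**2 + dzy**2 / 12.0)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return ReducedDomain(
        z=z.copy(), z0=z0.copy(), gx=gx, gy=gy,
        spacing=eps, method=method, periodic_xy=hf.periodic_xy,
    )


def state_to_integrated(state: FieldState, rd: ReducedDomain) -> np.ndarray:
    """Stack plan-view concentrations into integrated quantities Q = c * z."""
    return np.stack([state.components[n] * rd.z for n in state.names])


def integrated_to_state(Q: np.ndarray, names: tuple[str, ...], rd: ReducedDomain, t: float = 0.0) -> FieldState:
    comps = {n: Q[i] / rd.z for i, n in enumerate(names)}
    return FieldState(components=comps, domain=rd, t=t)


def _face_coefficients(rd: ReducedDomain, kin: KineticsSpec, harmonic: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-component face transmissibilities D*z (arithmetic mean by default).

    Shapes (C, ny, nx+1) and (C, ny+1, nx); zero encodes a no-flux boundary
    face, while periodic boundaries share the wrap value.
    """
    ny, nx = rd.shape
    C = kin.n_components
    D = kin.diffusivities
    fxc = np.zeros((C, ny, nx + 1))
    fyc = np.zeros((C, ny + 1, nx))
    per_y, per_x = rd.periodic_xy

    def mean(a, b):
        if harmonic:
            return 2.0 * a * b / (a + b)
        return 0.5 * (a + b)

    for c in range(C):
        nodex = D[c] * rd.gx * rd.z
        nodey = D[c] * rd.gy * rd.z
        fxc[c, :, 1:nx] = mean(nodex[:, :-1], nodex[:, 1:])
        fyc[c, 1:ny, :] = mean(nodey[:-1, :], nodey[1:, :])
        if per_x:
            wrap = mean(nodex[:, -1], nodex[:, 0])
            fxc[c, :, 0] = wrap
            fxc[c, :, nx] = wrap
        if per_y:
            wrap = mean(nodey[-1, :], nodey[0, :])
            fyc[c, 0, :] = wrap
            fyc[c, ny, :] = wrap
    return fxc, fyc


def step_reduced(
    Q: np.ndarray,
    rd: ReducedDomain,
    kin: KineticsSpec,
    cfg: SolverConfig | None = None,
    harmonic_faces: bool = False,
) -> np.ndarray:
    """One flux-conservative Euler step of the reduced equation (reference).

    Vectorised single-step implementation used for testing and small runs;
    ``run_reduced_to_steady`` drives the compiled kernel instead.
    """
    cfg = cfg or SolverConfig()
    dt = cfg.resolve_dt(kin, rd.spacing, n_dim=2)
    fxc, fyc = _face_coefficients(rd, kin, harmonic_faces)
    inv_eps2 = 1.0 / rd.spacing**2
    C, ny, nx = Q.shape
    c = Q / rd.z
    rates = kin.rates(*list(c))
    out = np.empty_like(Q)
    for ci in range(C):
        cc = c[ci]
        east = np.roll(cc, -1, axis=1)
        west = np.roll(cc, 1, axis=1)
        south = np.roll(cc, -1, axis=0)
        north = np.roll(cc, 1, axis=0)
        div = (
            fxc[ci, :, 1:] * (east - cc)
            - fxc[ci, :, :-1] * (cc - west)
            + fyc[ci, 1:, :] * (south - cc)
            - fyc[ci, :-1, :] * (cc - north)
        ) * inv_eps2
        out[ci] = Q[ci] + dt * (div + rates[ci] * rd.z)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite integrated concentration: instability")
    return out


def run_reduced_to_steady(
    Q: np.ndarray,
    rd: ReducedDomain,
    kin: KineticsSpec,
    cfg: SolverConfig | None = None,
    harmonic_faces: bool = False,
) -> tuple[np.ndarray, int, bool]:
    """Iterate the reduced system to the steady-state criterion on c = Q/z."""
    cfg = cfg or SolverConfig()
    dt = cfg.resolve_dt(kin, rd.spacing, n_dim=2)
    fxc, fyc = _face_coefficients(rd, kin, harmonic_faces)
    inv_eps2 = 1.0 / rd.spacing**2
    cur = np.ascontiguousarray(Q.astype(np.float64))
    nxt = cur.copy()
    z = np.ascontiguousarray(rd.z)
    curc = cur / z[None, :, :]
    nxtc = curc.copy()
    p = kin.packed_params()
    steps = 0
    converged = False
    while steps < cfg.max_steps:
        n = min(cfg.check_every, cfg.max_steps - steps)
        maxchange = _kernels.step_chunk_2d(
            cur, nxt, curc, nxtc, z, fxc, fyc, inv_eps2, dt, kin.model_id, p, n
        )
        steps += n
        if not np.isfinite(maxchange) or not np.all(np.isfinite(cur)):
            raise FloatingPointError(f"non-finite state after {steps} steps: instability")
        if maxchange < cfg.tol:
            converged = True
            break
    return cur, steps, converged


def compare_to_3d(plan3d: np.ndarray, plan2d: np.ndarray, sm: ScaleMap) -> tuple[float, float]:
    """Compare two plan-view green-intensity images scale by scale.

    Returns ``(wrong_colour_pct, mean_abs_diff_pct)``: the percentage of
    scales whose binary colour (mean g thresholded at 0.5) differs, and the
    mean absolute per-element difference of g, as a percentage.
    """
    if plan3d.shape != plan2d.shape:
        raise ValueError("plan-view images must share one shape")
    from .metrics import classify_scale_colours

    col3 = classify_scale_colours(plan3d, sm)
    col2 = classify_scale_colours(plan2d, sm)
    wrong = float(np.mean(col3 != col2) * 100.0)
    valid = np.isfinite(plan3d) & np.isfinite(plan2d)
    diff = float(np.mean(np.abs(plan3d[valid] - plan2d[valid])) * 100.0)
    return wrong, diff
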