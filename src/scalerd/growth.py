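"""Quasi-static pattern development on a growing domain.

Skin patterning reaches reaction-diffusion equilibrium much faster than the
animal grows, so growth is simulated by alternating (i) an incremental,
isotropic enlargement of the physical domain at a fixed element count,
L(tau) = (1 + tau * delta_tau) * L(0), with the thickness map and the
effective diffusivities recomputed on the rescaled geometry, and (ii)
relaxation of the reduced 2D system back to steady state, carrying the
concentration fields over unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HeightField
from .metrics import (
    binarize,
    border_curvature,
    extract_borders,
    pattern_length_scale,
)
from .models import FieldState, KineticsSpec, green_intensity
from .reduce2d import reduce_geometry, run_reduced_to_steady
from .solver3d import SolverConfig

__all__ = ["GrowthSchedule", "GrowthRecord", "GrowthTrajectory", "grow_and_relax", "relative_length_scale_series"]


@dataclass
class GrowthSchedule:
    """Relative growth increments: size factor 1 + tau * delta_tau at step tau."""

    delta_tau: float = 0.02
    n_steps: int = 48

    def __post_init__(self) -> None:
        if self.delta_tau < 0:
            raise ValueError("delta_tau must be non-negative")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    def size_factor(self, tau: int) -> float:
        return 1.0 + tau * self.delta_tau


@dataclass
class GrowthRecord:
    tau: int
    normalized_size: float
    image: np.ndarray  # plan-view green intensity at steady state
    length_scale: float
    length_scale_flagged: bool
    curvature: float
    steps: int
    converged: bool


@dataclass
class GrowthTrajectory:
    records: list[GrowthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _measure(g_image: np.ndarray, r_avg_px: float) -> tuple[float, bool, float]:
    binary = binarize(g_image, mode="fixed")
    ls = pattern_length_scale(binary, r_avg_px)
    try:
        curv = border_curvature(extract_borders(binary), r_avg_px)
    except ValueError:
        curv = float("nan")
    return ls.mean, ls.flagged, curv


def grow_and_relax(
    state: FieldState,
    hf: HeightField,
    kin: KineticsSpec,
    cfg: SolverConfig,
    sched: GrowthSchedule,
    r_avg_px: float,
    method: str = "bradley",
    abort_on_nonconvergence: bool = False,
) -> GrowthTrajectory:
    """Run the quasi-static growth loop and record per-step pattern metrics.

    ``state`` holds plan-view concentration grids (one per component) on
    the initial reduced geometry; it is relaxed once at tau = 0 before the
    first enlargement.  ``r_avg_px`` is the mean scale radius in grid
    elements, which growth leaves unchanged (scales stretch with the skin).
    """
    names = state.names
    conc = state.stacked().astype(np.float64)
    traj = GrowthTrajectory()
    for tau in range(sched.n_steps + 1):
        f = sched.size_factor(tau)
        hf_tau = HeightField(
            z_top=hf.z_top,
            z_bottom=hf.z_bottom,
            spacing=hf.spacing * f,
            periodic_xy=hf.periodic_xy,
        )
        rd = reduce_geometry(hf_tau, method=method)
        Q = conc * rd.z[None, :, :]
        Q, steps, converged = run_reduced_to_steady(Q, rd, kin, cfg)
        if not converged and abort_on_nonconvergence:
            raise RuntimeError(f"growth step {tau} did not reach steady state")
        conc = Q / rd.z[None, :, :]
        g = green_intensity(conc[0], conc[1])
        ls, flagged, curv = _measure(g, r_avg_px)
        traj.records.append(
            GrowthRecord(
                tau=tau,
                normalized_size=f,
                image=g,
                length_scale=ls,
                length_scale_flagged=flagged,
                curvature=curv,
                steps=steps,
                converged=converged,
            )
        )
    return traj


def relative_length_scale_series(traj: GrowthTrajectory) -> np.ndarray:
    """(normalized size, mean relative length scale) pairs, one per record."""
    if not traj.records:
        raise ValueError("empty trajectory")
    return np.array([(r.normalized_size, r.length_scale) for r in traj.records])
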