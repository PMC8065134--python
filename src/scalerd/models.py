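"""Reaction kinetics, colour read-out and initial conditions.

Three kinetics are provided:

* the three-component activator/inhibitor network with clipped linear
  reaction terms used for fish and lizard skin patterning (``nakamasu``),
  where u and v are short-range factors (melanophore- and
  xanthophore-like) and w a long-range factor;
* the Gray-Scott two-component model (``gray_scott``);
* the Schnakenberg two-component model (``schnakenberg``).

Concentrations are dimensionless; a pattern is rendered through the green
intensity ``g = clip((v - u) / (v + u) + 0.5, 0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .geometry import ScaleMap, VoxelDomain

__all__ = [
    "KineticsSpec",
    "FieldState",
    "NAKAMASU_DEFAULTS",
    "GRAY_SCOTT_DEFAULTS",
    "SCHNAKENBERG_DEFAULTS",
    "nakamasu_rates",
    "gray_scott_rates",
    "schnakenberg_rates",
    "green_intensity",
    "init_scalewise",
    "init_uniform",
]

# Default coefficient sets.  The three-component values reproduce the adult
# ocellated-lizard labyrinthine pattern; D_w = 12 * D_u encodes the much
# longer range of the w factor.
NAKAMASU_DEFAULTS: dict[str, float] = {
    "c1": -0.04, "c2": -0.056, "c3": 0.382,
    "c4": -0.05, "c5": 0.0, "c6": 0.25,
    "c7": 0.016, "c8": -0.03, "c9": 0.24,
    "c_u": 0.02, "c_v": 0.025, "c_w": 0.06,
    "D_u": 1.125, "D_v": 1.125, "D_w": 13.5,
    "F_max": 0.5, "G_max": 0.5, "H_max": 0.5,
}

GRAY_SCOTT_DEFAULTS: dict[str, float] = {
    "F": 0.042, "k": 0.063, "D_u": 0.15, "D_v": 0.075,
}

SCHNAKENBERG_DEFAULTS: dict[str, float] = {
    "a": 0.1, "b": 0.9, "gamma": 1.0, "d": 40.0,
}

_MODEL_IDS = {"nakamasu": 0, "gray_scott": 1, "schnakenberg": 2}

# colour anchor states used for scale-wise initial conditions
_GREEN_STATE = {
    "nakamasu": (1.2, 6.6, 2.3),
    "gray_scott": (0.5, 0.25),
    "schnakenberg": (0.5, 0.25),
}
_BLACK_STATE = {
    "nakamasu": (5.3, 0.92, 4.0),
    "gray_scott": (0.0, 1.0),
    "schnakenberg": (0.0, 1.0),
}


@dataclass
class KineticsSpec:
    """A reaction-diffusion model plus its full parameter set."""

    model: str = "nakamasu"
    params: dict[str, float] = dc_field(default_factory=dict)
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.model not in _MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(_MODEL_IDS)}")
        defaults = {
            "nakamasu": NAKAMASU_DEFAULTS,
            "gray_scott": GRAY_SCOTT_DEFAULTS,
            "schnakenberg": SCHNAKENBERG_DEFAULTS,
        }[self.model]
        unknown = set(self.params) - set(defaults)
        if unknown:
            raise ValueError(f"unknown parameters for {self.model}: {sorted(unknown)}")
        merged = dict(defaults)
        merged.update(self.params)
        self.params = merged
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if any(d < 0 for d in self.diffusivities):
            raise ValueError("diffusivities must be non-negative")
        if self.model == "nakamasu" and any(
            self.params[k] < 0 for k in ("F_max", "G_max", "H_max")
        ):
            raise ValueError("clipping bounds must be non-negative")

    @property
    def model_id(self) -> int:
        return _MODEL_IDS[self.model]

    @property
    def n_components(self) -> int:
        return 3 if self.model == "nakamasu" else 2

    @property
    def component_names(self) -> tuple[str, ...]:
        return ("u", "v", "w")[: self.n_components]

    @property
    def diffusivities(self) -> tuple[float, ...]:
        p = self.params
        if self.model == "nakamasu":
            return (p["D_u"], p["D_v"], p["D_w"])
        if self.model == "gray_scott":
            return (p["D_u"], p["D_v"])
        return (1.0, p["d"])  # schnakenberg: D_u = 1, D_v = d

    @property
    def green_state(self) -> tuple[float, ...]:
        return _GREEN_STATE[self.model]

    @property
    def black_state(self) -> tuple[float, ...]:
        return _BLACK_STATE[self.model]

    def rates(self, *components: np.ndarray) -> tuple[np.ndarray, ...]:
        """Reaction-only rates for this model (no diffusion)."""
        if self.model == "nakamasu":
            return nakamasu_rates(*components, params=self.params)
        if self.model == "gray_scott":
            return gray_scott_rates(*components, params=self.params)
        return schnakenberg_rates(*components, params=self.params)

    def packed_params(self) -> np.ndarray:
        """Flat coefficient vector consumed by the compiled update kernels."""
        p = self.params
        if self.model == "nakamasu":
            keys = ("c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8", "c9",
                    "c_u", "c_v", "c_w", "F_max", "G_max", "H_max")
        elif self.model == "gray_scott":
            keys = ("F", "k")
        else:
            keys = ("a", "b", "gamma")
        return np.array([p[k] for k in keys], dtype=np.float64)


@dataclass
class FieldState:
    """Named concentration grids on a voxel domain or reduced 2D grid."""

    components: dict[str, np.ndarray]
    domain: object = None
    t: float = 0.0

    def stacked(self) -> np.ndarray:
        return np.stack(list(self.components.values()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.components)

    def copy(self) -> "FieldState":
        return FieldState(
            components={k: v.copy() for k, v in self.components.items()},
            domain=self.domain,
            t=self.t,
        )


# ---------------------------------------------------------------------------
# reaction terms


def _clip(x: np.ndarray, hi: float) -> np.ndarray:
    return np.clip(x, 0.0, hi)


def nakamasu_rates(u, v, w, params: Mapping[str, float] = NAKAMASU_DEFAULTS):
    """Clipped-linear three-component reaction rates (no diffusion).

    Each production term is a linear form in the other two components,
    clipped to ``[0, .max]``, minus first-order decay.
    """
    p = params
    du = _clip(p["c1"] * v + p["c2"] * w + p["c3"], p["F_max"]) - p["c_u"] * u
    dv = _clip(p["c4"] * u + p["c5"] * w + p["c6"], p["G_max"]) - p["c_v"] * v
    dw = _clip(p["c7"] * u + p["c8"] * v + p["c9"], p["H_max"]) - p["c_w"] * w
    return du, dv, dw


def gray_scott_rates(u, v, params: Mapping[str, float] = GRAY_SCOTT_DEFAULTS):
    """Gray-Scott reaction rates: feed F, kill k."""
    uvv = u * v * v
    du = -uvv + params["F"] * (1.0 - u)
    dv = uvv - (params["F"] + params["k"]) * v
    return du, dv


def schnakenberg_rates(u, v, params: Mapping[str, float] = SCHNAKENBERG_DEFAULTS):
    """Schnakenberg reaction rates; homogeneous fixed point (a+b, b/(a+b)^2)."""
    g = params["gamma"]
    uuv = u * u * v
    du = g * (params["a"] - u + uuv)
    dv = g * (params["b"] - uuv)
    return du, dv


def green_intensity(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Green colour intensity g in [0, 1]; 1 = green, 0 = black.

    Where u + v = 0 the ratio is direction-dependent and g is set to the
    neutral value 0.5.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    s = u + v
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s != 0, (v - u) / np.where(s != 0, s, 1.0), 0.0)
    return np.clip(ratio + 0.5, 0.0, 1.0)


# ---------------------------------------------------------------------------
# initial conditions


def _apply_noise(arr: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    if noise == 0:
        return arr
    return arr * (1.0 + rng.uniform(-noise, noise, size=arr.shape))


def _column_state(plan: np.ndarray, domain) -> np.ndarray:
    """Broadcast a plan-view (y, x) field through the occupied columns."""
    if isinstance(domain, VoxelDomain):
        nz = domain.shape[0]
        return np.broadcast_to(plan[None, :, :], (nz,) + plan.shape).copy()
    return plan.copy()


def init_scalewise(
    sm: ScaleMap,
    domain,
    kin: KineticsSpec,
    fraction_black: float = 0.5,
    noise: float = 0.01,
    seed: int | None = 0,
    green_state: tuple[float, ...] | None = None,
    black_state: tuple[float, ...] | None = None,
) -> FieldState:
    """Assign each scale at random to the green or black anchor state.

    Every node of a black scale (through the full column depth) is set to
    the model's black triple, otherwise to the green triple; inter-scale
    border nodes take the state of the nearest scale.  Each node is then
    perturbed multiplicatively by +-``noise``.  The per-model anchor
    defaults can be overridden (some kinetics only ignite from particular
    backgrounds; see the methods note).
    """
    if not (0.0 <= fraction_black <= 1.0):
        raise ValueError("fraction_black must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = sm.n_scales
    black = rng.random(n) < fraction_black
    labels = sm.labels
    if (labels == 0).any():
        # border pixels inherit the colour of the nearest labelled pixel
        _, (iy, ix) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
        labels = labels[iy, ix]
    scale_is_black = np.concatenate([[False], black])[labels]
    green_state = green_state if green_state is not None else kin.green_state
    black_state = black_state if black_state is not None else kin.black_state
    comps: dict[str, np.ndarray] = {}
    for name, gval, bval in zip(kin.component_names, green_state, black_state):
        plan = np.where(scale_is_black, bval, gval).astype(float)
        comps[name] = _apply_noise(_column_state(plan, domain), noise, rng)
    return FieldState(components=comps, domain=domain, t=0.0)


def init_uniform(
    domain,
    kin: KineticsSpec,
    base_state: tuple[float, ...] | None = None,
    noise: float = 0.01,
    seed: int | None = 0,
) -> FieldState:
    """Uniform initial condition with multiplicative +-``noise`` perturbation."""
    rng = np.random.default_rng(seed)
    if base_state is None:
        base_state = kin.green_state
    if len(base_state) != kin.n_components:
        raise ValueError("base_state must provide one value per component")
    if isinstance(domain, VoxelDomain):
        shape = domain.shape
    else:
        shape = np.asarray(domain).shape if not hasattr(domain, "shape") else domain.shape
    comps = {
        name: _apply_noise(np.full(shape, val, dtype=float), noise, rng)
        for name, val in zip(kin.component_names, base_state)
    }
    return FieldState(components=comps, domain=domain, t=0.0)
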