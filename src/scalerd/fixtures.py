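"""Deterministic generators of synthetic test inputs and scenario configs.

Everything here is reproducible bit-for-bit under a fixed seed: striped
ground-truth images for the length-scale metric, noisy (thickness, pigment
height) clouds with a planted quartic bound for the chromatophore fit, and
ready-to-run configuration bundles for the standard experiments at full and
reduced (test) size.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

__all__ = ["make_stripe_image", "make_pigment_cloud", "make_scenario", "SCENARIO_NAMES"]


def make_stripe_image(width: int, period: int, shape: tuple[int, int]) -> np.ndarray:
    """Binary vertical-stripe green-intensity image.

    Foreground (g = 1) columns of width ``width`` repeat every ``period``
    columns.
    """
    if not (0 < width < period):
        raise ValueError("need 0 < width < period")
    ny, nx = shape
    cols = (np.arange(nx) % period) < width
    return np.broadcast_to(cols[None, :], (ny, nx)).astype(float)


def make_pigment_cloud(
    n: int,
    quartic: Sequence[float],
    noise_sd: float,
    seed: int = 0,
    bimodal: bool = False,
) -> np.ndarray:
    """Synthetic (thickness, pigment height) samples with a planted quartic.

    Thickness is uniform on [0.2, 1]; height is the quartic evaluated at the
    thickness plus Gaussian noise, clipped to [0, 1].  With ``bimodal`` half
    the samples are shifted upward by 0.25 (emulating the black-scale mode
    of real pigment-position histograms).
    """
    if n < 1000:
        raise ValueError("need at least 1000 samples for stable bin statistics")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.2, 1.0, size=n)
    h = np.polyval(np.asarray(quartic, dtype=float), t) + rng.normal(0.0, noise_sd, size=n)
    if bimodal:
        h[rng.random(n) < 0.5] += 0.25
    h = np.clip(h, 0.0, 1.0)
    return np.column_stack([t, h])


# ---------------------------------------------------------------------------
# scenario bundles

_NAKAMASU_KINETICS = {"model": "nakamasu", "params": {}, "dt": 0.01}

_SCENARIOS: dict[str, dict] = {
    # hexagonal-prism lattice, scale-by-scale emergence at h_p/h = 0.3
    "fig2": {
        "seed": 0,
        "geometry": {
            "kind": "prism_lattice",
            "n_x": 6, "n_y": 6, "scale_pitch": 20.0,
            "h": 10.0, "h_p": 3.0, "T": 2.0, "spacing": 1.0,
            "periodic": True,
        },
        "kinetics": copy.deepcopy(_NAKAMASU_KINETICS),
        "init": {"kind": "scalewise", "fraction_black": 0.5, "noise": 0.01},
        "solver": {"tol": 1e-7, "check_every": 200, "max_steps": 2_000_000},
    },
    # statistics-derived bottom surface on a Gaussian-bump top surface
    "fig3_synthetic": {
        "seed": 0,
        "geometry": {
            "kind": "gaussian_lattice",
            "n_x": 8, "n_y": 4, "scale_pitch": 30.0, "sigma": 8.0,
            "h": 16.0, "h_p": 5.0, "spacing": 1.0, "periodic": True,
        },
        "statistics": {"min_h": 2.0, "max_h": 16.0, "mode": "full_skin"},
        "kinetics": copy.deepcopy(_NAKAMASU_KINETICS),
        "init": {"kind": "uniform", "noise": 0.01},
        "solver": {"tol": 1e-7, "check_every": 200, "max_steps": 2_000_000},
    },
    # Gaussian-bump lattice: 3D vs dimensionality-reduced 2D comparison
    "fig4": {
        "seed": 0,
        "geometry": {
            "kind": "gaussian_lattice",
            "n_x": 45, "n_y": 48, "scale_pitch": 30.0, "sigma": 8.0,
            "h": 16.0, "h_p": 4.96, "spacing": 3.0, "periodic": True,
        },
        "kinetics": {
            "model": "nakamasu",
            "params": {"D_u": 11.25, "D_v": 11.25, "D_w": 135.0},
            "dt": 0.01,
        },
        "reduction": {"method": "bradley"},
        "init": {"kind": "scalewise", "fraction_black": 0.5, "noise": 0.01},
        "solver": {"tol": 1e-7, "check_every": 200, "max_steps": 2_000_000},
    },
    # quasi-static growth from a random 30%-black scale pattern
    "fig5_random": {
        "seed": 0,
        "geometry": {
            "kind": "gaussian_lattice",
            "n_x": 52, "n_y": 14, "scale_pitch": 20.0, "sigma": 5.5,
            "h": 10.0, "h_p": 3.0, "spacing": 0.58, "periodic": True,
        },
        "kinetics": copy.deepcopy(_NAKAMASU_KINETICS),
        "reduction": {"method": "bradley"},
        "growth": {"delta_tau": 0.05, "n_steps": 19},
        "init": {"kind": "scalewise", "fraction_black": 0.3, "noise": 0.01},
        "solver": {"tol": 1e-7, "check_every": 200, "max_steps": 2_000_000},
    },
}

# smaller / coarser geometries sized for test suites
_REDUCED_OVERRIDES: dict[str, dict] = {
    "fig2": {
        "geometry": {"h": 12.0, "h_p": 3.6, "T": 4.0, "spacing": 2.0},
        "kinetics": {"dt": 0.04},
    },
    "fig3_synthetic": {"geometry": {"n_x": 4, "n_y": 4, "scale_pitch": 20.0, "sigma": 6.0, "h": 10.0, "h_p": 3.0}},
    # at 10x10 the 10x-scaled diffusivities are sub-wavelength; the reduced
    # size keeps the bump geometry and reverts to the base diffusivities
    "fig4": {
        "geometry": {"n_x": 10, "n_y": 10},
        "kinetics": {"params": {"D_u": 1.125, "D_v": 1.125, "D_w": 13.5}, "dt": 0.1},
    },
    "fig5_random": {
        "geometry": {"n_x": 12, "n_y": 6, "scale_pitch": 20.0, "sigma": 5.5, "h": 12.0, "h_p": 3.6, "spacing": 2.0},
        "growth": {"delta_tau": 0.1, "n_steps": 10},
        "kinetics": {"dt": 0.065},
    },
}

SCENARIO_NAMES = tuple(sorted(_SCENARIOS))


def _deep_update(base: dict, upd: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def make_scenario(name: str, size: str = "full") -> dict:
    """Configuration bundle for one of the standard synthetic experiments.

    ``size`` is ``"full"`` for the headline geometry or ``"reduced"`` for a
    smaller lattice suitable for test runs (same physics except where the
    smaller domain requires a matching pattern wavelength).
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    cfg = copy.deepcopy(_SCENARIOS[name])
    if size == "reduced":
        cfg = _deep_update(cfg, _REDUCED_OVERRIDES[name])
    elif size != "full":
        raise ValueError("size must be 'full' or 'reduced'")
    cfg["scenario"] = {"name": name, "size": size}
    return cfg
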