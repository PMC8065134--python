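"""Run configuration: schema, validation and the pipeline driver.

One config file drives every subcommand; sections are ``geometry``,
``kinetics``, ``solver``, ``reduction``, ``growth``, ``init``, ``io`` plus
a top-level ``seed``.  Unknown keys are rejected, and a resolved copy (all
defaults materialised) is written next to the outputs for provenance.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .geometry import (
    HeightField,
    PrismLattice,
    build_gaussian_lattice,
    build_prism_lattice,
    extract_scale_map,
    synthesize_bottom_from_statistics,
    voxelize,
)
from .growth import GrowthSchedule, grow_and_relax, relative_length_scale_series
from .metrics import binarize, border_curvature, extract_borders, homogeneity_error, pattern_length_scale
from .models import FieldState, KineticsSpec, green_intensity, init_scalewise, init_uniform
from .reduce2d import compare_to_3d, integrated_to_state, reduce_geometry, run_reduced_to_steady, state_to_integrated
from .solver3d import SolverConfig, project_plan_view, run_to_steady
from . import io as sio

__all__ = ["load_config", "validate_config", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, dict] = {
    "scenario": {"name": None, "size": "full"},
    "geometry": {
        "kind": None, "n_x": None, "n_y": None, "scale_pitch": None,
        "h": None, "h_p": None, "T": 0.0, "sigma": None, "spacing": 1.0,
        "periodic": True, "path": None, "height_threshold": 0.5,
    },
    "statistics": {"min_h": None, "max_h": None, "mode": "full_skin"},
    "kinetics": {"model": "nakamasu", "params": {}, "dt": 0.01},
    "solver": {"tol": 1e-7, "check_every": 100, "max_steps": 2_000_000, "dt": None},
    "reduction": {"method": "bradley"},
    "growth": {"delta_tau": 0.02, "n_steps": 48},
    "init": {"kind": "scalewise", "fraction_black": 0.5, "noise": 0.01, "base_state": None},
    "io": {"out_dir": None, "image_format": "png", "snapshot_every": 0},
}
_TOP_KEYS = set(_SCHEMA) | {"seed"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Check keys against the schema and materialise all defaults."""
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    resolved: dict = {"seed": int(cfg.get("seed", 0))}
    for section, defaults in _SCHEMA.items():
        given = cfg.get(section, {})
        if given is None:
            given = {}
        if not isinstance(given, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(given) - set(defaults)
        if bad:
            raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(bad)}")
        merged = copy.deepcopy(defaults)
        merged.update(given)
        resolved[section] = merged
    return resolved


def build_geometry(cfg: dict) -> HeightField:
    g = cfg["geometry"]
    kind = g["kind"]
    if kind == "prism_lattice":
        hf = build_prism_lattice(PrismLattice(
            n_x=g["n_x"], n_y=g["n_y"], scale_pitch=g["scale_pitch"],
            h=g["h"], h_p=g["h_p"], T=g["T"], spacing=g["spacing"],
            periodic=g["periodic"],
        ))
    elif kind == "gaussian_lattice":
        hf = build_gaussian_lattice(
            n_x=g["n_x"], n_y=g["n_y"], sigma=g["sigma"], h=g["h"],
            h_p=g["h_p"], spacing=g["spacing"], scale_pitch=g["scale_pitch"],
            periodic=g["periodic"],
        )
    elif kind == "height_map":
        hf = sio.read_height_map(g["path"])
    else:
        raise ConfigError(f"unknown geometry kind {kind!r}")
    st = cfg.get("statistics", {})
    if st.get("min_h") is not None:
        hf = synthesize_bottom_from_statistics(
            hf.z_top, min_h=st["min_h"], max_h=st["max_h"], mode=st["mode"],
            spacing=hf.spacing, periodic_xy=hf.periodic_xy,
        )
    return hf


def build_kinetics(cfg: dict) -> KineticsSpec:
    k = cfg["kinetics"]
    missing = {"model", "params", "dt"} - set(k)
    if missing:
        raise ConfigError(f"kinetics section missing key(s): {sorted(missing)}")
    return KineticsSpec(model=k["model"], params=dict(k["params"] or {}), dt=k["dt"])


def build_solver(cfg: dict) -> SolverConfig:
    s = cfg["solver"]
    return SolverConfig(dt=s["dt"], tol=s["tol"], check_every=s["check_every"], max_steps=s["max_steps"])


def _build_initial(cfg: dict, sm, domain, kin: KineticsSpec) -> FieldState:
    ini = cfg["init"]
    if ini["kind"] == "scalewise":
        return init_scalewise(
            sm, domain, kin, fraction_black=ini["fraction_black"],
            noise=ini["noise"], seed=cfg["seed"],
        )
    if ini["kind"] == "uniform":
        base = tuple(ini["base_state"]) if ini["base_state"] else None
        return init_uniform(domain, kin, base_state=base, noise=ini["noise"], seed=cfg["seed"])
    raise ConfigError(f"unknown init kind {ini['kind']!r}")


def _plan_domain_for_init(sm, rd):
    """A 2D stand-in domain so init builders produce plan-view grids."""
    return rd


def run_pipeline(cfg: dict, task: str, out_dir: str | Path | None = None) -> dict:
    """Execute one configured experiment and return the metric report.

    Tasks: ``simulate3d`` (full voxel run), ``reduce2d`` (reduced 2D run
    with the configured method), ``compare`` (3D plus both reduction
    methods, with scale-colour disagreement), ``grow`` (quasi-static
    growth trajectory).
    """
    cfg = validate_config(cfg)
    t0 = time.time()
    out = Path(out_dir or cfg["io"]["out_dir"] or ".")
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg))
    kin = build_kinetics(cfg)
    scfg = build_solver(cfg)
    hf = build_geometry(cfg)
    report: dict = {"task": task, "seed": cfg["seed"]}

    def finish() -> dict:
        report["runtime_s"] = round(time.time() - t0, 2)
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
        return report

    if task == "simulate3d":
        dom = voxelize(hf)
        sm = extract_scale_map(hf, cfg["geometry"]["height_threshold"])
        state = _build_initial(cfg, sm, dom, kin)
        every = int(cfg["io"]["snapshot_every"] or 0)
        if every > 0:
            # integrate in snapshot-sized chunks, writing a plan view each
            import dataclasses

            steps = 0
            converged = False
            snap = 0
            while steps < scfg.max_steps and not converged:
                chunk = dataclasses.replace(scfg, max_steps=min(every, scfg.max_steps - steps))
                state, s, converged = run_to_steady(state, kin, chunk)
                steps += s
                snap += 1
                sio.write_pattern(out / f"snapshot_{snap:04d}.png", project_plan_view(state, dom, "mean"))
        else:
            state, steps, converged = run_to_steady(state, kin, scfg)
        g = project_plan_view(state, dom, "mean")
        _, mean_err = homogeneity_error(g, sm)
        report.update(steps=steps, converged=converged, mean_homogeneity_error=mean_err)
        sio.write_pattern(out / "steady_plan.png", g)
        sio.save_state_arrays(out / "steady_state.npz", **state.components)
        return finish()

    if task in ("reduce2d", "compare"):
        sm = extract_scale_map(hf, cfg["geometry"]["height_threshold"])
        methods = [cfg["reduction"]["method"]] if task == "reduce2d" else ["fick_jacobs", "bradley"]
        rd0 = reduce_geometry(hf, method=methods[0])
        plan_state = _build_initial(cfg, sm, rd0, kin)
        results = {}
        for method in methods:
            rd = reduce_geometry(hf, method=method)
            Q = state_to_integrated(plan_state, rd)
            Q, steps, converged = run_reduced_to_steady(Q, rd, kin, scfg)
            st = integrated_to_state(Q, plan_state.names, rd)
            g = green_intensity(st.components["u"], st.components["v"])
            results[method] = g
            report[method] = {"steps": steps, "converged": converged}
            sio.write_pattern(out / f"steady_{method}.png", g)
        if task == "compare":
            dom = voxelize(hf)
            state3 = _build_initial(cfg, sm, dom, kin)
            state3, steps, converged = run_to_steady(state3, kin, scfg)
            g3 = project_plan_view(state3, dom, "mean")
            sio.write_pattern(out / "steady_3d.png", g3)
            report["3d"] = {"steps": steps, "converged": converged}
            for method, g in results.items():
                wrong, diff = compare_to_3d(g3, g, sm)
                report[method]["wrong_colour_pct"] = wrong
                report[method]["mean_abs_diff_pct"] = diff
        return finish()

    if task == "grow":
        sm = extract_scale_map(hf, cfg["geometry"]["height_threshold"])
        rd0 = reduce_geometry(hf, method=cfg["reduction"]["method"])
        plan_state = _build_initial(cfg, sm, rd0, kin)
        sched = GrowthSchedule(**cfg["growth"])
        traj = grow_and_relax(
            plan_state, hf, kin, scfg, sched, r_avg_px=sm.r_avg_px,
            method=cfg["reduction"]["method"],
        )
        series = relative_length_scale_series(traj)
        rows = ["tau,normalized_size,length_scale,curvature,steps,converged"]
        for r in traj:
            rows.append(f"{r.tau},{r.normalized_size},{r.length_scale},{r.curvature},{r.steps},{r.converged}")
        (out / "trajectory.csv").write_text("\n".join(rows) + "\n")
        for r in traj:
            sio.write_pattern(out / f"pattern_tau{r.tau:03d}.png", r.image)
        report.update(
            length_scale_series=series.tolist(),
            curvature_series=[r.curvature for r in traj],
            converged_all=all(r.converged for r in traj),
        )
        return finish()

    raise ConfigError(f"unknown task {task!r}")


def measure_image(path: str | Path, r_avg: float, mode: str = "fixed", blur: float = 0.0) -> dict:
    """Length scale and border curvature of a pattern image file."""
    from PIL import Image

    img = np.asarray(Image.open(path))
    binary = binarize(img, mode=mode, blur=blur)
    ls = pattern_length_scale(binary, r_avg)
    try:
        curv = border_curvature(extract_borders(binary), r_avg)
    except ValueError:
        curv = float("nan")
    return {
        "image": str(path),
        "r_avg_px": r_avg,
        "length_scale": ls.mean,
        "length_scale_flagged": ls.flagged,
        "curvature": curv,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
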