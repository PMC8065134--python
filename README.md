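# scalerd

Reaction-diffusion colour patterning on 3D skin-scale geometries.

Adult ocellated lizards wear a labyrinthine mosaic of green and black
skin scales in which each scale is monochromatic and scales flip colour
like cells of a cellular automaton. `scalerd` implements the physical
explanation for that behaviour: the skin is a *thin 3D reaction-diffusion
domain whose thickness drops several-fold in the narrow channels between
scales* (thickness ratio h_p/h ≈ 0.3 in real skin), and that geometry
alone — with spatially constant diffusivities — quantises a continuous
Turing pattern to the lattice of scales.

The package provides, for people who model pigmentation patterning or
reaction-diffusion on corrugated thin domains:

- **Synthetic skin geometries** (`scalerd.geometry`): hexagonal-prism
  lattices, quasi-hexagonal Gaussian-bump lattices, bottom surfaces
  synthesised from measured thickness statistics, and the quartic lower
  bound of the pigment-cell layer fitted from (thickness, pigment height)
  clouds; height-map import/export (16-bit TIFF/PNG + JSON sidecar, CSV).
- **Kinetics** (`scalerd.models`): the three-component clipped-linear
  melanophore/xanthophore network du/dt = F(u,v,w) − c_u u + D_u∇²u (and
  cyclic), Gray-Scott, and Schnakenberg; the green read-out
  g = clip((v−u)/(v+u) + 0.5, 0, 1); scale-wise and uniform initial
  conditions with ±1% multiplicative noise.
- **A 3D voxel solver** (`scalerd.solver3d`): Euler forward with the
  7-point stencil on masked voxel domains, periodic/no-flux boundaries,
  the steady-state criterion Σ|Δc| < 10⁻⁷ per node, compiled inner loops.
- **3D→2D thin-domain reduction** (`scalerd.reduce2d`):
  ∂Q/∂t = ∇·(Dz∇(Q/z)) + f(Q/z)z for the thickness-integrated
  concentration Q, with constant (Fick-Jacobs) or slope-penalised
  effective diffusivity D(x) = D/(1 + (∂z₀/∂x)² + (∂z/∂x)²/12) (Bradley),
  and a scale-by-scale comparison against full 3D runs.
- **Quasi-static growth** (`scalerd.growth`): L(τ) = (1 + τΔτ)·L(0) at
  fixed element count, re-relaxing to steady state each increment.
- **Pattern morphometrics** (`scalerd.metrics`): binarisation (fixed
  127.5 threshold for renders, deterministic 1-D k-means for
  photographs), border extraction, relative pattern length scale
  (border distances in units of the mean scale radius r_avg), Menger
  border curvature, and the per-scale colour homogeneity error
  e(p) = min(green(p), 1 − green(p)).

## Worked example

Render a 6×6 hexagonal-prism lattice with realistic inter-scale thinning
(h_p/h = 0.3), start from a random half-black scale assignment, integrate
the three-component system to steady state and score how monochromatic
the scales ended up:

```python
from scalerd import (PrismLattice, build_prism_lattice, extract_scale_map,
                     voxelize, KineticsSpec, init_scalewise, SolverConfig,
                     run_to_steady, project_plan_view, homogeneity_error)

spec = PrismLattice(n_x=6, n_y=6, scale_pitch=20.0, h=12.0, h_p=3.6,
                    T=4.0, spacing=2.0, periodic=True)
hf  = build_prism_lattice(spec)
sm  = extract_scale_map(hf)            # 36 scales, d_avg = 20
dom = voxelize(hf)
kin = KineticsSpec("nakamasu")         # printed defaults, dt = 0.01
ic  = init_scalewise(sm, dom, kin, fraction_black=0.5, seed=1)
state, steps, ok = run_to_steady(ic, kin, SolverConfig(dt=0.04, check_every=2000))
g = project_plan_view(state, dom, "mean")
print(sm.n_scales, steps, ok, round(homogeneity_error(g, sm)[1], 4))
```

prints

```
36 48000 True 0.0078
```

— after 48,000 steps the pattern is steady and the mean homogeneity error
is 0.0078: every prism is essentially one colour, even though nothing in
the equations knows about prisms. Rebuilding the same lattice with
h_p = h (a flat slab) and rerunning raises the error to 0.0513 — the
labyrinth then freely crosses prism borders. That contrast is the
geometry-driven discretisation effect at the heart of the package.

The same studies are scripted as CLI scenarios:

```bash
scalerd fixtures --name fig2 --size reduced --out fig2.yaml
scalerd simulate3d --config fig2.yaml --out out/ --seed 1
scalerd measure --image out/steady_plan.png --r-avg 5
```

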