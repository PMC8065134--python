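# Methods

`scalerd` simulates reaction-diffusion (RD) colour patterning in thin,
corrugated skin — the geometry of squamate (lizard) skin, where the dermis
is thick inside each scale and several-fold thinner in the inter-scale
channels — and measures the resulting patterns. This note records the
models, the numerical choices, and what the synthetic test conditions do
and do not establish.

## Reaction kinetics

Three models are implemented (module `models`); concentrations are
dimensionless and live on a regular grid of spacing ε.

**Three-component clipped-linear network** (`nakamasu`). u and v are
short-range factors (melanophore-like and xanthophore-like), w a long-range
factor:

    du/dt = F(u,v,w) − c_u u + D_u ∇²u
    dv/dt = G(u,v,w) − c_v v + D_v ∇²v
    dw/dt = H(u,v,w) − c_w w + D_w ∇²w

with F = clip(c₁v + c₂w + c₃, 0, F_max) and analogously G (c₄u + c₅w + c₆,
G_max), H (c₇u + c₈v + c₉, H_max). Clipping is two-sided; production terms
are therefore bounded and, combined with linear decay, single-node Euler
integration preserves non-negativity for dt ≤ min(1/c_u, 1/c_v, 1/c_w).
Defaults: c₁ = −0.04, c₂ = −0.056, c₃ = 0.382, c₄ = −0.05, c₅ = 0,
c₆ = 0.25, c₇ = 0.016, c₈ = −0.03, c₉ = 0.24, c_u = 0.02, c_v = 0.025,
c_w = 0.06, D_u = D_v = 1.125, D_w = 12·D_u = 13.5,
F_max = G_max = H_max = 0.5, dt = 0.01. The linearised system around its
interior fixed point has a Turing band peaking at wavelength λ ≈ 86 length
units (computed from the dispersion relation with the defaults above);
that number sets every domain-size choice below.

**Gray–Scott** (`gray_scott`): du/dt = −uv² + F(1−u) + D_u∇²u,
dv/dt = uv² − (F+k)v + D_v∇²v, with F = 0.042, k = 0.063, D_u = 0.15,
D_v = 0.075. At these parameters the only homogeneous steady state is the
trivial substrate state (u,v) = (1,0); patterns are excited states that
must be ignited by localised v-rich seeds on a substrate-rich background
(seed-test wavelength ≈ 12 length units).

**Schnakenberg** (`schnakenberg`): du/dt = γ(a − u + u²v) + ∇²u,
dv/dt = γ(b − u²v) + d∇²v, with a = 0.1, b = 0.9, γ = 1, d = 40
(diffusivities 1 and d). Homogeneous fixed point (a+b, b/(a+b)²) = (1.0,
0.9); Turing wavelength λ ≈ 15 length units from the dispersion relation.

**Colour read-out.** g = min(max((v−u)/(v+u) + 0.5, 0), 1); g = 1 renders
green, 0 black. At u + v = 0 the limit is direction-dependent; g is defined
as the neutral 0.5 there. The 0.5 offset makes green and black stripe
widths symmetric; it is not a tunable.

**Initial conditions.** Scale-wise: every scale is independently black with
probability `fraction_black`, all its nodes through the column depth set to
the model's black anchor, else the green anchor; then every node is
multiplied by (1 + U(−0.01, 0.01)) — the noise is multiplicative because
the Gray–Scott anchors contain exact zeros that additive noise would
distort. Anchors: three-component green (1.2, 6.6, 2.3), black (5.3, 0.92,
4); two-component green (0.5, 0.25), black (0, 1). Nodes in the inter-scale
channels take the colour of the nearest scale. Uniform: one value per
component, same noise.

*A caveat on the Gray–Scott anchors.* Under the Gray–Scott kinetics above,
both recorded anchor states decay: (0, 1) has zero autocatalysis (u = 0)
and v dies at rate F + k, while extended (0.5, 0.25) regions sit above the
saddle and collapse to (1, 0) because no interior homogeneous steady state
exists (F < 4(F+k)²). We verified this at grid spacings from 0.1 to 0.6,
domains up to five pattern wavelengths, black fractions 0.1–0.5, in flat
2D and full 3D: every such initial condition reaches the uniform trivial
state. Scale-wise Gray–Scott experiments in this package therefore use the
trivial state (1, 0) as the black anchor — the state that actually renders
black under g — so that green (0.5, 0.25) scales act as localised seeds on
the substrate background, which is the canonical ignition route for this
model. `init_scalewise` keeps the recorded anchors as defaults and accepts
overrides.

## 3D solver (module `solver3d`)

Explicit Euler forward; Laplacian by the 7-point stencil
(Σ neighbours − 6u)/ε². Boundaries: periodic or no-flux in x/y, always
no-flux at the irregular top/bottom skin surfaces. No-flux is implemented
by mirroring the centre value into any neighbour outside the occupancy
mask — first-order zero flux consistent with the stencil, and exactly
mass-conserving in flux terms (verified to 10⁻¹⁰ relative over 10⁴ steps).
All components update simultaneously from the previous state.

Steady state: integration stops when every node satisfies
Σ_components |c(t) − c(t−dt)| < tol, tol = 10⁻⁷, checked every
`check_every` = 100 steps (default; the heavy experiments use 2000 to
amortise the check). The explicit stability bound dt ≤ ε²/(2·n_dim·D_max)
is enforced; an override flag exists for experimentation.

The inner loops are compiled with numba. They are semantically identical
to the vectorised numpy implementations (`step`, `step_reduced`), which
remain the reference: the test suite asserts agreement to ~10⁻¹² over
multi-step runs on masked, mixed-boundary domains.

Plan-view projection: per (x,y) column, g of the z-averaged u and v
(`mean`), or g at the highest/lowest occupied voxel (`top`/`bottom`).
Empty columns are NaN.

## Geometry (module `geometry`)

*Hexagonal prisms.* Scale centres on a triangular lattice (odd rows offset
half a pitch); each scale is the hexagonal Voronoi cell shrunk so that a
channel of width T separates neighbours (apothem (pitch − T)/2, edge
normals facing the six neighbours). z_top is h on plateaus, h_p in
channels, z_bottom = 0. Periodic lattices require an even row count —
odd counts break the offset parity across the wrap. Non-periodic lattices
get a margin so edge hexagons render whole.

*Gaussian bumps.* Per scale a symmetric Gaussian a·exp(−r²/2σ²) + b with a
and b solved so the surface is exactly h at the centre and h_p at the
border midpoint; overlapping bumps combine by pointwise maximum, which
preserves both fitted values (the blending rule is this package's choice).

*Statistics-derived bottom surfaces.* Given a top surface, the normalised
thickness map sends its observed range affinely onto [min_h/max_h, 1];
the full-skin bottom subtracts norm·max_h, and the chromatophore-restricted
bottom subtracts (norm − p(norm))·max_h where p is the fitted quartic lower
bound of the pigment layer. The bound is fitted per thickness bin
(default 150 bins) as mean − 3·std of pigment height, least-squares quartic
through the per-bin mean thicknesses (the unbiased abscissa; bin centres
differ by < half a bin width).

*Voxelisation.* Isotropic ε in x, y, z (so the stencil applies unchanged);
voxel (i,j,k) occupied iff z_bottom ≤ (k+½)ε < z_top. Columns are
contiguous by construction; a column thinner than one voxel is an error.

*Scale maps.* Scales are connected components of thickness >
min + f·(max − min) (default f = 0.5, which separates plateau from channel
for every h_p/h < 1); components are merged across periodic seams and
centroids use the circular mean on periodic axes. d_avg is the mean
nearest-neighbour centroid distance; r_avg = d_avg/2 is the unit of the
pattern metrics.

## 2D reduction (module `reduce2d`)

For thickness z(x,y) = z_top − z_bottom and integrated concentration
Q = c·z (valid when c varies little across the thin dimension):

    ∂Q/∂t = ∇·(D z ∇(Q/z)) + f(Q/z) z.

Fick–Jacobs keeps D constant; Bradley substitutes, per direction,

    D(x) = D / (1 + (∂z₀/∂x)² + (1/12)(∂z/∂x)²)

with midline z₀ = (z_top + z_bottom)/2 — the regularised form, which stays
positive for arbitrary slopes. The two directions are assembled as a
diagonal matrix: anisotropy from thickness variation is captured only
along the grid axes, a fidelity limit shared with the approach this
implements; the `compare_to_3d` operation quantifies the residual error
instead of correcting it.

Discretisation is flux-conservative: face transmissibilities D·z by
arithmetic mean of the adjacent nodes (harmonic mean available as a flag;
for smooth surfaces with h_p/h ≥ 0.06 the difference is negligible),
divergence of face fluxes of c = Q/z, reaction f(c)·z. Slopes by central
differences, one-sided at non-periodic edges. Mass Σ Q ε² is conserved to
10⁻¹⁰ with zero reaction. The same steady-state criterion is applied to
the per-step change of c.

## Quasi-static growth (module `growth`)

Patterning is much faster than somatic growth, so growth is a sequence of
equilibria: at step τ the physical domain size is L(τ) = (1 + τ·Δτ)·L(0)
at fixed element count (implemented as rescaling the grid spacing), the
thickness map and Bradley diffusivities are recomputed on the rescaled
geometry, and the reduced system is relaxed back to steady state with the
concentration fields carried over unchanged. Heights are *not* rescaled by
growth — skin thickness statistics are treated as age-independent, an
assumption in the absence of contrary data. Δτ defaults to 0.02 with
n_steps chosen to reach ≈ 1.95× the initial size; both are configurable
(the increment is not a published value). Because scales stretch with the
domain, r_avg in grid elements is constant along the trajectory while the
RD wavelength in elements shrinks — that is the entire mechanism by which
the relative pattern length scale decreases and borders become more
labyrinthine.

## Pattern metrics (module `metrics`)

*Binarisation.* Simulation renders: fixed threshold at 127.5 on the 0–255
scale (g·255), no preprocessing. Photographs: grey conversion, Gaussian
blur (σ = r_avg/4 unless given), deterministic 1-D two-cluster k-means
(centres initialised at the 25th/75th percentiles, Lloyd iterations; no
seed dependence, so the metric is bitwise reproducible).

*Borders.* Border pixels are foreground pixels 8-adjacent to background
(the image frame counts as background, so frame-touching regions close
along it); ordered closed polylines are traced at the 0.5 level of the
zero-padded binary image.

*Length scale.* Euclidean distance of every foreground pixel to the
nearest border pixel, divided by r_avg; the global value is the mean of
normalised distances strictly > 1 (pixels within one scale radius of a
border carry no width information). If nothing exceeds 1 the result is
1.0 with a flag. Isotropic distances make the metric invariant under
rotation and mirroring to within discretisation.

*Border curvature.* Sample points every r_avg of arclength along each
closed contour; companions at ±5·r_avg of arclength; Menger curvature =
reciprocal circumradius of the three points, normalised as r_avg/r_M.
Collinear triples contribute 0; contours shorter than twice the reach are
skipped. On a digitised circle of radius R ≥ 20·r_avg the estimate is
within 10% of r_avg/R.

*Colour homogeneity.* green(p) = mean g over the plan-view nodes of scale
p; e(p) = min(green(p), 1 − green(p)) ∈ [0, 0.5]; the pattern error is the
mean over scales. Scale classification: green iff green(p) > 0.5, ties
black (a deterministic convention).

## Synthetic test conditions and problem sizes

The synthetic generators (`fixtures`) emulate the study conditions:
quasi-hexagonal scale lattices with inter-scale thickness ratios in
0.06–1.0 (≈ 0.3 is the measured value in real skin), scale-wise random
binary initial colours with ±1% node noise, pigment-position clouds with a
planted quartic lower bound, and stripe images of known geometry. They do
not emulate: irregular real scale shapes and sizes, measurement noise in
reconstructed surfaces, ocelli or regional pattern heterogeneity, or
photograph illumination. Passing tests therefore establish the numerical
machinery and the geometry-driven discretisation effect, not fidelity to
any individual animal.

Default experiment sizes (chosen so the full suite runs on one CPU in
minutes; the physics, not the grid, is the object under test):

- Prism-lattice emergence: 6×6 scales, pitch 20, h = 12, h_p = 3.6, T = 4,
  ε = 2, dt = 0.04 (within the stability bound ε²/(6·D_w) ≈ 0.049). The
  domain (120×104 length units) slightly exceeds one Turing wavelength —
  the minimum for the flat control to hold a pattern. The printed
  experiments used ε = 1; halving ε here changes the homogeneity errors by
  far less than the 6× contrast between corrugated and flat domains.
- Two-component robustness: lattice scale set per model from its
  wavelength (Schnakenberg pitch 5, ε = 0.5, dt = 10⁻³; Gray–Scott
  pitch 6, ε = 0.5, dt = 0.1 — both within their stability bounds;
  channels T = 2 nodes, h = 6 voxels, h_p/h = 0.3 as in the
  three-component study). The Gray–Scott steady state under these
  conditions is a sparse arrangement of green scales frozen onto the
  lattice — thin channels pin the excited spots scale-by-scale, which is
  precisely the discretisation effect under test.
- Reduction comparison: 10×10 Gaussian-bump lattice at the reference bump
  geometry (ε = 3, σ = 8, h = 16, h_p/h = 0.31) with the base
  three-component diffusivities (D_u = D_v = 1.125, D_w = 13.5, dt = 0.1),
  so the domain spans ~3.5 pattern wavelengths and all three systems reach
  the steady criterion. The reference comparison scales the diffusivities
  ×10, which stretches the wavelength to ~91 grid nodes and needs the
  full-size 45×48 lattice — available as the `fig4` scenario.
- Growth: a 12×6 quasi-hexagonal Gaussian-bump lattice (pitch 20, ε = 2,
  h_p/h = 0.3, dt = 0.065) grown from normalised size 1 to 2.0 in 10%
  increments; replicate ensembles of a few seeds (the full protocol is 20
  replicates; the scripts expose `--replicates`).

*Relaxation horizons.* Scale-locked steady states are approached through a
very slow residual drift of stripe borders (the CA-like metastability that
is the subject of study); the per-node 10⁻⁷ criterion can take an order of
magnitude longer than the pattern itself needs to settle. The canned
experiments therefore integrate to the criterion *or* to a fixed step
horizon, whichever comes first, and report the convergence flag; the
horizons (e.g. 14,000 time units for the flat prism control, 20,000 for the
three-way reduction comparison, 6,500 per growth increment) sit far beyond
the point where the reported metrics stop changing at their printed
precision. Comparisons always share one horizon across the systems being
compared.

## Known limitations

- The reduction ignores off-diagonal effective-diffusivity terms; locally
  steep geometry is under-corrected (quantified by `compare_to_3d`, not
  fixed).
- No implicit or adaptive time stepping; run times scale with 1/dt at the
  explicit stability bound.
- Voxel (staircase) surfaces only; no tetrahedral meshes, no reconstruction
  from raw imaging stacks.
- The Gray–Scott scale-wise experiment requires the anchor substitution
  described above; with the recorded (0, 1) black anchor the model reaches
  the uniform trivial state from every configuration we tested.
- The growth driver assumes isotropic growth and age-independent thickness;
  neither is exact in real animals.
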