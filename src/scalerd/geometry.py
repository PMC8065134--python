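"""Synthetic and statistics-derived 3D skin domains.

Lizard skin is a thin, corrugated sheet: thick within each scale and much
thinner in the inter-scale channels (thickness ratio roughly 0.06-1).  This
module builds such domains as paired top/bottom height maps on a regular
grid -- hexagonal-prism lattices, lattices of Gaussian bumps, and bottom
surfaces synthesised from measured thickness statistics -- and derives the
plan-view labelling of individual scales that the colour metrics need.

Conventions: 2D grids are indexed ``[row, col] == [y, x]``; 3D voxel masks
``[z, y, x]``.  All lengths (heights, pitches, spacings) share one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "HeightField",
    "PrismLattice",
    "VoxelDomain",
    "ScaleMap",
    "ChromatophoreBound",
    "build_prism_lattice",
    "build_gaussian_lattice",
    "synthesize_bottom_from_statistics",
    "fit_chromatophore_bound",
    "extract_scale_map",
    "rescale_surface",
    "voxelize",
]

_ROW_SPACING = np.sqrt(3.0) / 2.0  # row spacing of a triangular lattice, in pitches


def _check_periodic_rows(n_y: int, periodic: bool) -> None:
    # the offset row pattern has period 2: an odd row count cannot tile a torus
    if periodic and n_y % 2 != 0:
        raise ValueError("periodic triangular lattices require an even number of rows (n_y)")


@dataclass
class HeightField:
    """Thin 3D domain bounded below by ``z_bottom`` and above by ``z_top``.

    Both surfaces live on the same regular (y, x) grid with isotropic
    spacing.  Thickness ``z_top - z_bottom`` must be positive everywhere.
    """

    z_top: np.ndarray
    z_bottom: np.ndarray
    spacing: float
    periodic_xy: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        self.z_top = np.asarray(self.z_top, dtype=float)
        self.z_bottom = np.asarray(self.z_bottom, dtype=float)
        if self.z_top.shape != self.z_bottom.shape:
            raise ValueError("z_top and z_bottom must share one grid shape")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if np.any(self.thickness <= 0):
            raise ValueError("domain thickness must be strictly positive everywhere")

    @property
    def thickness(self) -> np.ndarray:
        return self.z_top - self.z_bottom

    @property
    def midline(self) -> np.ndarray:
        return 0.5 * (self.z_top + self.z_bottom)

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_top.shape


@dataclass
class PrismLattice:
    """Parameters of a hexagonal-prism scale lattice.

    ``h`` is the skin thickness within a scale, ``h_p`` the (smaller)
    thickness of the inter-scale channels, ``T`` the channel width and
    ``scale_pitch`` the centre-to-centre distance of neighbouring scales.
    """

    n_x: int
    n_y: int
    scale_pitch: float
    h: float
    h_p: float
    T: float
    spacing: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.h_p <= self.h):
            raise ValueError("need 0 < h_p <= h")
        if not (0 <= self.T < self.scale_pitch):
            raise ValueError("need 0 <= T < scale_pitch")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("need at least one scale in each direction")


@dataclass
class VoxelDomain:
    """3D boolean occupancy grid, ``mask[z, y, x]``, with isotropic spacing."""

    mask: np.ndarray
    spacing: float
    periodic_xy: tuple[bool, bool] = (False, False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_occupied(self) -> int:
        return int(self.mask.sum())

    def column_heights(self) -> np.ndarray:
        """Number of occupied voxels per (y, x) column."""
        return self.mask.sum(axis=0)


@dataclass
class ScaleMap:
    """Plan-view labelling of scales: 0 = inter-scale border, k >= 1 = scale k."""

    labels: np.ndarray
    centroids: np.ndarray  # (n, 2) array of (y, x) in grid units
    d_avg: float  # mean nearest-neighbour centroid distance, length units
    spacing: float

    @property
    def n_scales(self) -> int:
        return len(self.centroids)

    @property
    def r_avg(self) -> float:
        """Mean scale radius: half the mean centre-to-centre distance."""
        return self.d_avg / 2.0

    @property
    def r_avg_px(self) -> float:
        return self.r_avg / self.spacing


@dataclass
class ChromatophoreBound:
    """Quartic lower bound of the pigment-cell layer vs normalised thickness.

    ``coefficients`` are highest-order-first (``numpy.polyval`` layout).
    """

    coefficients: np.ndarray
    fit_bins: int
    fit_range: tuple[float, float] = (0.0, 1.0)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(self.coefficients, x)


# ---------------------------------------------------------------------------
# lattice construction


def _lattice_centres(
    n_x: int, n_y: int, pitch: float, periodic: bool = True
) -> tuple[np.ndarray, float, float]:
    """Triangular-lattice scale centres; odd rows offset by half a pitch.

    Returns (centres (n,2) as (y,x), extent_x, extent_y).  Periodic extents
    tile the plane; non-periodic lattices get a half-pitch margin so edge
    hexagons render in full.
    """
    row = pitch * _ROW_SPACING
    # hexagon vertices reach pitch/sqrt(3) from the centre in y
    my = 0.6 * pitch if not periodic else 0.0
    mx = 0.5 * pitch if not periodic else 0.0
    ys, xs = [], []
    for j in range(n_y):
        off = 0.5 * pitch if (j % 2) else 0.0
        for i in range(n_x):
            xs.append(i * pitch + off + mx)
            ys.append(j * row + my)
    centres = np.column_stack([ys, xs]).astype(float)
    return centres, n_x * pitch + 2 * mx, n_y * row + 2 * my


def _grid_for_extent(extent_x: float, extent_y: float, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    nx = int(round(extent_x / spacing))
    ny = int(round(extent_y / spacing))
    # node-centred grid: node (0, 0) coincides with the first scale centre
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    return y, x


def _displacement_to_nearest(
    yy: np.ndarray,
    xx: np.ndarray,
    centres: np.ndarray,
    extent_x: float,
    extent_y: float,
    periodic: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per grid node: (dy, dx, centre index) to the nearest lattice centre.

    For periodic lattices the nearest centre is found under the minimum-image
    convention by tiling ghost copies of the centres.
    """
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    if periodic:
        shifts = [
            (sy * extent_y, sx * extent_x)
            for sy in (-1, 0, 1)
            for sx in (-1, 0, 1)
        ]
        tiled = np.vstack([centres + np.array(s) for s in shifts])
        owner = np.tile(np.arange(len(centres)), len(shifts))
    else:
        tiled = centres
        owner = np.arange(len(centres))
    tree = cKDTree(tiled)
    _, idx = tree.query(pts, k=1)
    d = pts - tiled[idx]
    return d[:, 0].reshape(yy.shape), d[:, 1].reshape(yy.shape), owner[idx].reshape(yy.shape)


def _hex_distance(dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Hexagon support function for the triangular lattice used here.

    Edge normals point at the six in-row / cross-row neighbours (0 and
    +-60 degrees from the x axis); a point lies inside the hexagon of
    apothem ``a`` iff this distance is <= ``a``.
    """
    c, s = 0.5, _ROW_SPACING
    return np.maximum.reduce(
        [np.abs(dx), np.abs(c * dx + s * dy), np.abs(c * dx - s * dy)]
    )


def build_prism_lattice(spec: PrismLattice) -> HeightField:
    """Render a hexagonal-prism lattice to a height field.

    Flat bottom at 0; top at ``h`` inside each hexagonal plateau (apothem
    ``(scale_pitch - T) / 2``) and ``h_p`` in the channels between.
    """
    if spec.T > 0 and spec.T < spec.spacing:
        raise ValueError(
            f"spacing {spec.spacing} too coarse to resolve the inter-scale "
            f"border width T={spec.T}: less than one node across the channel"
        )
    _check_periodic_rows(spec.n_y, spec.periodic)
    centres, ex, ey = _lattice_centres(spec.n_x, spec.n_y, spec.scale_pitch, spec.periodic)
    y, x = _grid_for_extent(ex, ey, spec.spacing)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    dy, dx, _ = _displacement_to_nearest(yy, xx, centres, ex, ey, spec.periodic)
    apothem = 0.5 * (spec.scale_pitch - spec.T)
    inside = _hex_distance(dy, dx) <= apothem
    z_top = np.where(inside, spec.h, spec.h_p)
    return HeightField(
        z_top=z_top,
        z_bottom=np.zeros_like(z_top),
        spacing=spec.spacing,
        periodic_xy=(spec.periodic, spec.periodic),
    )


def build_gaussian_lattice(
    n_x: int,
    n_y: int,
    sigma: float,
    h: float,
    h_p: float,
    spacing: float,
    scale_pitch: float,
    periodic: bool = True,
) -> HeightField:
    """Lattice of symmetric 2D Gaussian bumps on a triangular lattice.

    Each scale contributes ``a * exp(-r^2 / (2 sigma^2)) + b`` with ``a`` and
    ``b`` fitted so the surface equals ``h`` at the scale centre and ``h_p``
    at the midpoint between neighbouring centres; overlapping bumps are
    blended by the pointwise maximum, which preserves both fitted values.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if h_p > h:
        raise ValueError("need h_p <= h")
    _check_periodic_rows(n_y, periodic)
    e_mid = np.exp(-((scale_pitch / 2.0) ** 2) / (2.0 * sigma**2))
    if e_mid > 0.99:
        raise ValueError(
            "sigma too large relative to the scale pitch: centre/border "
            "contrast cannot be fitted (a <= 0)"
        )
    a = (h - h_p) / (1.0 - e_mid)
    b = h - a
    centres, ex, ey = _lattice_centres(n_x, n_y, scale_pitch, periodic)
    y, x = _grid_for_extent(ex, ey, spacing)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    # the pointwise max over bumps is attained by the nearest centre
    dy, dx, _ = _displacement_to_nearest(yy, xx, centres, ex, ey, periodic)
    r2 = dy**2 + dx**2
    z_top = a * np.exp(-r2 / (2.0 * sigma**2)) + b
    if np.any(z_top <= 0):
        raise ValueError("fitted Gaussian surface dips below zero; increase sigma or h_p")
    return HeightField(
        z_top=z_top,
        z_bottom=np.zeros_like(z_top),
        spacing=spacing,
        periodic_xy=(periodic, periodic),
    )


# ---------------------------------------------------------------------------
# thickness statistics


def synthesize_bottom_from_statistics(
    z_top: np.ndarray,
    min_h: float,
    max_h: float,
    mode: str = "full_skin",
    bound: ChromatophoreBound | None = None,
    spacing: float = 1.0,
    periodic_xy: tuple[bool, bool] = (False, False),
) -> HeightField:
    """Derive a bottom surface from a top surface using thickness statistics.

    The normalised thickness map sends the observed range of ``z_top``
    affinely onto ``[min_h / max_h, 1]``; ``full_skin`` subtracts
    ``norm * max_h`` from the top surface, while ``chromatophore`` restricts
    the domain to the pigment-cell layer by subtracting only the part of the
    thickness below the fitted lower pigment bound.
    """
    if not (0 < min_h < max_h):
        raise ValueError("need 0 < min_h < max_h")
    z_top = np.asarray(z_top, dtype=float)
    lo, hi = float(z_top.min()), float(z_top.max())
    if hi == lo:
        raise ValueError("constant top surface: normalised thickness undefined")
    ratio = min_h / max_h
    norm = (z_top - lo) / (hi - lo) * (1.0 - ratio) + ratio
    if mode == "full_skin":
        z_bottom = z_top - norm * max_h
    elif mode == "chromatophore":
        if bound is None:
            raise ValueError("chromatophore mode requires a fitted ChromatophoreBound")
        p = np.clip(bound(norm), 0.0, None)
        z_bottom = z_top - (norm - p) * max_h
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(z_top - z_bottom <= 0):
        raise ValueError("statistics produce non-positive thickness; check the bound")
    return HeightField(z_top=z_top, z_bottom=z_bottom, spacing=spacing, periodic_xy=periodic_xy)


def fit_chromatophore_bound(
    samples: np.ndarray | Sequence[tuple[float, float]],
    n_bins: int = 150,
    n_std: float = 3.0,
) -> ChromatophoreBound:
    """Fit the quartic lower bound of pigment height vs skin thickness.

    ``samples`` is an (n, 2) array of (thickness, pigment height) pairs,
    both normalised to [0, 1] by their maxima.  Per thickness bin the mean
    and standard deviation of pigment height are computed; a fourth-order
    polynomial is then least-squares fitted to ``mean - n_std * std`` at the
    occupied bin centres.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of (thickness, height)")
    t, ht = samples[:, 0], samples[:, 1]
    lo, hi = float(t.min()), float(t.max())
    if hi == lo:
        raise ValueError("all samples share one thickness; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    if occupied.sum() < 5:
        raise ValueError(
            f"only {int(occupied.sum())} occupied thickness bins; "
            "a quartic fit needs at least 5"
        )
    sums = np.bincount(which, weights=ht, minlength=n_bins)
    sq = np.bincount(which, weights=ht**2, minlength=n_bins)
    mean = sums[occupied] / counts[occupied]
    var = np.maximum(sq[occupied] / counts[occupied] - mean**2, 0.0)
    lower = mean - n_std * np.sqrt(var)
    # abscissa = per-bin mean thickness (unbiased for non-uniform bin filling)
    tsums = np.bincount(which, weights=t, minlength=n_bins)
    centres = tsums[occupied] / counts[occupied]
    coeffs = np.polyfit(centres, lower, deg=4)
    return ChromatophoreBound(coefficients=coeffs, fit_bins=n_bins, fit_range=(lo, hi))


# ---------------------------------------------------------------------------
# scale labelling


def _merge_periodic_labels(labels: np.ndarray, periodic_xy: tuple[bool, bool]) -> np.ndarray:
    """Union labels of components touching across periodic seams."""
    n = labels.max()
    parent = np.arange(n + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    pairs = []
    if periodic_xy[1]:  # x seam: last column adjacent to first
        pairs.append((labels[:, -1], labels[:, 0]))
    if periodic_xy[0]:  # y seam
        pairs.append((labels[-1, :], labels[0, :]))
    for a, b in pairs:
        both = (a > 0) & (b > 0)
        for i, j in zip(a[both], b[both]):
            union(int(i), int(j))
    roots = np.array([find(i) for i in range(n + 1)])
    # compress to consecutive ids 1..m
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]]


def _periodic_centroids(labels: np.ndarray, spacing: float, periodic_xy: tuple[bool, bool]) -> np.ndarray:
    """Component centroids, wrap-aware via the circular mean where periodic."""
    n = labels.max()
    ny, nx = labels.shape
    cents = np.zeros((n, 2))
    for axis, size, per in ((0, ny, periodic_xy[0]), (1, nx, periodic_xy[1])):
        coords = np.arange(size)
        idx = np.indices(labels.shape)[axis]
        if per:
            ang = 2 * np.pi * idx / size
            cs = ndimage.sum_labels(np.cos(ang), labels, index=np.arange(1, n + 1))
            sn = ndimage.sum_labels(np.sin(ang), labels, index=np.arange(1, n + 1))
            mean_ang = np.arctan2(sn, cs) % (2 * np.pi)
            cents[:, axis] = mean_ang * size / (2 * np.pi)
        else:
            tot = ndimage.sum_labels(idx.astype(float), labels, index=np.arange(1, n + 1))
            cnt = ndimage.sum_labels(np.ones_like(idx, dtype=float), labels, index=np.arange(1, n + 1))
            cents[:, axis] = tot / cnt
    return cents


def extract_scale_map(hf: HeightField, height_threshold: float = 0.5) -> ScaleMap:
    """Label individual scales by thresholding the thickness map.

    The absolute threshold is ``min + height_threshold * (max - min)`` of the
    thickness; connected components of the supra-threshold set are the
    scales.  ``d_avg`` is the mean distance from each scale centroid to its
    nearest neighbour (length units).
    """
    th = hf.thickness
    lo, hi = float(th.min()), float(th.max())
    if hi <= lo:
        raise ValueError("thickness is constant: no scales separable")
    cut = lo + height_threshold * (hi - lo)
    fg = th > cut
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("threshold leaves no scale components")
    if any(hf.periodic_xy):
        labels = _merge_periodic_labels(labels, hf.periodic_xy)
        n = labels.max()
    cents_px = _periodic_centroids(labels, hf.spacing, hf.periodic_xy)
    if n >= 2:
        pts = cents_px * hf.spacing
        if any(hf.periodic_xy):
            ny, nx = labels.shape
            ey, ex = ny * hf.spacing, nx * hf.spacing
            shifts = [
                (sy * ey if hf.periodic_xy[0] else 0.0, sx * ex if hf.periodic_xy[1] else 0.0)
                for sy in (-1, 0, 1)
                for sx in (-1, 0, 1)
            ]
            tiled = np.vstack([pts + np.array(s) for s in set(shifts)])
        else:
            tiled = pts
        tree = cKDTree(tiled)
        dist, _ = tree.query(pts, k=2)
        d_avg = float(dist[:, 1].mean())
    else:
        d_avg = 0.0
    return ScaleMap(labels=labels, centroids=cents_px, d_avg=d_avg, spacing=hf.spacing)


def rescale_surface(hf: HeightField, d_avg_target: float, sm: ScaleMap) -> HeightField:
    """Isotropically rescale a surface so its mean centre distance matches a target."""
    if d_avg_target <= 0:
        raise ValueError("target centre distance must be positive")
    if sm.d_avg <= 0:
        raise ValueError("scale map has no measurable centre distance")
    f = d_avg_target / sm.d_avg
    return HeightField(
        z_top=hf.z_top * f,
        z_bottom=hf.z_bottom * f,
        spacing=hf.spacing * f,
        periodic_xy=hf.periodic_xy,
    )


# ---------------------------------------------------------------------------
# voxelisation


def voxelize(hf: HeightField) -> VoxelDomain:
    """Discretise a height field onto an isotropic voxel grid.

    Voxel (z=k, y=j, x=i) is occupied iff
    ``z_bottom[j,i] <= (k + 1/2) * spacing < z_top[j,i]``.
    """
    eps = hf.spacing
    nz = int(np.ceil(hf.z_top.max() / eps))
    kc = (np.arange(nz) + 0.5) * eps
    mask = (kc[:, None, None] >= hf.z_bottom[None, :, :]) & (kc[:, None, None] < hf.z_top[None, :, :])
    cols = mask.sum(axis=0)
    if np.any(cols < 1):
        raise ValueError(
            "thinnest column resolves to zero voxels at this spacing; "
            "refine the grid or thicken the domain"
        )
    return VoxelDomain(mask=mask, spacing=eps, periodic_xy=hf.periodic_xy)
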