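"""Geometry construction: lattices, thickness statistics, scale maps, voxelisation."""

import numpy as np
import pytest

from scalerd.geometry import (
    ChromatophoreBound,
    HeightField,
    PrismLattice,
    build_gaussian_lattice,
    build_prism_lattice,
    extract_scale_map,
    fit_chromatophore_bound,
    rescale_surface,
    synthesize_bottom_from_statistics,
    voxelize,
)
from scalerd.fixtures import make_pigment_cloud


class TestPrismLattice:
    def test_degenerate_flat_slab(self):
        hf = build_prism_lattice(PrismLattice(3, 3, 20.0, 10.0, 10.0, 2.0, 1.0, periodic=False))
        assert hf.z_top.max() - hf.z_top.min() < 1e-9
        assert np.allclose(hf.z_top, 10.0)

    def test_two_height_levels(self, prism_hf):
        levels = np.unique(prism_hf.z_top)
        assert set(levels) == {3.0, 10.0}
        assert np.all(prism_hf.z_bottom == 0.0)

    def test_scale_count_matches_lattice(self, prism_hf):
        sm = extract_scale_map(prism_hf, 0.5)
        assert sm.n_scales == 9
        assert sm.d_avg == pytest.approx(20.0, rel=0.05)

    def test_coarse_spacing_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            build_prism_lattice(PrismLattice(3, 4, 20.0, 10.0, 3.0, T=1.0, spacing=2.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PrismLattice(3, 3, 20.0, 10.0, 12.0, 2.0, 1.0)  # h_p > h
        with pytest.raises(ValueError):
            PrismLattice(3, 3, 20.0, 10.0, 3.0, 25.0, 1.0)  # T >= pitch

    def test_odd_rows_cannot_tile_torus(self):
        with pytest.raises(ValueError, match="even number of rows"):
            build_prism_lattice(PrismLattice(3, 3, 20.0, 10.0, 3.0, 2.0, 1.0, periodic=True))


class TestGaussianLattice:
    def test_centre_and_border_values(self):
        # single bump: the surface equals h at the centre node and h_p at the
        # midpoint between periodic neighbour centres
        h, h_p, sigma, pitch = 16.0, 5.0, 8.0, 30.0
        hf = build_gaussian_lattice(1, 2, sigma, h, h_p, spacing=1.0, scale_pitch=pitch)
        assert hf.z_top[0, 0] == pytest.approx(h, abs=1e-12)
        assert hf.z_top[0, 15] == pytest.approx(h_p, abs=1e-9)

    def test_zero_contrast_limit_is_flat(self):
        hf = build_gaussian_lattice(2, 2, 6.0, 10.0, 10.0, 1.0, scale_pitch=20.0)
        assert np.allclose(hf.z_top, 10.0, atol=1e-9)

    def test_component_count(self):
        hf = build_gaussian_lattice(3, 3, 6.0, 10.0, 3.0, 1.0, scale_pitch=20.0, periodic=False)
        sm = extract_scale_map(hf, 0.5)
        assert sm.n_scales == 9

    def test_oversized_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            build_gaussian_lattice(2, 2, 1e6, 10.0, 3.0, 1.0, scale_pitch=20.0)


@pytest.fixture()
def z_top():
    rng = np.random.default_rng(7)
    base = rng.uniform(5.0, 20.0, size=(24, 24))
    from scipy import ndimage

    return ndimage.gaussian_filter(base, 3.0)


class TestBottomSynthesis:

    def test_endpoints_of_normalisation(self, z_top):
        min_h, max_h = 2.0, 8.0
        hf = synthesize_bottom_from_statistics(z_top, min_h, max_h, "full_skin")
        j, i = np.unravel_index(z_top.argmax(), z_top.shape)
        assert hf.thickness[j, i] == pytest.approx(max_h)
        j, i = np.unravel_index(z_top.argmin(), z_top.shape)
        assert hf.thickness[j, i] == pytest.approx(min_h / max_h * max_h)

    def test_thickness_maximal_where_top_is(self, z_top):
        hf = synthesize_bottom_from_statistics(z_top, 2.0, 8.0, "full_skin")
        assert hf.thickness.argmax() == z_top.argmax()
        assert np.all(hf.thickness <= 8.0 + 1e-12)

    def test_zero_bound_reduces_to_full_skin(self, z_top):
        zero = ChromatophoreBound(coefficients=np.zeros(5), fit_bins=150)
        full = synthesize_bottom_from_statistics(z_top, 2.0, 8.0, "full_skin")
        chrom = synthesize_bottom_from_statistics(z_top, 2.0, 8.0, "chromatophore", bound=zero)
        np.testing.assert_allclose(chrom.z_bottom, full.z_bottom)

    def test_constant_top_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            synthesize_bottom_from_statistics(np.full((8, 8), 5.0), 2.0, 8.0)


class TestChromatophoreBound:
    def test_planted_quartic_recovery(self):
        q = np.array([0.3, -0.2, 0.1, 0.4, 0.1])
        sd = 0.03
        cloud = make_pigment_cloud(100_000, q, sd, seed=42)
        bound = fit_chromatophore_bound(cloud, n_bins=150, n_std=3.0)
        t = np.linspace(0.25, 0.95, 200)
        expected = np.polyval(q, t) - 3.0 * sd
        assert np.max(np.abs(bound(t) - expected)) < 0.02

    def test_noiseless_line_recovered_exactly(self):
        # one discrete thickness value per bin, so the per-bin std is zero
        # and the fitted bound must coincide with the line itself
        t = np.repeat(np.linspace(0.103, 0.997, 60), 50)
        samples = np.column_stack([t, 0.5 * t])
        bound = fit_chromatophore_bound(samples, n_bins=150)
        assert np.max(np.abs(bound(t) - 0.5 * t)) < 1e-6

    def test_too_few_bins_rejected(self):
        t = np.repeat([0.2, 0.4, 0.6, 0.8], 100)
        samples = np.column_stack([t, t])
        with pytest.raises(ValueError, match="occupied"):
            fit_chromatophore_bound(samples, n_bins=150)


class TestScaleMapAndRescale:
    def test_flat_slab_rejected(self):
        hf = HeightField(np.full((16, 16), 5.0), np.zeros((16, 16)), 1.0)
        with pytest.raises(ValueError):
            extract_scale_map(hf)

    def test_rescale_identity(self, prism_hf, prism_sm):
        out = rescale_surface(prism_hf, prism_sm.d_avg, prism_sm)
        np.testing.assert_allclose(out.z_top, prism_hf.z_top)
        assert out.spacing == pytest.approx(prism_hf.spacing)

    def test_rescale_doubles_thickness(self, prism_hf, prism_sm):
        out = rescale_surface(prism_hf, 2 * prism_sm.d_avg, prism_sm)
        np.testing.assert_allclose(out.thickness, 2 * prism_hf.thickness)

    def test_rescale_round_trip(self, prism_hf, prism_sm):
        out = rescale_surface(prism_hf, 10.0, prism_sm)
        sm2 = extract_scale_map(out, 0.5)
        assert sm2.d_avg == pytest.approx(10.0, abs=out.spacing)

    def test_nonpositive_target_rejected(self, prism_hf, prism_sm):
        with pytest.raises(ValueError):
            rescale_surface(prism_hf, -1.0, prism_sm)


class TestVoxelize:
    def test_flat_slab_column_height(self):
        hf = HeightField(np.full((8, 8), 6.0), np.zeros((8, 8)), 1.0)
        dom = voxelize(hf)
        assert np.all(dom.column_heights() == 6)

    def test_prism_columns(self, prism_hf):
        dom = voxelize(prism_hf)
        heights = np.unique(dom.column_heights())
        assert set(heights) == {3, 10}

    def test_columns_contiguous_in_z(self, gaussian_hf):
        dom = voxelize(gaussian_hf)
        m = dom.mask
        runs = np.abs(np.diff(m.astype(int), axis=0)).sum(axis=0)
        # a contiguous column changes occupancy at most twice along z
        assert np.all(runs <= 2)

    def test_volume_matches_analytic(self):
        spec = PrismLattice(3, 4, 17.0, 8.0, 2.4, 2.0, 1.0, periodic=True)
        hf = build_prism_lattice(spec)
        dom = voxelize(hf)
        cell_area = spec.scale_pitch**2 * np.sqrt(3) / 2
        plateau_frac = (spec.scale_pitch - spec.T) ** 2 / spec.scale_pitch**2
        vol = 12 * cell_area * (plateau_frac * spec.h + (1 - plateau_frac) * spec.h_p)
        voxel_vol = dom.n_occupied * spec.spacing**3
        assert voxel_vol == pytest.approx(vol, rel=0.02)

    def test_unresolvable_thickness_rejected(self):
        hf = HeightField(np.full((4, 4), 0.4), np.zeros((4, 4)), 1.0)
        with pytest.raises(ValueError, match="zero voxels"):
            voxelize(hf)
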