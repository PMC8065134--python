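"""Pattern morphometrics: binarisation, borders, length scale, curvature, homogeneity."""

import numpy as np
import pytest
from scipy import ndimage

from scalerd.fixtures import make_stripe_image
from scalerd.geometry import ScaleMap
from scalerd.metrics import (
    binarize,
    border_curvature,
    border_pixels,
    classify_scale_colours,
    extract_borders,
    homogeneity_error,
    pattern_length_scale,
    _menger_curvature_points,
)


def _disc(shape, centre, radius):
    yy, xx = np.indices(shape)
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2


class TestBinarize:
    def test_bimodal_kmeans_equals_fixed_threshold(self, rng):
        img = rng.choice([25.0, 230.0], size=(40, 40))
        np.testing.assert_array_equal(binarize(img, "kmeans"), binarize(img, "fixed"))

    def test_fixed_mode_reproduces_binary_g(self, rng):
        g = rng.choice([0.0, 1.0], size=(30, 30))
        assert np.array_equal(binarize(g, "fixed"), g.astype(bool))

    def test_zero_blur_splits_raw_intensities(self, rng):
        # without smoothing, k-means output is a clean cut of the raw values
        img = rng.uniform(0, 255, (30, 30))
        out = binarize(img, "kmeans", blur=0.0)
        assert img[out].min() > img[~out].max()
        np.testing.assert_array_equal(out, binarize(img, "kmeans", blur=0.0))

    def test_constant_image_rejected_in_kmeans(self):
        with pytest.raises(ValueError, match="constant"):
            binarize(np.full((10, 10), 0.3), "kmeans")


class TestBorders:
    def test_filled_disc_single_contour(self):
        binary = _disc((50, 50), (25, 25), 12)
        bs = extract_borders(binary)
        assert len(bs.contours) == 1

    def test_two_discs_two_contours(self):
        binary = _disc((60, 60), (18, 18), 8) | _disc((60, 60), (42, 42), 8)
        bs = extract_borders(binary)
        assert len(bs.contours) == 2

    def test_checkerboard_every_pixel_is_border(self):
        yy, xx = np.indices((16, 16))
        binary = (yy + xx) % 2 == 0
        bp = border_pixels(binary)
        np.testing.assert_array_equal(bp, binary)

    def test_border_pixels_are_foreground_adjacent_to_background(self, rng):
        binary = ndimage.binary_closing(rng.random((40, 40)) > 0.4)
        bp = border_pixels(binary)
        assert np.all(binary[bp])
        # every border pixel touches background (8-adjacency, frame counts)
        padded = np.pad(binary, 1, constant_values=False)
        for j, i in zip(*np.where(bp)):
            nb = padded[j : j + 3, i : i + 3]
            assert not nb.all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            extract_borders(np.ones((10, 10), bool))


class TestPatternLengthScale:
    def test_matches_brute_force_on_stripes(self):
        img = make_stripe_image(width=12, period=24, shape=(40, 72))
        binary = binarize(img, "fixed")
        r_avg = 3.0
        res = pattern_length_scale(binary, r_avg)
        # brute force: per foreground pixel, min distance to any border pixel
        bp = np.column_stack(np.where(border_pixels(binary)))
        fg = np.column_stack(np.where(binary))
        d = np.sqrt(((fg[:, None, :] - bp[None, :, :]) ** 2).sum(-1)).min(1) / r_avg
        expected = d[d > 1.0].mean()
        assert res.mean == pytest.approx(expected, abs=1e-12)

    def test_rotation_and_mirror_invariance(self):
        img = make_stripe_image(width=10, period=20, shape=(60, 60)).astype(bool)
        base = pattern_length_scale(img, 2.5).mean
        assert pattern_length_scale(np.rot90(img), 2.5).mean == pytest.approx(base, abs=1e-12)
        assert pattern_length_scale(img[:, ::-1], 2.5).mean == pytest.approx(base, abs=1e-12)

    def test_doubling_r_avg_halves_distances(self):
        img = make_stripe_image(width=12, period=24, shape=(40, 48)).astype(bool)
        a = pattern_length_scale(img, 2.0)
        b = pattern_length_scale(img, 4.0)
        np.testing.assert_allclose(b.distance_map[img], a.distance_map[img] / 2.0)

    def test_thin_pattern_flagged(self):
        img = make_stripe_image(width=6, period=24, shape=(30, 48)).astype(bool)
        res = pattern_length_scale(img, r_avg=6.0)
        assert res.flagged and res.mean == 1.0

    def test_deterministic_bitwise(self):
        img = make_stripe_image(width=12, period=24, shape=(40, 48)).astype(bool)
        assert pattern_length_scale(img, 3.0).mean == pattern_length_scale(img, 3.0).mean


class TestBorderCurvature:
    def test_explicit_three_point_circumradius(self):
        # (0,0), (1,1), (2,0) lie on the unit circle centred at (1,0)
        assert _menger_curvature_points((0, 0), (1, 1), (2, 0)) == pytest.approx(1.0)

    def test_collinear_points_zero_curvature(self):
        assert _menger_curvature_points((0, 0), (1, 1), (2, 2)) == 0.0

    def test_digitised_circle_curvature(self):
        r_avg, R = 6.0, 120.0
        binary = _disc((260, 260), (130, 130), R)
        bs = extract_borders(binary)
        kappa = border_curvature(bs, r_avg)
        assert kappa == pytest.approx(r_avg / R, rel=0.10)

    def test_short_contours_rejected(self):
        binary = _disc((30, 30), (15, 15), 3)
        bs = extract_borders(binary)
        with pytest.raises(ValueError, match="too short"):
            border_curvature(bs, r_avg=20.0)


def _grid_scale_map(n_side=4, cell=8):
    labels = np.zeros((n_side * cell, n_side * cell), int)
    k = 1
    cents = []
    for j in range(n_side):
        for i in range(n_side):
            labels[j * cell : (j + 1) * cell, i * cell : (i + 1) * cell] = k
            cents.append(((j + 0.5) * cell, (i + 0.5) * cell))
            k += 1
    return ScaleMap(labels=labels, centroids=np.array(cents), d_avg=float(cell), spacing=1.0)


class TestHomogeneity:
    def test_monochromatic_scales_score_zero(self, rng):
        sm = _grid_scale_map()
        colours = rng.choice([0.0, 1.0], size=sm.n_scales)
        g = colours[sm.labels - 1]
        errs, mean = homogeneity_error(g, sm)
        assert mean == 0.0 and np.all(errs == 0.0)

    def test_uniform_grey_is_maximal_error(self):
        sm = _grid_scale_map()
        errs, mean = homogeneity_error(np.full(sm.labels.shape, 0.5), sm)
        assert mean == 0.5 and np.all(errs == 0.5)

    def test_single_mixed_scale_contributes_half_over_n(self):
        sm = _grid_scale_map()
        g = np.ones(sm.labels.shape)
        half = sm.labels == 1
        idx = np.where(half)
        g[idx[0][: idx[0].size // 2], idx[1][: idx[1].size // 2]] = 0.0
        errs, mean = homogeneity_error(g, sm)
        assert errs[0] == pytest.approx(0.5)
        assert mean == pytest.approx(0.5 / sm.n_scales)

    def test_error_bounds(self, rng):
        sm = _grid_scale_map()
        _, mean = homogeneity_error(rng.random(sm.labels.shape), sm)
        assert 0.0 <= mean <= 0.5

    def test_classification_and_tie_rule(self, rng):
        sm = _grid_scale_map()
        g = np.full(sm.labels.shape, 0.5)
        g[sm.labels == 3] = 1.0
        cols = classify_scale_colours(g, sm)
        assert cols[2]  # the uniformly green scale
        assert not cols[0]  # exact 0.5 ties are black

    def test_classification_matches_brute_force_means(self, rng):
        sm = _grid_scale_map()
        g = rng.random(sm.labels.shape)
        cols = classify_scale_colours(g, sm)
        for p in range(1, sm.n_scales + 1):
            assert cols[p - 1] == (g[sm.labels == p].mean() > 0.5)
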