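"""Level-set segmentation: building blocks, energy oracles, evolution."""

import numpy as np
import pytest

from pulmostage.acm import (
    Contour,
    LevelSetParams,
    SnakeParams,
    energy,
    evolve,
    extract_contour,
    init_level_set_squares,
    regularized_dirac,
    regularized_heaviside,
    region_intensity_inside,
    region_intensity_outside,
    sample_contour,
    segment_volume,
    signed_distance,
    snake_energy,
)
from pulmostage.phantom import PhantomSpec, generate_phantom
from conftest import dice


def disc_mask(shape, center, radius):
    r, c = np.indices(shape)
    return (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius ** 2


class TestSignedDistance:
    def test_disc_center_depth(self):
        mask = disc_mask((41, 41), (20, 20), 10)
        phi = signed_distance(mask).phi
        assert phi[20, 20] == pytest.approx(-10, abs=1.0)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            signed_distance(np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            signed_distance(np.zeros((8, 8), dtype=bool))

    def test_matches_brute_force_boundary_distance(self):
        rng = np.random.default_rng(3)
        mask = disc_mask((24, 24), (12, 10), 6) | disc_mask((24, 24), (8, 16), 4)
        phi = signed_distance(mask).phi
        # brute force: distance to the nearest pixel of the opposite phase
        pts_in = np.argwhere(mask)
        pts_out = np.argwhere(~mask)
        brute = np.empty(mask.shape)
        for r in range(24):
            for c in range(24):
                other = pts_out if mask[r, c] else pts_in
                d = np.sqrt(((other - (r, c)) ** 2).sum(axis=1)).min()
                brute[r, c] = -d if mask[r, c] else d
        assert np.abs(phi - brute).max() <= np.sqrt(2.0)

    def test_unit_gradient_away_from_zero_set(self):
        mask = disc_mask((41, 41), (20, 20), 10)
        phi = signed_distance(mask).phi
        gr, gc = np.gradient(phi)
        mag = np.sqrt(gr ** 2 + gc ** 2)
        # away from the zero set and from the skeleton (where the distance
        # field is genuinely non-smooth)
        band = (np.abs(phi) > 2) & (np.abs(phi) < 6)
        assert np.quantile(np.abs(mag[band] - 1), 0.95) < 0.1


class TestHeavisideDirac:
    def test_saturation_and_midpoint(self):
        assert regularized_heaviside(np.array([1e9]), 1.5)[0] == pytest.approx(1.0, abs=1e-6)
        assert regularized_heaviside(np.array([-1e9]), 1.5)[0] == pytest.approx(0.0, abs=1e-6)
        assert regularized_heaviside(np.array([0.0]), 1.5)[0] == 0.5

    def test_monotone(self):
        t = np.linspace(-30, 30, 2001)
        h = regularized_heaviside(t, 1.5)
        assert np.all(np.diff(h) > 0)

    def test_dirac_is_derivative(self):
        t = np.linspace(-10, 10, 200001)
        h = regularized_heaviside(t, 1.5)
        d_num = np.gradient(h, t)
        d = regularized_dirac(t, 1.5)
        assert np.abs(d - d_num)[1:-1].max() < 1e-6

    def test_dirac_symmetric_unit_mass(self):
        t = np.linspace(-4000, 4000, 800001)
        d = regularized_dirac(t, 1.5)
        assert np.allclose(d, d[::-1])
        assert np.trapezoid(d, t) == pytest.approx(1.0, abs=1e-3)


def brute_force_intensities(image, phi, eps):
    """Direct double-loop evaluation of the weighted-mean formulas."""
    num1 = den1 = num2 = den2 = 0.0
    h, w = image.shape
    for r in range(h):
        for c in range(w):
            ja = 0.5 * (1 + (2 / np.pi) * np.arctan(-phi[r, c] / eps))
            num1 += image[r, c] * ja
            den1 += ja
            num2 += image[r, c] * (1 - ja)
            den2 += 1 - ja
    return num1 / den1, num2 / den2


class TestRegionIntensities:
    def test_sharp_limit_perfect_partition(self):
        image = np.zeros((20, 20))
        image[:, :10] = 100.0
        phi = np.where(image == 100.0, -5.0, 5.0).astype(float)
        params = LevelSetParams(epsilon=1e-6)
        assert region_intensity_inside(image, phi, params) == pytest.approx(100.0, abs=1e-4)
        assert region_intensity_outside(image, phi, params) == pytest.approx(0.0, abs=1e-4)

    def test_constant_image(self):
        image = np.full((16, 16), 7.0)
        phi = np.linspace(-3, 3, 256).reshape(16, 16)
        params = LevelSetParams()
        assert region_intensity_inside(image, phi, params) == pytest.approx(7.0)
        assert region_intensity_outside(image, phi, params) == pytest.approx(7.0)

    def test_matches_brute_force_sums(self):
        rng = np.random.default_rng(11)
        image = rng.uniform(0, 100, (16, 16))
        phi = rng.normal(0, 3, (16, 16))
        params = LevelSetParams(epsilon=1.5)
        i1 = region_intensity_inside(image, phi, params)
        i2 = region_intensity_outside(image, phi, params)
        b1, b2 = brute_force_intensities(image, phi, params.epsilon)
        assert i1 == pytest.approx(b1, abs=1e-10)
        assert i2 == pytest.approx(b2, abs=1e-10)

    def test_one_sided_contour_falls_back_with_warning(self):
        image = np.random.default_rng(0).uniform(0, 1, (12, 12))
        phi = np.full((12, 12), 1e12)  # so far outside the Heaviside saturates
        params = LevelSetParams(epsilon=1.0)
        with pytest.warns(RuntimeWarning, match="one side"):
            i1 = region_intensity_inside(image, phi, params)
        assert i1 == pytest.approx(image.mean())


class TestEnergy:
    def test_constant_image_zero_energy(self):
        image = np.full((16, 16), 3.0)
        phi = np.linspace(-2, 2, 256).reshape(16, 16)
        e = energy(image, phi, LevelSetParams(gamma=0, beta_len=0))
        assert e.total == pytest.approx(0.0, abs=1e-20)

    def test_area_term_counts_enclosed_voxels(self):
        mask = disc_mask((32, 32), (16, 16), 7)
        phi = signed_distance(mask).phi
        params = LevelSetParams(gamma=1.0, beta_len=0.0, epsilon=1e-4)
        image = np.where(mask, 50.0, 0.0)
        e = energy(image, phi, params)
        assert e.area == pytest.approx(mask.sum(), rel=0.05)

    def test_matches_term_by_term_summation(self):
        rng = np.random.default_rng(5)
        image = rng.uniform(0, 10, (16, 16))
        phi = rng.normal(0, 2, (16, 16))
        params = LevelSetParams(gamma=0.7, beta_len=0.3, epsilon=1.2)
        e = energy(image, phi, params)
        i1, i2 = brute_force_intensities(image, phi, params.epsilon)
        ja = 0.5 * (1 + (2 / np.pi) * np.arctan(-phi / params.epsilon))
        data_in = ((image - i1) ** 2 * ja).sum()
        data_out = ((image - i2) ** 2 * (1 - ja)).sum()
        area = params.gamma * ja.sum()
        gr, gc = np.gradient(phi)
        delta = params.epsilon / (np.pi * (params.epsilon ** 2 + phi ** 2))
        length = params.beta_len * (delta * np.sqrt(gr ** 2 + gc ** 2)).sum()
        assert e.data_inside == pytest.approx(data_in, abs=1e-10)
        assert e.data_outside == pytest.approx(data_out, abs=1e-10)
        assert e.area == pytest.approx(area, abs=1e-10)
        assert e.length == pytest.approx(length, abs=1e-10)
        assert e.total == pytest.approx(data_in + data_out + area + length, abs=1e-8)

    def test_terms_nonnegative(self):
        rng = np.random.default_rng(8)
        image = rng.uniform(0, 5, (12, 12))
        phi = rng.normal(0, 1, (12, 12))
        e = energy(image, phi, LevelSetParams(gamma=0.5, beta_len=0.5))
        assert min(e.data_inside, e.data_outside, e.area, e.length) >= 0


class TestInitSquares:
    def test_default_55_seed_components(self):
        from scipy import ndimage

        field = init_level_set_squares((256, 256), 55)
        _, n = ndimage.label(field.mask)
        assert n == 55

    def test_single_centered_square_zero_crossing(self):
        field = init_level_set_squares((33, 33), 1, square_size=10)
        assert field.phi[16, 16] < 0
        assert field.phi[0, 0] > 0 and field.phi[-1, -1] > 0

    def test_sign_convention_at_centers_and_corners(self):
        field = init_level_set_squares((64, 64), 9)
        assert field.phi[0, 0] > 0
        assert (field.phi < 0).sum() > 0

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            init_level_set_squares((8, 8), 1000)


class TestEvolve:
    def test_zero_noise_disc_recovered(self, disc_phantom_2d):
        vol, truth = disc_phantom_2d
        result = segment_volume(vol)
        assert dice(result.mask, truth.mask) >= 0.98

    def test_constant_image_collapses_under_area_penalty(self):
        image = np.full((32, 32), 5.0)
        phi0 = init_level_set_squares((32, 32), 9).phi
        params = LevelSetParams(gamma=0.5, max_iter=300)
        result = evolve(image, phi0, params)
        assert result.mask.sum() == 0

    def test_agrees_with_otsu_on_bimodal_phantom(self):
        spec = PhantomSpec(nodule_diameter_mm=16, contrast=40, noise_sigma=0,
                           slab_shape=(64, 64), voxel_spacing_mm=(1.0, 1.0))
        vol, _ = generate_phantom(spec, seed=0)
        from skimage.filters import threshold_otsu

        otsu_mask = vol.intensities > threshold_otsu(vol.intensities)
        result = segment_volume(vol)
        assert dice(result.mask, otsu_mask) >= 0.98

    def test_energy_trace_monotone(self):
        spec = PhantomSpec(nodule_diameter_mm=14, contrast=40, noise_sigma=5,
                           slab_shape=(64, 64), voxel_spacing_mm=(1.0, 1.0))
        vol, _ = generate_phantom(spec, seed=2)
        result = segment_volume(vol)
        tr = result.energy_trace
        assert np.all(np.diff(tr) <= 1e-6 * np.abs(tr[:-1]) + 1e-12)

    def test_translation_equivariance(self):
        spec = PhantomSpec(nodule_diameter_mm=12, contrast=40, noise_sigma=0,
                           slab_shape=(64, 64), voxel_spacing_mm=(1.0, 1.0),
                           nodule_center=(28.0, 30.0))
        vol, _ = generate_phantom(spec, seed=0)
        shifted = PhantomSpec(nodule_diameter_mm=12, contrast=40, noise_sigma=0,
                              slab_shape=(64, 64), voxel_spacing_mm=(1.0, 1.0),
                              nodule_center=(33.0, 35.0))
        vol2, _ = generate_phantom(shifted, seed=0)
        m1 = segment_volume(vol).mask
        m2 = segment_volume(vol2).mask
        assert np.array_equal(np.roll(np.roll(m1, 5, axis=0), 5, axis=1), m2)

    def test_chan_vese_limit_matches_direct_implementation(self):
        """With a global kernel the update equals the classical two-phase
        piecewise-constant evolution, iteration by iteration."""
        rng = np.random.default_rng(4)
        image = rng.uniform(0, 1, (24, 24))
        image[8:16, 8:16] += 1.0
        mask0 = disc_mask((24, 24), (12, 12), 5)
        phi0 = signed_distance(mask0).phi
        eps, dt, gamma, beta = 1.5, 0.8, 0.1, 0.2
        n_iter = 12

        # direct classical implementation, inside-positive convention
        psi = -phi0.copy()
        psi_trace = []
        for _ in range(n_iter):
            h = 0.5 * (1 + (2 / np.pi) * np.arctan(psi / eps))
            c1 = (image * h).sum() / h.sum()
            c2 = (image * (1 - h)).sum() / (1 - h).sum()
            delta = eps / (np.pi * (eps ** 2 + psi ** 2))
            gr, gc = np.gradient(psi, axis=(0, 1))
            mag = np.maximum(np.sqrt(gr ** 2 + gc ** 2), 1e-8)
            kappa = np.gradient(gr / mag, axis=0) + np.gradient(gc / mag, axis=1)
            psi = psi + dt * delta * (beta * kappa - gamma
                                      - (image - c1) ** 2 + (image - c2) ** 2)
            psi_trace.append(psi.copy())

        params = LevelSetParams(gamma=gamma, beta_len=beta, epsilon=eps, dt=dt,
                                max_iter=1, line_search=False, reinit_every=0,
                                stable_iters=0)
        phi = phi0.copy()
        for k in range(n_iter):
            result = evolve(image, phi, params)
            phi = result.phi
            assert np.abs(phi + psi_trace[k]).max() <= 1e-8


class TestContours:
    def test_circle_radius_recovered(self):
        mask = disc_mask((64, 64), (32, 32), 12)
        phi = signed_distance(mask).phi
        contours = extract_contour(phi)
        assert len(contours) == 1
        pts = contours[0].points
        radii = np.sqrt(((pts - [32, 32]) ** 2).sum(axis=1))
        assert np.abs(radii - 12).max() <= 0.75

    def test_all_positive_field_has_no_contour(self):
        assert extract_contour(np.ones((16, 16))) == []

    def test_two_discs_two_contours(self):
        mask = disc_mask((64, 64), (18, 18), 8) | disc_mask((64, 64), (46, 46), 8)
        contours = extract_contour(signed_distance(mask).phi)
        assert len(contours) == 2
        assert all(c.closed for c in contours)


class TestSampleContour:
    def square(self):
        pts = [(0, 0), (0, 10), (10, 10), (10, 0)]
        dense = []
        for i in range(4):
            a, b = np.array(pts[i]), np.array(pts[(i + 1) % 4])
            for t in np.linspace(0, 1, 50, endpoint=False):
                dense.append(a + t * (b - a))
        return Contour(np.array(dense), closed=True)

    def test_square_resampled_to_corners(self):
        resampled = sample_contour(self.square(), 4)
        assert np.allclose(sorted(map(tuple, resampled.points)),
                           [(0, 0), (0, 10), (10, 0), (10, 10)])

    def test_identity_on_uniform_contour(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([10 + 5 * np.cos(theta), 10 + 5 * np.sin(theta)])
        c = Contour(pts, closed=True)
        r = sample_contour(c, 40)
        assert np.abs(r.points - pts).max() < 1e-9

    def test_arc_length_preserved(self):
        rng = np.random.default_rng(2)
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        radius = 10 + rng.normal(0, 0.3, 200).cumsum() * 0.01
        pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        c = Contour(pts, closed=True)
        r = sample_contour(c, 150)
        assert abs(r.arc_length() - c.arc_length()) / c.arc_length() < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sample_contour(self.square(), 2)


class TestSnakeEnergy:
    def test_circle_tension_closed_form(self):
        n = 400
        r = 7.0
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        c = Contour(pts, closed=True)
        e = snake_energy(c, np.zeros((32, 32)), SnakeParams(alpha=1, beta_curv=0, mu=0))
        # |C'(s)|^2 = (2 pi r)^2 for the unit-interval parametrization
        assert e["tension"] == pytest.approx((2 * np.pi * r) ** 2, rel=1e-3)

    def test_straight_segment_zero_rigidity(self):
        pts = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 5, 20)])
        c = Contour(pts, closed=False)
        e = snake_energy(c, np.zeros((16, 16)), SnakeParams())
        assert e["rigidity"] == pytest.approx(0.0, abs=1e-9)

    def test_edge_lowers_energy(self):
        image = np.zeros((40, 40))
        image[:, 20:] = 100.0  # vertical edge at col 20
        on_edge = Contour(np.column_stack([np.linspace(5, 35, 30),
                                           np.full(30, 19.5)]), closed=False)
        off_edge = Contour(np.column_stack([np.linspace(5, 35, 30),
                                            np.full(30, 5.0)]), closed=False)
        params = SnakeParams(alpha=0, beta_curv=0, mu=1.0)
        assert (snake_energy(on_edge, image, params)["total"]
                < snake_energy(off_edge, image, params)["total"])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            snake_energy(Contour(np.array([[0, 0], [1, 1]]), closed=False),
                         np.zeros((8, 8)))
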