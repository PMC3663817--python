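"""Peak detection and greedy-snake segmentation."""

import numpy as np
import pytest

from bollmark.detect import (
    Snake,
    evolve_snake_greedy,
    find_local_maxima,
    init_snake,
    snake_energy,
    snake_to_region,
)

from conftest import disk_image, full_mask_ratio, normalized_gradient


def gaussian_spot(shape, center, amp, sigma):
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return amp * np.exp(-d2 / (2 * sigma**2))


class TestFindLocalMaxima:
    def test_flat_image_has_no_peaks(self):
        ratio = full_mask_ratio(np.full((64, 64), 0.8))
        assert find_local_maxima(ratio) == []

    def test_two_separated_spots_found_at_centers(self):
        base = np.full((90, 90), 0.5)
        img = base + gaussian_spot((90, 90), (40, 30), 0.6, 3.0)
        img = img + gaussian_spot((90, 90), (40, 55), 0.6, 3.0)
        peaks = find_local_maxima(full_mask_ratio(img))
        assert len(peaks) == 2
        found = sorted((p.row, p.col) for p in peaks)
        assert abs(found[0][0] - 40) <= 1 and abs(found[0][1] - 30) <= 1
        assert abs(found[1][0] - 40) <= 1 and abs(found[1][1] - 55) <= 1

    def test_close_spots_merged_by_distance_rule(self):
        base = np.full((90, 90), 0.5)
        img = base + gaussian_spot((90, 90), (40, 30), 0.6, 3.0)
        img = img + gaussian_spot((90, 90), (40, 40), 0.5, 3.0)
        peaks = find_local_maxima(full_mask_ratio(img))
        assert len(peaks) == 1
        # higher-valued peak wins
        assert abs(peaks[0].col - 30) <= 2

    def test_peaks_sorted_and_spaced(self, rng):
        img = np.full((120, 120), 0.5)
        centers = [(20, 20), (20, 80), (80, 20), (80, 80), (50, 50)]
        for i, c in enumerate(centers):
            img += gaussian_spot((120, 120), c, 0.4 + 0.1 * i, 3.0)
        peaks = find_local_maxima(full_mask_ratio(img), min_distance_px=15)
        vals = [p.value for p in peaks]
        assert vals == sorted(vals, reverse=True)
        for i, a in enumerate(peaks):
            for b in peaks[i + 1 :]:
                assert np.hypot(a.row - b.row, a.col - b.col) >= 15


class TestSnakeGeometry:
    def test_init_circle_radii(self):
        s = init_snake((50, 50), 10)
        d = np.linalg.norm(s.vertices - np.array([50.0, 50.0]), axis=1)
        assert np.allclose(d, 10, atol=1e-9)
        assert s.n_vertices == 32 and not s.converged

    def test_four_vertex_snake_is_square(self):
        s = init_snake((0, 0), 5.0, n_vertices=4)
        sides = np.linalg.norm(
            np.roll(s.vertices, -1, axis=0) - s.vertices, axis=1
        )
        assert np.allclose(sides, 5.0 * np.sqrt(2))

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            init_snake((200, 200), 10, image_shape=(100, 100))

    def test_fresh_snake_energy_closed_form(self):
        # regular 32-gon of radius r on a zero-gradient image:
        # stretching = 32 * 2r sin(pi/32), bending = 32 * 4r sin^2(pi/32)
        r, n = 12.0, 32
        s = init_snake((60, 60), r)
        alpha, beta = 1.0, 0.5
        e = snake_energy(s, np.zeros((120, 120)), alpha, beta, 2.0)
        stretch = n * 2 * r * np.sin(np.pi / n)
        bend = n * 4 * r * np.sin(np.pi / n) ** 2
        assert e == pytest.approx(alpha * stretch + beta * bend, rel=1e-9)

    def test_internal_energy_scales_with_radius(self):
        # with gamma=0 both internal terms scale linearly in r, so any
        # uniform shrink strictly lowers the energy
        big = init_snake((60, 60), 15)
        small = init_snake((60, 60), 10)
        z = np.zeros((120, 120))
        assert snake_energy(small, z, 1, 0.5, 0) < snake_energy(big, z, 1, 0.5, 0)

    def test_on_boundary_energy_lower_than_offset(self):
        img = disk_image(10)
        g = normalized_gradient(img)
        on = init_snake((64, 64), 10)
        off = init_snake((64, 64), 15)
        gamma = 5.0
        assert snake_energy(on, g, 1, 0.5, gamma) < snake_energy(off, g, 1, 0.5, gamma)


class TestGreedyEvolution:
    def test_disk_boundary_recovered(self):
        img = disk_image(10)
        g = normalized_gradient(img)
        out = evolve_snake_greedy(init_snake((64, 64), 18), g)
        d = np.linalg.norm(out.vertices - np.array([64.0, 64.0]), axis=1)
        assert np.all(np.abs(d - 10) <= 1.0)
        assert out.converged

    def test_energy_never_increases(self):
        img = disk_image(10)
        g = normalized_gradient(img)
        s0 = init_snake((64, 64), 18)
        e0 = snake_energy(s0, g)
        out = evolve_snake_greedy(s0, g)
        assert out.energy <= e0 + 1e-9

    def test_snake_on_ridge_is_a_fixed_point(self):
        img = disk_image(10)
        g = normalized_gradient(img)
        locked = evolve_snake_greedy(init_snake((64, 64), 18), g)
        again = evolve_snake_greedy(Snake(locked.vertices.copy()), g)
        disp = np.linalg.norm(again.vertices - locked.vertices, axis=1).mean()
        assert disp <= 0.5
        assert again.converged

    def test_zero_gradient_contracts_to_centroid(self):
        out = evolve_snake_greedy(init_snake((64, 64), 15), np.zeros((128, 128)))
        d = np.linalg.norm(out.vertices - np.array([64.0, 64.0]), axis=1)
        assert d.mean() < 1.0  # collapsed, no lock-on anywhere

    def test_rotation_covariance_on_disk(self):
        # off-center disk; rotating the image by 90 deg rotates the region
        img = np.zeros((128, 128))
        img += disk_image(9, center=(50, 70))
        g = normalized_gradient(img)
        out = evolve_snake_greedy(init_snake((50, 70), 16), g)
        reg = {tuple(p) for p in snake_to_region(out, img.shape).region}

        rot = np.rot90(img)  # (r, c) -> (127 - c, r)
        g2 = normalized_gradient(rot)
        out2 = evolve_snake_greedy(init_snake((127 - 70, 50), 16), g2)
        reg2 = {tuple(p) for p in snake_to_region(out2, img.shape).region}
        mapped = {(127 - c, r) for (r, c) in reg}

        def hausdorff(a, b):
            aa = np.array(sorted(a))
            bb = np.array(sorted(b))
            d1 = max(min(np.hypot(*(p - q)) for q in bb) for p in aa)
            d2 = max(min(np.hypot(*(p - q)) for q in aa) for p in bb)
            return max(d1, d2)

        assert hausdorff(mapped, reg2) <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_disks_recovered_within_one_pixel(self, seed):
        rng = np.random.default_rng(seed)
        radius = rng.uniform(5, 20)
        center = rng.uniform(40, 88, 2)
        img = disk_image(radius, center=tuple(center))
        g = normalized_gradient(img)
        out = evolve_snake_greedy(init_snake(tuple(center), radius + 8), g)
        r_eq = np.sqrt(len(snake_to_region(out, img.shape).region) / np.pi)
        assert abs(r_eq - radius) <= 1.0


class TestSnakeToRegion:
    def test_square_lattice_count(self):
        s = Snake(np.array([[0, 0], [0, 4], [4, 4], [4, 0]], dtype=float))
        seg = snake_to_region(s, (10, 10))
        assert len(seg.region) == 25
        assert not seg.degenerate

    def test_circle_area_close_to_continuous(self):
        s = init_snake((20, 20), 10)
        seg = snake_to_region(s, (41, 41))
        assert abs(len(seg.region) - np.pi * 100) / (np.pi * 100) <= 0.03

    def test_collapsed_snake_is_degenerate(self):
        s = Snake(np.full((32, 2), 7.3))
        seg = snake_to_region(s, (20, 20))
        assert seg.degenerate
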