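"""Circular Hough transform: edges, voting, peak extraction."""

import numpy as np
import pytest

from dropcount.config import PipelineConfig
from dropcount.hough import (
    detect_overall,
    edge_map,
    find_circles,
    hough_accumulate,
)
from dropcount.simulate import SimulationParams, generate_fmi, rasterize_disks


def hough_bruteforce(edges: np.ndarray, rmin: int, rmax: int) -> np.ndarray:
    """Naive triple loop: every edge pixel votes on every center at every r."""
    h, w = edges.shape
    acc = np.zeros((rmax - rmin + 1, h, w))
    for er, ec in zip(*np.nonzero(edges)):
        for ri, r in enumerate(range(rmin, rmax + 1)):
            for a in range(h):
                for b in range(w):
                    if round(np.hypot(a - er, b - ec)) == r:
                        acc[ri, a, b] += 1
    return acc


class TestEdgeMap:
    def test_empty_map_has_no_edges(self):
        assert not edge_map(np.zeros((16, 16), dtype=bool)).any()

    def test_disk_edge_count_tracks_perimeter(self):
        disk = rasterize_disks((64, 64), [(32, 32, 20)])
        n_edge = edge_map(disk).sum()
        perimeter = 2 * np.pi * 20
        assert perimeter * 0.85 <= n_edge <= perimeter * 1.15

    def test_touching_disks_match_set_difference_oracle(self):
        union = rasterize_disks((80, 120), [(40, 40, 18), (40, 76, 18)])
        got = edge_map(union)
        # oracle: input minus its 4-neighborhood erosion, by explicit loops
        expected = np.zeros_like(union)
        h, w = union.shape
        for i in range(h):
            for j in range(w):
                if not union[i, j]:
                    continue
                nbrs = [
                    union[i + di, j + dj]
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if 0 <= i + di < h and 0 <= j + dj < w
                ]
                expected[i, j] = not all(nbrs) if len(nbrs) == 4 else False
        assert np.array_equal(got, expected)


class TestAccumulator:
    def test_no_edges_no_votes(self):
        acc = hough_accumulate(np.zeros((20, 20), dtype=bool), 3, 6)
        assert acc.votes.shape == (4, 20, 20)
        assert not acc.votes.any()

    def test_ideal_circle_peak_at_truth(self):
        edges = edge_map(rasterize_disks((110, 130), [(50, 60, 20)]))
        acc = hough_accumulate(edges, 16, 32)
        ri, a, b = np.unravel_index(np.argmax(acc.votes), acc.votes.shape)
        assert abs(a - 50) <= 1 and abs(b - 60) <= 1
        assert abs(int(acc.radii[ri]) - 20) <= 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_naive_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        edges = rng.random((28, 32)) > 0.92
        acc = hough_accumulate(edges, 3, 7)
        assert np.array_equal(
            acc.votes.astype(float), hough_bruteforce(edges, 3, 7)
        )

    def test_rejects_bad_radius_band(self):
        with pytest.raises(ValueError):
            hough_accumulate(np.zeros((8, 8), dtype=bool), 0, 5)
        with pytest.raises(ValueError):
            hough_accumulate(np.zeros((8, 8), dtype=bool), 6, 5)


class TestFindCircles:
    def test_empty_accumulator_empty_set(self):
        acc = hough_accumulate(np.zeros((50, 50), dtype=bool), 16, 32)
        assert len(find_circles(acc, 0.33)) == 0

    def test_ideal_circle_scores_high(self):
        edges = edge_map(rasterize_disks((110, 130), [(50, 60, 20)]))
        circles = find_circles(hough_accumulate(edges, 16, 32), 0.33)
        assert len(circles) == 1
        c = circles[0]
        assert c.score >= 0.9
        assert 0.0 <= c.score <= 1.0
        assert abs(c.row - 50) <= 1 and abs(c.col - 60) <= 1

    def test_two_separated_circles(self):
        mask = rasterize_disks((120, 170), [(55, 55, 20), (55, 105, 20)])
        circles = find_circles(hough_accumulate(edge_map(mask), 16, 32), 0.33)
        assert len(circles) == 2
        for c, (tr, tc) in zip(circles, [(55, 55), (55, 105)]):
            assert np.hypot(c.row - tr, c.col - tc) <= 2

    def test_tangent_circles_resolved(self):
        """The closely-connected case that defeats connected components."""
        mask = rasterize_disks((100, 140), [(50, 50, 18), (50, 86, 18)])
        circles = find_circles(hough_accumulate(edge_map(mask), 16, 32), 0.33)
        assert len(circles) == 2
        for c, (tr, tc) in zip(circles, [(50, 50), (50, 86)]):
            assert np.hypot(c.row - tr, c.col - tc) <= 2

    def test_translation_covariance(self):
        base = rasterize_disks((120, 140), [(50, 55, 18)])
        shifted = np.roll(np.roll(base, 7, axis=0), 9, axis=1)
        c0 = find_circles(hough_accumulate(edge_map(base), 16, 32), 0.33)[0]
        c1 = find_circles(hough_accumulate(edge_map(shifted), 16, 32), 0.33)[0]
        assert abs((c1.row - c0.row) - 7) <= 1
        assert abs((c1.col - c0.col) - 9) <= 1


class TestDetectOverall:
    def test_noise_only_image_yields_no_droplets(self):
        image, _ = generate_fmi(
            SimulationParams(height=420, width=640, n_droplets=0, n_speckles=8, seed=3)
        )
        assert len(detect_overall(image)) == 0

    def test_counts_match_truth_on_small_scene(self, small_frame):
        image, truth = small_frame
        detected = detect_overall(image)
        assert abs(len(detected) - truth.n_overall) <= 1

    def test_all_centers_inside_frame_and_radii_in_band(self, small_frame):
        image, _ = small_frame
        cfg = PipelineConfig()
        for c in detect_overall(image, cfg):
            assert 0 <= c.row < image.shape[0]
            assert 0 <= c.col < image.shape[1]
            assert cfg.radius_min <= c.radius <= cfg.radius_max
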