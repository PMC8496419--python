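"""Superpixel lattice construction, reduction and region partition."""

import numpy as np
import pytest

from smas.alignment import Landmarks
from smas.depth import REGION_IDS
from smas.grid import (LatticeWindow, extract_window, grid_from_landmarks,
                       region_masks, region_pixel_masks, superpixel_reduce)


def aligned_landmarks(fovea=(300.0, 200.0), d=400.0):
    fr, fc = fovea
    raphe = tuple((fr, fc - 60 - 10 * i) for i in range(5))
    return Landmarks(fovea=fovea, onh=(fr, fc + d), raphe_points=raphe,
                     laterality="right")


class TestGridFromLandmarks:
    @pytest.mark.parametrize("d, s", [(400.0, 20), (348.0, 17), (460.0, 23)])
    def test_superpixel_size(self, d, s):
        grid = grid_from_landmarks(aligned_landmarks(d=d), (700, 900))
        assert grid.size_px == s

    def test_twenty_superpixels_separate_fovea_and_onh(self):
        for s in (5, 6, 17, 20, 23):
            grid = grid_from_landmarks(aligned_landmarks(d=20.0 * s), (700, 900))
            assert grid.onh_cell[1] - grid.fovea_cell[1] == 20
            assert grid.onh_cell[0] == grid.fovea_cell[0]

    def test_fovea_at_cell_center(self):
        grid = grid_from_landmarks(aligned_landmarks(), (700, 900))
        center = grid.cell_center_px(*grid.fovea_cell)
        assert abs(center[0] - 300.0) <= 0.5 * grid.size_px
        assert abs(center[1] - 200.0) <= 0.5 * grid.size_px

    def test_tiny_distance_rejected(self):
        with pytest.raises(ValueError):
            grid_from_landmarks(aligned_landmarks(d=5.0), (700, 900))


class TestSuperpixelReduce:
    def test_uniform_image(self):
        grid = grid_from_landmarks(aligned_landmarks(fovea=(32.0, 20.0), d=160.0),
                                   (64, 200))
        lattice, valid = superpixel_reduce(np.full((64, 200), 0.7), grid)
        assert np.allclose(lattice[valid], 0.7)

    def test_checkerboard_halves(self):
        grid = grid_from_landmarks(aligned_landmarks(fovea=(32.0, 20.0), d=160.0),
                                   (64, 200))
        assert grid.size_px == 8
        img = np.indices((64, 200)).sum(axis=0) % 2  # 0/1 checkerboard
        lattice, valid = superpixel_reduce(img.astype(float), grid)
        assert np.allclose(lattice[valid], 0.5)

    def test_matches_loop_oracle(self, rng):
        img = rng.random((64, 64))
        grid = grid_from_landmarks(aligned_landmarks(fovea=(32.0, 8.0), d=320.0),
                                   (64, 64))
        assert grid.size_px == 16
        lattice, valid = superpixel_reduce(img, grid)
        s = grid.size_px
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                r0 = max(grid.row0 + r * s, 0)
                c0 = max(grid.col0 + c * s, 0)
                r1 = min(grid.row0 + (r + 1) * s, 64)
                c1 = min(grid.col0 + (c + 1) * s, 64)
                if r1 <= r0 or c1 <= c0:
                    continue
                assert lattice[r, c] == pytest.approx(
                    img[r0:r1, c0:c1].mean(), abs=1e-12)

    def test_commutes_with_scaling(self, rng):
        img = rng.random((64, 200))
        grid = grid_from_landmarks(aligned_landmarks(fovea=(32.0, 20.0), d=160.0),
                                   (64, 200))
        a, _ = superpixel_reduce(img * 3.5, grid)
        b, _ = superpixel_reduce(img, grid)
        assert np.allclose(a, 3.5 * b, equal_nan=True)

    def test_invalid_pixels_excluded(self):
        grid = grid_from_landmarks(aligned_landmarks(fovea=(32.0, 20.0), d=160.0),
                                   (64, 200))
        img = np.full((64, 200), 2.0)
        validity = np.ones((64, 200), dtype=bool)
        validity[:32] = False
        lattice, valid = superpixel_reduce(img, grid, validity=validity)
        assert not valid[0, 5]          # fully invalid cell flagged
        assert np.allclose(lattice[valid], 2.0)


class TestRegionMasks:
    def test_partition(self):
        grid = grid_from_landmarks(aligned_landmarks(), (700, 900))
        masks = region_masks(grid)
        total = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
        for mask in masks.values():
            total += mask
        assert np.all(total == 1)

    def test_onh_cell_in_onh_region(self):
        grid = grid_from_landmarks(aligned_landmarks(), (700, 900))
        masks = region_masks(grid)
        assert masks["onh_region"][grid.onh_cell]

    def test_far_temporal_fovea_row_is_raphe(self):
        grid = grid_from_landmarks(aligned_landmarks(fovea=(300.0, 300.0)),
                                   (700, 900))
        masks = region_masks(grid)
        r, c = grid.fovea_cell
        assert masks["raphe"][r, c - 12]
        assert masks["temporal_macula"][r, c - 5]

    def test_pixel_masks_agree_with_lattice(self):
        grid = grid_from_landmarks(aligned_landmarks(fovea=(100.0, 60.0), d=120.0),
                                   (256, 256))
        cell_masks = region_masks(grid)
        px_masks = region_pixel_masks(grid)
        s = grid.size_px
        for name in REGION_IDS:
            # a pixel inherits the region of its cell
            r, c = grid.fovea_cell[0] + 2, grid.fovea_cell[1] + 3
            row_px = grid.row0 + r * s + s // 2
            col_px = grid.col0 + c * s + s // 2
            assert px_masks[name][row_px, col_px] == cell_masks[name][r, c]


class TestLatticeWindow:
    def test_fovea_value_round_trips(self, rng):
        grid = grid_from_landmarks(aligned_landmarks(fovea=(100.0, 60.0), d=120.0),
                                   (256, 256))
        lattice = rng.random((grid.n_rows, grid.n_cols))
        valid = np.ones_like(lattice, dtype=bool)
        window = LatticeWindow()
        wv, wok = extract_window(lattice, valid, grid, window)
        assert wv[window.fovea_index] == lattice[grid.fovea_cell]
        assert wv[window.onh_index()] == lattice[grid.onh_cell]

    def test_out_of_image_cells_invalid(self, rng):
        grid = grid_from_landmarks(aligned_landmarks(fovea=(100.0, 60.0), d=120.0),
                                   (256, 256))
        lattice = rng.random((grid.n_rows, grid.n_cols))
        wv, wok = extract_window(lattice, np.ones_like(lattice, bool), grid)
        assert not wok[0, 0]            # far temporal corner beyond the image
        assert np.isnan(wv[0, 0])
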