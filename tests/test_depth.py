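"""Depth-pixel arithmetic, the six slab schemes, and slab averaging."""

import numpy as np
import pytest

from smas.depth import (DepthAxis, REGION_IDS, SlabBand, average_band,
                        build_method_slabs, pixel_depth_range, scheme_catalog,
                        schemes_from_yaml, schemes_to_yaml, smas_band)


class TestPixelDepthRange:
    @pytest.mark.parametrize("k, expected", [
        (1, (0.0, 3.87)),
        (13, (46.44, 50.31)),       # Hood slab posterior boundary, ~50.3 um
        (50, (189.63, 193.5)),      # deepest pixel ends 193.5 um below ILM
    ])
    def test_printed_boundaries(self, k, expected):
        lo, hi = pixel_depth_range(k)
        assert lo == pytest.approx(expected[0])
        assert hi == pytest.approx(expected[1])

    @pytest.mark.parametrize("k", [0, 51, -3])
    def test_out_of_range(self, k):
        with pytest.raises(IndexError):
            pixel_depth_range(k)

    def test_total_span(self):
        assert DepthAxis().total_depth_um == pytest.approx(193.5)


class TestSmasBands:
    @pytest.mark.parametrize("m, pixels, depths", [
        (1, (3, 6), (7.74, 23.22)),     # shallowest analysed band
        (7, (27, 30), (100.62, 116.1)),  # last analysed band ends ~116 um
        (12, (47, 50), (178.02, 193.5)),
    ])
    def test_band_pixels_and_depths(self, m, pixels, depths):
        band = smas_band(m)
        assert (band.pixel_start, band.pixel_end) == pixels
        assert band.depth_range_um() == pytest.approx(depths)

    @pytest.mark.parametrize("m", [0, 13])
    def test_index_errors(self, m):
        with pytest.raises(IndexError):
            smas_band(m)

    def test_bands_tile_pixels_3_to_50(self):
        bands = [smas_band(m) for m in range(1, 13)]
        assert all(b.width == 4 for b in bands)
        covered = [p for b in bands for p in range(b.pixel_start, b.pixel_end + 1)]
        assert covered == list(range(3, 51))


class TestSchemeCatalog:
    def test_six_schemes(self):
        cat = scheme_catalog()
        assert set(cat) == {"SMAS", "Hood", "Ashimatey", "BestVis", "AllVis", "Deep"}

    def test_uniform_schemes(self):
        cat = scheme_catalog()
        assert all(b == SlabBand(1, 13) for b in cat["Hood"].bands.values())
        assert all(b == SlabBand(10, 20) for b in cat["Deep"].bands.values())

    def test_region_dependent_bands(self):
        cat = scheme_catalog()
        ash = cat["Ashimatey"].bands
        assert ash["onh_region"] == SlabBand(7, 13)
        assert ash["raphe"] == SlabBand(5, 6)
        assert ash["temporal_macula"] == SlabBand(7, 9)
        allvis = cat["AllVis"].bands
        assert allvis["onh_region"] == SlabBand(3, 21)
        assert allvis["raphe"] == SlabBand(3, 8)
        assert allvis["inferior_nasal"] == SlabBand(3, 12)
        best = cat["BestVis"].bands
        assert best["raphe"] == SlabBand(4, 6)
        assert best["central"] == SlabBand(5, 7)
        for scheme in cat.values():
            if not scheme.is_multi_slab:
                assert set(scheme.bands) == set(REGION_IDS)

    @pytest.mark.parametrize("band, posterior_um", [
        (SlabBand(1, 13), 50.3),    # Hood
        (SlabBand(10, 20), 77.4),   # Deep
        (SlabBand(3, 21), 81.3),    # AllVis, ONH region
        (SlabBand(3, 6), 23.2),     # first SMAS band
        (SlabBand(27, 30), 116.1),  # seventh SMAS band
        (SlabBand(47, 50), 193.5),  # last SMAS band
    ])
    def test_posterior_depths_match_printed_values(self, band, posterior_um):
        assert round(band.depth_range_um()[1], 1) == posterior_um

    def test_smas_analyzed_slabs(self):
        assert scheme_catalog()["SMAS"].analyzed_slabs == 7

    def test_yaml_round_trip(self):
        cat = scheme_catalog()
        assert schemes_from_yaml(schemes_to_yaml(cat)) == cat


class TestAverageBand:
    def test_constant_depth_values(self):
        stack = np.arange(1, 51, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        slab = average_band(stack, SlabBand(3, 6))
        assert np.allclose(slab, 4.5)

    def test_single_pixel_band_is_identity(self, rng):
        stack = rng.random((50, 6, 6))
        assert np.array_equal(average_band(stack, SlabBand(10, 10)), stack[9])

    def test_matches_loop_oracle(self, rng):
        stack = rng.random((50, 8, 8))
        band = SlabBand(3, 6)
        oracle = np.zeros((8, 8))
        for r in range(8):
            for c in range(8):
                oracle[r, c] = sum(stack[k, r, c] for k in range(2, 6)) / 4.0
        assert np.allclose(average_band(stack, band), oracle, atol=1e-9)

    def test_monotone_in_stack(self, rng):
        a = rng.random((20, 5, 5))
        b = a + rng.random((20, 5, 5))  # pointwise >= a
        band = SlabBand(2, 9)
        assert np.all(average_band(stack=b, band=band) >= average_band(a, band))

    def test_band_exceeding_depth(self):
        with pytest.raises(IndexError):
            average_band(np.zeros((10, 4, 4)), SlabBand(8, 12))


class TestBuildMethodSlabs:
    def _masks(self, shape):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, len(REGION_IDS), size=shape)
        return {r: labels == i for i, r in enumerate(REGION_IDS)}

    def test_smas_yields_seven_images(self, rng):
        stack = rng.random((50, 6, 6))
        out = build_method_slabs(stack, scheme_catalog()["SMAS"])
        assert len(out) == 7
        assert out[0][1] == SlabBand(3, 6)

    def test_hood_yields_one_image(self, rng):
        stack = rng.random((50, 6, 6))
        out = build_method_slabs(stack, scheme_catalog()["Hood"])
        assert len(out) == 1
        assert np.allclose(out[0][0], stack[:13].mean(axis=0))

    def test_composite_stitches_per_region_oracle(self, rng):
        stack = rng.random((50, 12, 12))
        masks = self._masks((12, 12))
        scheme = scheme_catalog()["Ashimatey"]
        (composite, bands, cov), = build_method_slabs(stack, scheme, masks)
        assert cov == "composite"
        for region, band in scheme.bands.items():
            expected = stack[band.pixel_start - 1: band.pixel_end].mean(axis=0)
            assert np.allclose(composite[masks[region]], expected[masks[region]])

    def test_missing_region_mask_is_an_error(self, rng):
        stack = rng.random((50, 6, 6))
        masks = self._masks((6, 6))
        del masks["raphe"]
        with pytest.raises(ValueError, match="raphe"):
            build_method_slabs(stack, scheme_catalog()["Ashimatey"], masks)
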