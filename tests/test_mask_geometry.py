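"""Mask extraction, validation rules and lesion morphometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from earlyamdrate.mask_geometry import (LesionMask, MaskExtractionError,
                                        extract_masks, masks_from_rle,
                                        masks_to_rle, measure_geometry,
                                        render_masks, validate_mask)
from earlyamdrate.oct_preprocess import ScanCalibration, pixel_area


def mask_of(pixels, colour=(255, 0, 0)):
    return LesionMask(frozenset(pixels), colour, "s1")


class TestValidateMask:
    def test_diagonal_pair_is_valid(self):
        assert validate_mask(mask_of({(0, 0), (1, 1)})) == []

    def test_single_pixel_below_minimal_size(self):
        violations = validate_mask(mask_of({(5, 5)}))
        assert len(violations) == 1
        assert "minimal size" in violations[0].message

    def test_gap_breaks_connectivity(self):
        violations = validate_mask(mask_of({(0, 0), (0, 2)}))
        assert len(violations) == 1
        assert "connected" in violations[0].message

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            validate_mask(mask_of(set()))

    def test_grey_colour_rejected(self):
        with pytest.raises(ValueError, match="grey"):
            mask_of({(0, 0), (0, 1)}, colour=(7, 7, 7))


class TestExtractMasks:
    def _base(self, shape=(20, 30)):
        rng = np.random.default_rng(0)
        return rng.integers(0, 256, size=shape).astype(np.uint8)

    def test_five_distinct_colours_give_five_masks(self):
        base = self._base()
        colours = [(255, 0, 0), (0, 160, 0), (0, 80, 255), (255, 200, 0),
                   (200, 0, 200)]
        masks = [mask_of({(2, 3 + 5 * i), (3, 3 + 5 * i)}, c)
                 for i, c in enumerate(colours)]
        overlay = render_masks(base, masks)
        recovered = extract_masks(overlay, base)
        assert len(recovered) == 5
        assert {m.colour_id for m in recovered} == set(colours)

    def test_pure_greyscale_overlay_yields_nothing(self):
        base = self._base()
        overlay = np.repeat(base[:, :, None], 3, axis=2)
        assert extract_masks(overlay, base) == []

    def test_disconnected_colour_rejected(self):
        base = self._base()
        overlay = np.repeat(base[:, :, None], 3, axis=2)
        for r, c in [(2, 2), (3, 2), (10, 20), (11, 20)]:  # two blobs
            overlay[r, c] = (255, 0, 0)
        with pytest.raises(MaskExtractionError, match="connected"):
            extract_masks(overlay, base)

    def test_undersized_colour_rejected(self):
        base = self._base()
        overlay = np.repeat(base[:, :, None], 3, axis=2)
        overlay[4, 4] = (0, 0, 255)
        with pytest.raises(MaskExtractionError, match="minimal size"):
            extract_masks(overlay, base)

    def test_shape_mismatch_rejected(self):
        base = self._base((20, 30))
        overlay = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="shape"):
            extract_masks(overlay, base)

    def test_touching_lesions_stay_separate(self):
        # confluent lesions share a border; exact-colour grouping must
        # not merge them
        base = self._base()
        left = mask_of({(5, 5), (6, 5), (5, 6), (6, 6)}, (255, 0, 0))
        right = mask_of({(5, 7), (6, 7), (5, 8), (6, 8)}, (0, 0, 255))
        recovered = extract_masks(render_masks(base, [left, right]), base)
        assert [m.pixel_set for m in recovered] == [left.pixel_set,
                                                   right.pixel_set]

    def test_deterministic_ordering(self):
        base = self._base()
        a = mask_of({(2, 10), (3, 10)}, (0, 200, 0))
        b = mask_of({(8, 4), (9, 4)}, (200, 0, 0))
        recovered = extract_masks(render_masks(base, [a, b]), base)
        assert [m.colour_id for m in recovered] == [b.colour_id, a.colour_id]


class TestMeasureGeometry:
    def test_block_geometry(self, calib):
        pixels = {(r, c) for r in range(4, 7) for c in range(10, 13)}
        geom = measure_geometry(mask_of(pixels), calib)
        assert geom.area_px == 9
        assert geom.area_um2 == pytest.approx(9 * 43.6149, abs=1e-6)
        assert geom.diameter_px == 3
        assert geom.diameter_um == pytest.approx(33.81, abs=1e-9)
        assert geom.centroid == (5.0, 11.0)

    def test_horizontal_run(self, calib):
        pixels = {(7, c) for c in range(20, 25)}
        geom = measure_geometry(mask_of(pixels), calib)
        assert geom.diameter_px == 5
        assert geom.centroid[0] == 7.0

    def test_vertical_pair_has_diameter_one(self, calib):
        geom = measure_geometry(mask_of({(0, 0), (1, 0)}), calib)
        assert geom.diameter_px == 1
        assert geom.area_px == 2

    def test_l_shape_centroid(self, calib):
        # brute-force mean over the enumerated coordinates
        pixels = {(0, 0), (0, 1), (0, 2), (0, 3),
                  (1, 0), (2, 0), (3, 0), (4, 0)}
        rows = [p[0] for p in pixels]
        cols = [p[1] for p in pixels]
        expected = (sum(rows) / len(pixels), sum(cols) / len(pixels))
        geom = measure_geometry(mask_of(pixels), calib)
        assert geom.centroid == pytest.approx(expected)
        assert geom.centroid == pytest.approx((1.25, 0.75))

    def test_invalid_mask_rejected(self, calib):
        with pytest.raises(ValueError, match="invalid mask"):
            measure_geometry(mask_of({(0, 0), (0, 5)}), calib)

    def test_area_ratio_equals_pixel_area(self, calib):
        for pixels in [{(0, 0), (1, 1)}, {(3, c) for c in range(9)}]:
            geom = measure_geometry(mask_of(pixels), calib)
            assert geom.area_um2 / geom.area_px == pytest.approx(
                pixel_area(calib))
            assert 1 <= geom.diameter_px <= geom.area_px


@st.composite
def connected_masks(draw):
    """Random 8-connected masks grown pixel by pixel from a seed."""
    pixels = {(draw(st.integers(5, 40)), draw(st.integers(5, 40)))}
    for _ in range(draw(st.integers(1, 15))):
        r, c = draw(st.sampled_from(sorted(pixels)))
        dr = draw(st.integers(-1, 1))
        dc = draw(st.integers(-1, 1))
        pixels.add((r + dr, c + dc))
    if len(pixels) < 2:
        pixels.add((max(p[0] for p in pixels) + 1, next(iter(pixels))[1]))
    return mask_of(pixels)


class TestTranslationInvariance:
    @settings(max_examples=50, derandomize=True)
    @given(mask=connected_masks(), d_row=st.integers(-30, 30),
           d_col=st.integers(-30, 30))
    def test_shift_moves_centroid_only(self, calib, mask, d_row, d_col):
        before = measure_geometry(mask, calib)
        after = measure_geometry(mask.translate(d_row, d_col), calib)
        assert after.area_px == before.area_px
        assert after.area_um2 == before.area_um2
        assert after.diameter_px == before.diameter_px
        assert after.centroid[0] == pytest.approx(before.centroid[0] + d_row)
        assert after.centroid[1] == pytest.approx(before.centroid[1] + d_col)

    @settings(max_examples=30, derandomize=True)
    @given(mask=connected_masks())
    def test_centroid_inside_bounding_box(self, calib, mask):
        geom = measure_geometry(mask, calib)
        r0, c0, r1, c1 = mask.bounding_box()
        assert r0 <= geom.centroid[0] <= r1
        assert c0 <= geom.centroid[1] <= c1


class TestRleRoundtrip:
    @settings(max_examples=30, derandomize=True)
    @given(mask=connected_masks())
    def test_rle_roundtrip(self, mask):
        [recovered] = masks_from_rle(masks_to_rle([mask]))
        assert recovered.pixel_set == mask.pixel_set
        assert recovered.colour_id == mask.colour_id
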