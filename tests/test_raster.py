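"""Aperture rasterization against exhaustive pixel/edge oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imrtqa import (
    ApertureImage,
    GeometryMismatchError,
    Segment,
    default_geometry,
)
from imrtqa.raster import (
    PIXEL_DX_CM,
    PIXEL_DY_CM,
    area_perimeter,
    composite_image,
    connected_openings,
    rasterize_composite,
    rasterize_stack,
    row_profile,
)

from bruteforce import flood_fill_components, mask_features
from conftest import segment_all_pairs


def one_pair_segment(stack: str, pair: int, left: float, right: float) -> Segment:
    """Segment with a single open pair in one stack; the other stack wide open."""
    g = default_geometry()
    tl, tr = np.zeros(g.top_pairs), np.zeros(g.top_pairs)
    bl, br = np.zeros(g.bottom_pairs), np.zeros(g.bottom_pairs)
    if stack == "top":
        tl[pair], tr[pair] = left, right
    else:
        bl[pair], br[pair] = left, right
    return Segment(0.0, 10.0, tl, tr, bl, br)


class TestRasterizeStack:
    def test_closed_pair_rasterizes_to_nothing(self):
        img = rasterize_stack(one_pair_segment("top", 10, 0.5, 0.5), "top")
        assert not img.mask.any()

    def test_open_top_pair_covers_two_rows_of_200_columns(self):
        # 2.00 cm opening at 0.01 cm pitch -> 200 columns; one 0.83 cm top
        # leaf spans two 0.415 cm composite rows
        img = rasterize_stack(one_pair_segment("top", 16, -1.0, 1.0), "top")
        open_rows = np.flatnonzero(img.mask.any(axis=1))
        assert len(open_rows) == 2
        assert list(img.mask.sum(axis=1)[open_rows]) == [200, 200]

    def test_minimal_opening_rasterizes_to_single_column(self):
        img = rasterize_stack(one_pair_segment("top", 16, -0.005, 0.005), "top")
        open_rows = np.flatnonzero(img.mask.any(axis=1))
        assert list(img.mask.sum(axis=1)[open_rows]) == [1, 1]
        assert len(np.unique(np.nonzero(img.mask)[1])) == 1

    def test_stack_offset_staggers_top_and_bottom_rows(self):
        top = rasterize_stack(one_pair_segment("top", 16, -1, 1), "top")
        bottom = rasterize_stack(one_pair_segment("bottom", 17, -1, 1), "bottom")
        top_rows = set(np.flatnonzero(top.mask.any(axis=1)))
        bot_rows = set(np.flatnonzero(bottom.mask.any(axis=1)))
        # half-leaf offset: the two stacks' row pairs overlap by one row
        assert len(top_rows & bot_rows) == 1


class TestComposite:
    def test_identical_stacks_give_identity(self):
        seg = segment_all_pairs(-2, 2)
        top = rasterize_stack(seg, "top")
        bottom = rasterize_stack(seg, "bottom")
        comp = composite_image(top, bottom)
        assert np.array_equal(comp.mask, top.mask & bottom.mask)

    def test_disjoint_stack_openings_give_empty_composite(self):
        g = default_geometry()
        seg = Segment(
            0.0, 10.0,
            np.full(g.top_pairs, -5.0), np.full(g.top_pairs, -1.0),
            np.full(g.bottom_pairs, 1.0), np.full(g.bottom_pairs, 5.0),
        )
        assert not rasterize_composite(seg).mask.any()

    def test_commutativity_and_area_bound(self, rng):
        g = default_geometry()
        seg = Segment(
            0.0, 10.0,
            rng.uniform(-5, 0, g.top_pairs), rng.uniform(0, 5, g.top_pairs),
            rng.uniform(-5, 0, g.bottom_pairs), rng.uniform(0, 5, g.bottom_pairs),
        )
        top = rasterize_stack(seg, "top")
        bottom = rasterize_stack(seg, "bottom")
        ab = composite_image(top, bottom)
        ba = composite_image(bottom, top)
        assert np.array_equal(ab.mask, ba.mask)
        assert ab.mask.sum() <= min(top.mask.sum(), bottom.mask.sum())

    def test_grid_mismatch_rejected(self):
        a = ApertureImage(np.zeros((4, 5), dtype=bool), 0.0, 0.0)
        b = ApertureImage(np.zeros((4, 5), dtype=bool), 0.415, 0.0)
        with pytest.raises(GeometryMismatchError):
            composite_image(a, b)


class TestAreaPerimeter:
    def test_empty_image(self):
        img = ApertureImage(np.zeros((10, 20), dtype=bool), 0.0, 0.0)
        assert area_perimeter(img) == (0.0, 0.0, 0.0, 0.0)

    def test_single_pixel_edges(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        area, perim, side, tip = area_perimeter(ApertureImage(mask, 0, 0))
        assert area == pytest.approx(PIXEL_DX_CM * PIXEL_DY_CM)
        assert tip == pytest.approx(2 * PIXEL_DY_CM)  # 0.83
        assert side == pytest.approx(2 * PIXEL_DX_CM)  # 0.02
        assert perim == pytest.approx(0.85)

    @pytest.mark.parametrize("h,w", [(1, 1), (3, 7), (10, 400), (70, 2800)])
    def test_rectangle_matches_analytic_perimeter(self, h, w):
        mask = np.zeros((h + 2, w + 2), dtype=bool)
        mask[1 : 1 + h, 1 : 1 + w] = True
        area, perim, side, tip = area_perimeter(ApertureImage(mask, 0, 0))
        width_cm, height_cm = w * PIXEL_DX_CM, h * PIXEL_DY_CM
        assert area == pytest.approx(width_cm * height_cm)
        assert perim == pytest.approx(2 * (width_cm + height_cm))
        assert side == pytest.approx(2 * width_cm)
        assert tip == pytest.approx(2 * height_cm)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_masks_match_exhaustive_edge_count(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 30)) < 0.4
        img = ApertureImage(mask, 0.0, 0.0)
        oracle = mask_features(mask, 0.0)
        area, perim, side, tip = area_perimeter(img)
        assert area == pytest.approx(oracle["area"])
        assert side == pytest.approx(oracle["side"])
        assert tip == pytest.approx(oracle["tip"])
        assert perim == pytest.approx(oracle["perimeter"])

    def test_area_invariant_under_whole_pixel_translation(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[5:9, 10:22] = True
        shifted = np.roll(mask, (3, 7), axis=(0, 1))
        a1 = area_perimeter(ApertureImage(mask, 0, 0))[0]
        a2 = area_perimeter(ApertureImage(shifted, 0, 0))[0]
        assert a1 == a2


class TestConnectedOpenings:
    def test_empty_and_two_rectangles(self):
        mask = np.zeros((10, 30), dtype=bool)
        assert connected_openings(ApertureImage(mask, 0, 0)) == 0
        mask[1:4, 2:8] = True
        mask[6:9, 15:25] = True
        assert connected_openings(ApertureImage(mask, 0, 0)) == 2

    def test_diagonal_contact_counts_as_separate_openings(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert connected_openings(ApertureImage(mask, 0, 0)) == 2

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_masks_match_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((50, 200)) < 0.35
        assert connected_openings(ApertureImage(mask, 0, 0)) == (
            flood_fill_components(mask)
        )


class TestRowProfile:
    def test_rectangle_rows_identical(self):
        seg = segment_all_pairs(-1.5, 2.5)
        profiles = [p for p in row_profile(rasterize_composite(seg)) if p.active]
        assert len(profiles) > 0
        for p in profiles:
            assert p.left == pytest.approx(-1.5, abs=1e-9)
            assert p.right == pytest.approx(2.5, abs=1e-9)
            assert p.gap == pytest.approx(4.0, abs=1e-9)
            assert len(p.runs) == 1

    def test_two_run_row_reports_outermost_edges(self):
        mask = np.zeros((3, 100), dtype=bool)
        mask[1, 10:20] = True
        mask[1, 50:70] = True
        [p] = [p for p in row_profile(ApertureImage(mask, 0.0, 0.0)) if p.active]
        assert len(p.runs) == 2
        assert p.left == pytest.approx(0.10)
        assert p.right == pytest.approx(0.70)
        assert p.gap == pytest.approx(0.60)

    def test_single_run_gap_equals_open_column_count(self, rng):
        mask = np.zeros((5, 200), dtype=bool)
        for r in range(5):
            a = rng.integers(0, 100)
            b = a + rng.integers(1, 100)
            mask[r, a:b] = True
        for p in row_profile(ApertureImage(mask, -1.0, -1.0)):
            count = mask[p.row].sum()
            assert p.gap == pytest.approx(PIXEL_DX_CM * count)
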