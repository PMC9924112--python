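"""Aperture rasterization and geometric primitives.

Each segment's two leaf banks are converted into binary beam's-eye-view
images on a common composite grid: 0.01 cm crossline pixels by 0.415 cm
inline rows (half a leaf width, the effective resolution of the staggered
stacks).  The composite aperture is the logical AND of the two per-stack
images — a pixel is exposed only where both stacks are open.  All
complexity metrics downstream are computed from these composite images.

Grid layout
-----------
Columns span a fixed +/- 14.0 cm crossline extent (2800 columns), wide
enough for any physical field; rows span the bottom stack's inline extent
(35 leaves x 0.83 cm) at the 0.415 cm composite pitch (70 rows).  A pixel
is open iff its crossline center lies in the half-open leaf interval
[left, right); a closed pair (left == right) therefore exposes nothing,
and an interval aligned with pixel edges opens exactly width/0.01 columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    PIXEL_DX_CM,
    PIXEL_DY_CM,
    ApertureImage,
    GeometryMismatchError,
    MLCGeometry,
    Segment,
)

__all__ = [
    "RowProfile",
    "rasterize_stack",
    "composite_image",
    "rasterize_composite",
    "area_perimeter",
    "connected_openings",
    "row_profile",
    "render_ascii",
]

#: Fixed crossline half-extent of aperture images, cm.
CROSSLINE_HALF_EXTENT_CM = 14.0
#: Number of crossline columns.
N_COLS = int(round(2 * CROSSLINE_HALF_EXTENT_CM / PIXEL_DX_CM))
#: Tolerance for leaf-edge / pixel-center comparisons, cm (positions are
#: round-tripped to 1e-9 cm, so boundaries are stable at this scale).
EDGE_TOL_CM = 1e-9


@dataclass
class RowProfile:
    """Per-row summary of a composite aperture.

    ``left`` / ``right`` are the outermost open pixel edges in cm (the
    effective leaf-pair positions for that composite row); ``gap`` their
    difference; ``runs`` the list of disjoint open intervals for
    multi-hole rows.  Inactive rows have ``gap = 0`` and empty runs.
    """

    row: int
    active: bool
    left: float
    right: float
    gap: float
    runs: List[Tuple[float, float]]


def _grid_params(geometry: MLCGeometry) -> Tuple[float, int, float]:
    """(row_origin, n_rows, col_origin) of the composite grid, cm."""
    row_origin = geometry.bottom_inline_low
    n_rows = int(round(geometry.bottom_pairs * geometry.leaf_width_iso / PIXEL_DY_CM))
    return row_origin, n_rows, -CROSSLINE_HALF_EXTENT_CM


def rasterize_stack(
    segment: Segment, stack: str, geometry: MLCGeometry | None = None
) -> ApertureImage:
    """Rasterize one leaf bank ('top' or 'bottom') onto the composite grid.

    A pixel is open iff its inline center falls within one of this
    stack's leaf pairs and its crossline center lies in that pair's
    half-open [left, right) interval; composite rows outside the stack's
    inline extent are closed.
    """
    if geometry is None:
        geometry = default_geometry_of(segment)
    segment.validate_against(geometry)
    if stack == "top":
        left, right = segment.top_left, segment.top_right
        stack_low, n_pairs = geometry.top_inline_low, geometry.top_pairs
    elif stack == "bottom":
        left, right = segment.bottom_left, segment.bottom_right
        stack_low, n_pairs = geometry.bottom_inline_low, geometry.bottom_pairs
    else:
        raise ValueError(f"stack must be 'top' or 'bottom', got {stack!r}")

    row_origin, n_rows, col_origin = _grid_params(geometry)
    mask = np.zeros((n_rows, N_COLS), dtype=bool)

    # Inline row centers -> leaf-pair index of this stack (or -1).
    row_centers = row_origin + PIXEL_DY_CM * (np.arange(n_rows) + 0.5)
    pair_idx = np.floor((row_centers - stack_low) / geometry.leaf_width_iso).astype(int)
    valid = (row_centers >= stack_low - EDGE_TOL_CM) & (
        pair_idx >= 0
    ) & (pair_idx < n_pairs)

    col_centers = col_origin + PIXEL_DX_CM * (np.arange(N_COLS) + 0.5)
    for r in np.nonzero(valid)[0]:
        p = pair_idx[r]
        lo, hi = left[p], right[p]
        if hi - lo <= EDGE_TOL_CM:
            continue  # closed pair
        mask[r] = (col_centers >= lo - EDGE_TOL_CM) & (col_centers < hi - EDGE_TOL_CM)
    return ApertureImage(mask, row_origin, col_origin)


def default_geometry_of(segment: Segment) -> MLCGeometry:
    """Infer the default geometry matching a segment's array lengths."""
    return MLCGeometry(
        top_pairs=len(segment.top_left), bottom_pairs=len(segment.bottom_left)
    )


def composite_image(top: ApertureImage, bottom: ApertureImage) -> ApertureImage:
    """Elementwise AND of the two per-stack images (identical grids)."""
    if not top.same_grid_as(bottom):
        raise GeometryMismatchError("top and bottom aperture grids differ")
    return ApertureImage(top.mask & bottom.mask, top.row_origin, top.col_origin)


def rasterize_composite(
    segment: Segment, geometry: MLCGeometry | None = None
) -> ApertureImage:
    """Composite aperture of a segment: AND of both rasterized stacks."""
    top = rasterize_stack(segment, "top", geometry)
    bottom = rasterize_stack(segment, "bottom", geometry)
    return composite_image(top, bottom)


def area_perimeter(img: ApertureImage) -> Tuple[float, float, float, float]:
    """Open area and exposed-edge perimeter of a binary aperture.

    Returns ``(area_cm2, perimeter_cm, side_perimeter_cm, tip_perimeter_cm)``.
    Tip edges run at constant crossline coordinate (leaf-tip faces, each
    0.415 cm long); side edges at constant inline coordinate (leaf sides,
    each 0.01 cm).  ``perimeter = side + tip``.
    """
    m = img.mask
    area = float(m.sum()) * PIXEL_DX_CM * PIXEL_DY_CM
    # Exposed edges between crossline neighbours (and at image borders)
    # are leaf-tip faces of length PIXEL_DY_CM.
    padded = np.pad(m, ((0, 0), (1, 1)))
    n_tip = int(np.count_nonzero(np.diff(padded.astype(np.int8), axis=1)))
    # Exposed edges between inline neighbours are leaf sides, PIXEL_DX_CM.
    padded = np.pad(m, ((1, 1), (0, 0)))
    n_side = int(np.count_nonzero(np.diff(padded.astype(np.int8), axis=0)))
    tip = n_tip * PIXEL_DY_CM
    side = n_side * PIXEL_DX_CM
    return area, side + tip, side, tip


def connected_openings(img: ApertureImage) -> int:
    """Number of 4-connected components of open pixels."""
    _, n = ndimage.label(img.mask)  # default structure = 4-connectivity
    return int(n)


def row_profile(img: ApertureImage) -> List[RowProfile]:
    """Outermost open edges, gap and open runs for every composite row."""
    profiles: List[RowProfile] = []
    for r in range(img.n_rows):
        row = img.mask[r]
        idx = np.flatnonzero(row)
        if idx.size == 0:
            profiles.append(RowProfile(r, False, 0.0, 0.0, 0.0, []))
            continue
        # Decompose into maximal runs of consecutive open columns.
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        runs = [
            (
                img.col_origin + PIXEL_DX_CM * idx[s],
                img.col_origin + PIXEL_DX_CM * (idx[e] + 1),
            )
            for s, e in zip(starts, ends)
        ]
        left = runs[0][0]
        right = runs[-1][1]
        profiles.append(RowProfile(r, True, left, right, right - left, runs))
    return profiles


def render_ascii(img: ApertureImage, col_step: int = 20) -> str:
    """Coarse ASCII rendering of an aperture mask (debugging aid)."""
    sub = img.mask[:, ::col_step]
    return "\n".join("".join("#" if v else "." for v in row) for row in sub)
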