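"""Domain types and machine-geometry configuration.

The machine modelled here is a 0.35 T MR-linac delivering step-and-shoot
IMRT through two stacked multileaf-collimator (MLC) banks.  The top stack
has 34 opposed leaf pairs (68 leaves), the bottom stack 35 pairs (70
leaves); both project to a 0.83 cm leaf width at the 90 cm
source-to-axis distance, and the bottom stack is shifted inline by half a
leaf width (0.415 cm) so that the composite aperture has an effective
0.415 cm inline resolution.

Coordinate conventions used throughout the package:

* crossline ``x``: the leaf-travel direction, signed cm at isocenter;
* inline ``y``: parallel to the static magnetic field (superior-inferior);
* ``z``: the beam axis at gantry 0.

``Grid3D`` volumes are indexed ``values[ix, iy, iz]`` on those axes with
voxel-center origins in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Tuple

import numpy as np

__all__ = [
    "MLCGeometry",
    "Segment",
    "Plan",
    "Grid3D",
    "ApertureImage",
    "GammaResult",
    "MetricReport",
    "ValidationError",
    "GeometryMismatchError",
    "default_geometry",
    "total_mu",
    "METRIC_NAMES",
    "METRIC_UNITS",
    "PIXEL_DX_CM",
    "PIXEL_DY_CM",
]

#: Crossline pixel pitch of aperture images, cm.
PIXEL_DX_CM = 0.01
#: Inline pixel pitch of aperture images (half a leaf width), cm.
PIXEL_DY_CM = 0.415


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class GeometryMismatchError(ValidationError):
    """Array lengths or grids do not match the declared geometry."""


@dataclass(frozen=True)
class MLCGeometry:
    """Dual-stacked MLC bank geometry projected to isocenter.

    Parameters
    ----------
    top_pairs, bottom_pairs:
        Number of opposed leaf pairs per stack.
    leaf_width_iso:
        Projected leaf width at isocenter, cm.
    stack_offset:
        Inline shift of the bottom stack relative to the top, cm
        (half a leaf width on this machine).
    sad:
        Source-to-axis distance, cm.
    """

    top_pairs: int = 34
    bottom_pairs: int = 35
    leaf_width_iso: float = 0.83
    stack_offset: float = 0.415
    sad: float = 90.0

    def __post_init__(self) -> None:
        if self.top_pairs < 1 or self.bottom_pairs < 1:
            raise ValidationError("leaf pair counts must be positive")
        if self.leaf_width_iso <= 0 or self.sad <= 0:
            raise ValidationError("all lengths must be positive")

    # Inline extents (cm).  Both stacks are centered on the inline axis;
    # the half-leaf stagger means their edges differ by stack_offset.
    @property
    def bottom_inline_low(self) -> float:
        return -0.5 * self.bottom_pairs * self.leaf_width_iso

    @property
    def top_inline_low(self) -> float:
        return -0.5 * self.top_pairs * self.leaf_width_iso


def default_geometry() -> MLCGeometry:
    """MRIdian-style defaults: 34/35 pairs, 0.83 cm leaves, 0.415 cm offset,
    SAD 90 cm."""
    return MLCGeometry()


@dataclass
class Segment:
    """One static step-and-shoot aperture with its monitor units.

    Leaf-tip positions are signed crossline coordinates in cm at
    isocenter; a pair is open iff ``left < right``.  Overtravel across
    x = 0 is legal (both tips may share a sign).
    """

    gantry_deg: float
    mu: float
    top_left: np.ndarray
    top_right: np.ndarray
    bottom_left: np.ndarray
    bottom_right: np.ndarray

    def __post_init__(self) -> None:
        self.gantry_deg = float(self.gantry_deg) % 360.0
        self.mu = float(self.mu)
        if self.mu < 0:
            raise ValidationError("segment MU must be >= 0")
        for name in ("top_left", "top_right", "bottom_left", "bottom_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate_against(self, geometry: MLCGeometry) -> None:
        for name, n in (
            ("top_left", geometry.top_pairs),
            ("top_right", geometry.top_pairs),
            ("bottom_left", geometry.bottom_pairs),
            ("bottom_right", geometry.bottom_pairs),
        ):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise GeometryMismatchError(
                    f"{name} has length {arr.shape}, expected ({n},)"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite positions")


@dataclass
class Plan:
    """An ordered sequence of segments delivered with one MLC geometry."""

    plan_id: str
    segments: list
    geometry: MLCGeometry = field(default_factory=default_geometry)

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValidationError("a plan needs at least one segment")
        for seg in self.segments:
            seg.validate_against(self.geometry)
        if sum(s.mu for s in self.segments) <= 0:
            raise ValidationError("total MU must be positive")

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def total_mu(plan: Plan) -> float:
    """Cumulative monitor units of a plan."""
    return float(sum(s.mu for s in plan.segments))


@dataclass
class Grid3D:
    """A scalar volume (dose in Gy or relative, or CT numbers in HU).

    ``values[ix, iy, iz]`` with ``spacing = (dx, dy, dz)`` mm and
    ``origin`` the center of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError("Grid3D values must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be strictly positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates along one axis, mm."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_grid_as(self, other: "Grid3D", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def copy(self) -> "Grid3D":
        return Grid3D(self.values.copy(), self.spacing, self.origin)


@dataclass
class ApertureImage:
    """Binary beam's-eye-view image of an aperture.

    Rows are inline bins at the composite pitch (0.415 cm, half a leaf
    width); columns are crossline bins at 0.01 cm.  ``row_origin`` /
    ``col_origin`` give the low edge of bin 0 in cm.
    """

    mask: np.ndarray
    row_origin: float
    col_origin: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("aperture mask must be 2D")
        self.row_origin = float(self.row_origin)
        self.col_origin = float(self.col_origin)

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    def same_grid_as(self, other: "ApertureImage", tol: float = 1e-9) -> bool:
        return (
            self.mask.shape == other.mask.shape
            and abs(self.row_origin - other.row_origin) <= tol
            and abs(self.col_origin - other.col_origin) <= tol
        )


@dataclass
class GammaResult:
    """Outcome of a 3D gamma comparison.

    ``gamma`` holds the per-voxel gamma index (NaN outside the evaluated
    mask); ``gpr_percent`` is the percentage of evaluated voxels with
    gamma <= 1; ``mean_gamma`` the mean over evaluated voxels.
    """

    gamma: Grid3D
    evaluated_mask: Grid3D
    gpr_percent: float
    mean_gamma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gpr_percent <= 100.0):
            raise ValidationError("gpr_percent outside [0, 100]")
        if self.mean_gamma < 0:
            raise ValidationError("mean_gamma must be >= 0")


#: Canonical metric names, in report order.
METRIC_NAMES = (
    "Cumulative area",
    "Cumulative perimeter",
    "Perimeter-to-area ratio",
    "Edge metric",
    "Number of active MLC pairs",
    "ALPO",
    "LSV",
    "AAV",
    "MCS",
    "Aperture irregularity",
    "Unique opening index",
    "Cross-axis score",
    "Small aperture score 5 mm",
    "Small aperture score 10 mm",
    "Small aperture score 20 mm",
    "MAD",
    "LTI",
    "LTIMCS",
    "Number of segments",
    "MUs per segment",
    "Total MUs",
    "THI",
    "DWTHI",
)

#: Units for each metric ("" for dimensionless).
METRIC_UNITS: Mapping[str, str] = {
    "Cumulative area": "cm^2",
    "Cumulative perimeter": "cm",
    "Perimeter-to-area ratio": "1/cm",
    "Edge metric": "cm",
    "Number of active MLC pairs": "",
    "ALPO": "cm",
    "LSV": "",
    "AAV": "",
    "MCS": "",
    "Aperture irregularity": "",
    "Unique opening index": "",
    "Cross-axis score": "",
    "Small aperture score 5 mm": "",
    "Small aperture score 10 mm": "",
    "Small aperture score 20 mm": "",
    "MAD": "cm",
    "LTI": "",
    "LTIMCS": "",
    "Number of segments": "",
    "MUs per segment": "MU",
    "Total MUs": "MU",
    "THI": "HU/mm",
    "DWTHI": "HU/mm",
}


@dataclass
class MetricReport:
    """Named complexity-metric values for one plan.

    ``metrics`` maps each of the 23 canonical metric names to a
    ``(value, units)`` tuple.  THI/DWTHI are NaN when no CT/dose volume
    was supplied.
    """

    plan_id: str
    metrics: dict

    def __post_init__(self) -> None:
        missing = [n for n in METRIC_NAMES if n not in self.metrics]
        extra = [n for n in self.metrics if n not in METRIC_NAMES]
        if missing or extra:
            raise ValidationError(
                f"metric report must contain exactly the canonical names; "
                f"missing={missing}, unexpected={extra}"
            )

    def value(self, name: str) -> float:
        return self.metrics[name][0]

    def as_dict(self) -> dict:
        return {name: self.metrics[name][0] for name in METRIC_NAMES}
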