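"""Seeded synthetic fixtures: plans, HU phantoms and dose-grid pairs.

Clinical delivery logs, CT series and dose grids are patient data and
cannot ship with the package, so every other module is exercised against
generated stand-ins with known ground truth:

* multi-segment step-and-shoot plans with rectangular, random-contiguous
  or multi-hole apertures and realistic MU scales (cohort-scale plans
  default to 77 segments and ~46 MU per segment);
* HU phantoms — uniform, water/lung/water slab, or a linear HU ramp whose
  gradient (and hence THI) is analytic;
* paired dose grids on the treatment-planning voxel size (2 x 3 x 2 mm)
  where the evaluated copy carries engineered cubic perturbations whose
  gamma fail mask is computed by the exhaustive oracle at generation
  time.

Generation is a pure function of the :class:`FixtureSpec` (same spec and
seed give bit-identical fixtures).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import Grid3D, MLCGeometry, Plan, Segment, ValidationError, default_geometry
from .gamma import GammaCriteria, gamma_volume_exhaustive

__all__ = ["FixtureSpec", "make_plan", "make_phantom", "make_dose_pair"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture.

    ``perturbations`` lists ``(center_mm, half_width_mm, amplitude)``
    cubic dose perturbations, with amplitude a fraction of the maximum
    reference dose; ``None`` draws a random set, ``()`` disables them.
    """

    seed: int = 0
    # --- plan ---
    n_segments: int = 77
    aperture_style: str = "random-contiguous"  # rectangle | random-contiguous | multi-hole
    mu_mean: float = 46.5
    mu_sigma: float = 0.5  # log-scale sd of the lognormal MU draw
    # --- phantom ---
    phantom_style: str = "uniform"  # uniform | slab | ramp
    hu_value: float = 0.0
    hu_slope: float = 10.0  # HU/mm along x for the ramp style
    water_hu: float = 0.0
    lung_hu: float = -700.0
    # --- grids ---
    grid_shape: Tuple[int, int, int] = (20, 20, 20)
    grid_spacing: Tuple[float, float, float] = (2.0, 3.0, 2.0)
    # --- dose pair ---
    dose_style: str = "gaussian-blob"  # uniform | gaussian-blob
    blob_sigma_mm: float = 10.0
    perturbations: Optional[Sequence] = None
    noise_sigma: float = 0.0  # i.i.d. Gaussian noise, fraction of max dose


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    # Independent deterministic stream per fixture kind (crc32 keeps the
    # sub-seed platform- and process-independent, unlike hash()).
    return np.random.default_rng([spec.seed, zlib.crc32(stream.encode()) % (2**31)])


def _centered_origin(spec: FixtureSpec) -> Tuple[float, float, float]:
    return tuple(
        -0.5 * (n - 1) * s for n, s in zip(spec.grid_shape, spec.grid_spacing)
    )


def _draw_mus(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    # Lognormal with the requested arithmetic mean.
    mu_log = np.log(spec.mu_mean) - 0.5 * spec.mu_sigma**2
    return rng.lognormal(mu_log, spec.mu_sigma, size=spec.n_segments)


def _segment_from_rows(
    geom: MLCGeometry, row_lo: int, row_hi: int, left: np.ndarray, right: np.ndarray,
    gantry: float, mu: float, n_rows: int
) -> Segment:
    """Build a segment whose composite rows [row_lo, row_hi) open the
    per-row intervals (left, right); both stacks open the union of their
    rows' targets, so each pair stays contiguous."""
    tl = np.zeros(geom.top_pairs)
    tr = np.zeros(geom.top_pairs)
    bl = np.zeros(geom.bottom_pairs)
    br = np.zeros(geom.bottom_pairs)
    row_left = np.zeros(n_rows)
    row_right = np.zeros(n_rows)
    row_left[row_lo:row_hi] = left
    row_right[row_lo:row_hi] = right
    open_rows = np.zeros(n_rows, dtype=bool)
    open_rows[row_lo:row_hi] = right > left
    # bottom pair b covers rows (2b, 2b+1); top pair t covers rows (1+2t, 2+2t)
    for b in range(geom.bottom_pairs):
        rows = [r for r in (2 * b, 2 * b + 1) if r < n_rows and open_rows[r]]
        if rows:
            bl[b] = min(row_left[r] for r in rows)
            br[b] = max(row_right[r] for r in rows)
    for t in range(geom.top_pairs):
        rows = [r for r in (1 + 2 * t, 2 + 2 * t) if r < n_rows and open_rows[r]]
        if rows:
            tl[t] = min(row_left[r] for r in rows)
            tr[t] = max(row_right[r] for r in rows)
    return Segment(gantry, mu, tl, tr, bl, br)


def make_plan(spec: FixtureSpec, geometry: MLCGeometry | None = None) -> Plan:
    """Generate a synthetic step-and-shoot plan.

    Styles: ``rectangle`` (identical per-row intervals), ``random-
    contiguous`` (per-row intervals following a bounded random walk) and
    ``multi-hole`` (alternating row bands opening two disjoint crossline
    regions, giving non-contiguous composite apertures).
    """
    if spec.n_segments < 1:
        raise ValidationError("n_segments must be >= 1")
    geom = geometry or default_geometry()
    n_rows = int(round(geom.bottom_pairs * geom.leaf_width_iso / 0.415))
    rng = _rng(spec, "plan")
    mus = _draw_mus(rng, spec)
    gantries = np.sort(rng.uniform(0.0, 360.0, size=spec.n_segments))

    segments = []
    for s in range(spec.n_segments):
        if spec.aperture_style == "rectangle":
            half = rng.uniform(2.0, 5.0)
            center = rng.uniform(-1.0, 1.0)
            band = rng.integers(8, 21)
            row_lo = int(rng.integers(10, n_rows - 10 - band))
            left = np.full(band, center - half)
            right = np.full(band, center + half)
        elif spec.aperture_style == "random-contiguous":
            band = int(rng.integers(6, 25))
            row_lo = int(rng.integers(5, n_rows - 5 - band))
            centers = np.cumsum(rng.normal(0.0, 0.4, size=band)) + rng.uniform(-2, 2)
            gaps = rng.uniform(0.5, 6.0, size=band)
            left = centers - gaps / 2
            right = centers + gaps / 2
        elif spec.aperture_style == "multi-hole":
            band = int(rng.integers(8, 16)) * 2
            row_lo = int(rng.integers(5, n_rows - 5 - band))
            gaps = rng.uniform(1.0, 3.0, size=band)
            # alternating bands of 4 rows around two disjoint regions
            offset = np.where((np.arange(band) // 4) % 2 == 0, -4.0, 4.0)
            left = offset - gaps / 2
            right = offset + gaps / 2
        else:
            raise ValidationError(f"unknown aperture style {spec.aperture_style!r}")
        segments.append(
            _segment_from_rows(
                geom, row_lo, row_lo + len(left), left, right,
                gantries[s], mus[s], n_rows
            )
        )
    return Plan(f"synthetic-{spec.aperture_style}-{spec.seed}", segments, geom)


def make_phantom(spec: FixtureSpec) -> Grid3D:
    """HU phantom: uniform, water/lung/water slab (thirds along z), or a
    linear ramp ``HU = hu_slope * x_mm``."""
    shape = spec.grid_shape
    origin = _centered_origin(spec)
    if spec.phantom_style == "uniform":
        vals = np.full(shape, spec.hu_value, dtype=float)
    elif spec.phantom_style == "slab":
        vals = np.full(shape, spec.water_hu, dtype=float)
        nz = shape[2]
        vals[:, :, nz // 3 : 2 * nz // 3] = spec.lung_hu
    elif spec.phantom_style == "ramp":
        x = origin[0] + spec.grid_spacing[0] * np.arange(shape[0])
        vals = np.broadcast_to(
            (spec.hu_slope * x)[:, None, None], shape
        ).astype(float).copy()
    else:
        raise ValidationError(f"unknown phantom style {spec.phantom_style!r}")
    return Grid3D(vals, spec.grid_spacing, origin)


def _reference_dose(spec: FixtureSpec, rng: np.random.Generator) -> Grid3D:
    origin = _centered_origin(spec)
    if spec.dose_style == "uniform":
        vals = np.ones(spec.grid_shape, dtype=float)
    elif spec.dose_style == "gaussian-blob":
        coords = np.meshgrid(
            *(
                origin[a] + spec.grid_spacing[a] * np.arange(spec.grid_shape[a])
                for a in range(3)
            ),
            indexing="ij",
        )
        center = rng.uniform(-4.0, 4.0, size=3)
        sigma = spec.blob_sigma_mm * rng.uniform(0.8, 1.2)
        r2 = sum((c - mu) ** 2 for c, mu in zip(coords, center))
        vals = np.exp(-r2 / (2.0 * sigma**2))
    else:
        raise ValidationError(f"unknown dose style {spec.dose_style!r}")
    return Grid3D(vals, spec.grid_spacing, origin)


def _apply_cube(grid: Grid3D, center_mm, half_width_mm: float, amount: float) -> None:
    sel = []
    for ax in range(3):
        coords = grid.axis_coords(ax)
        lo, hi = center_mm[ax] - half_width_mm, center_mm[ax] + half_width_mm
        if center_mm[ax] < coords[0] - 1e-9 or center_mm[ax] > coords[-1] + 1e-9:
            raise ValidationError("perturbation blob center outside the dose grid")
        sel.append((coords >= lo) & (coords <= hi))
    grid.values[np.ix_(sel[0], sel[1], sel[2])] += amount


def make_dose_pair(
    spec: FixtureSpec,
    criteria: GammaCriteria | None = None,
    compute_fail_mask: bool = True,
):
    """Reference/evaluated dose pair with engineered disagreement.

    Returns ``(reference, evaluated, expected_fail_mask)``.  The fail
    mask (gamma > 1 under ``criteria``, evaluated by the exhaustive
    brute-force oracle) is the ground truth that the fast gamma chain
    must reproduce; pass ``compute_fail_mask=False`` to skip the oracle
    and get ``None`` in its place.
    """
    rng = _rng(spec, "dose")
    reference = _reference_dose(spec, rng)
    evaluated = reference.copy()
    ref_max = float(np.max(reference.values))

    perturbations = spec.perturbations
    if perturbations is None:
        k = int(rng.integers(1, 4))
        perturbations = [
            (
                tuple(rng.uniform(-8.0, 8.0, size=3)),
                float(rng.uniform(3.0, 8.0)),
                float(rng.uniform(-0.06, 0.06)),
            )
            for _ in range(k)
        ]
    for center, half_width, amplitude in perturbations:
        _apply_cube(evaluated, center, half_width, amplitude * ref_max)
    if spec.noise_sigma > 0:
        evaluated.values += rng.normal(
            0.0, spec.noise_sigma * ref_max, size=evaluated.values.shape
        )

    fail_mask = None
    if compute_fail_mask:
        res = gamma_volume_exhaustive(reference, evaluated, criteria or GammaCriteria())
        fail_mask = Grid3D(
            np.nan_to_num(res.gamma.values, nan=0.0) > 1.0,
            reference.spacing,
            reference.origin,
        )
    return reference, evaluated, fail_mask
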