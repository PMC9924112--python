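"""3D gamma-index QA between a planned and a recomputed dose distribution.

The comparison chain mirrors standard log-file QA practice for
Monte-Carlo-recomputed dose: a 3x3x3 median filter suppresses stochastic
noise in the recomputed volume, the planned (reference) distribution is
resampled onto the recomputed grid, and a global 3%/3 mm gamma analysis
with a 10% low-dose threshold yields the gamma pass rate (GPR) and mean
gamma.

The gamma index of reference voxel i is (Low et al.)

    gamma_i = min_p sqrt( (D_e(p) - D_r(i))^2 / (dd * D_norm)^2
                          + |r_i - p|^2 / dta^2 )

minimized over evaluated-dose positions p, with D_norm the maximum
reference dose for global normalization.  The minimization samples a
dense displacement grid (pitch ``interp_step * dta``) within a sphere of
radius ``search_radius_factor * dta``, interpolating the evaluated dose
trilinearly.  Two implementations are provided:

* the fast path visits displacements sorted by radius and stops as soon
  as the spatial term alone exceeds the current best gamma (an exact
  pruning, not an approximation);
* :func:`gamma_volume_exhaustive` scans every candidate with an
  independently written trilinear interpolation and no pruning — the
  brute-force oracle used for verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import GammaResult, Grid3D, ValidationError

__all__ = [
    "GammaCriteria",
    "median_filter_3x3x3",
    "resample_to",
    "gamma_volume",
    "gamma_volume_exhaustive",
    "qa_compare",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma comparison parameters.

    dose_tol: dose-difference tolerance as a fraction of the
        normalization dose (0.03 = 3%).
    dta: distance-to-agreement tolerance, mm.
    threshold: low-dose cutoff as a fraction of the maximum reference
        dose; voxels below it are not evaluated.
    norm: 'global' (normalize dose differences to max reference dose) or
        'local' (to the voxel's own reference dose).
    search_radius_factor: search-sphere radius in multiples of dta.
    interp_step: displacement-grid pitch as a fraction of dta.
    """

    dose_tol: float = 0.03
    dta: float = 3.0
    threshold: float = 0.10
    norm: str = "global"
    search_radius_factor: float = 3.0
    interp_step: float = 0.1

    def __post_init__(self) -> None:
        if self.dose_tol <= 0 or self.dta <= 0:
            raise ValidationError("dose_tol and dta must be positive")
        if not (0.0 <= self.threshold < 1.0):
            raise ValidationError("threshold must be in [0, 1)")
        if self.norm not in ("global", "local"):
            raise ValidationError("norm must be 'global' or 'local'")
        if self.search_radius_factor <= 0 or self.interp_step <= 0:
            raise ValidationError("search parameters must be positive")


def median_filter_3x3x3(dose: Grid3D) -> Grid3D:
    """Voxelwise median of the 27-neighborhood; border voxels use the
    truncated neighborhood that fits inside the volume."""
    if any(n < 3 for n in dose.values.shape):
        raise ValidationError("median filter needs >= 3 voxels per axis")
    padded = np.pad(dose.values.astype(float), 1, constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3, 3))
    filtered = np.nanmedian(windows, axis=(3, 4, 5))
    return Grid3D(filtered, dose.spacing, dose.origin)


def resample_to(dose: Grid3D, target: Grid3D) -> Grid3D:
    """Trilinear resampling of ``dose`` onto ``target``'s voxel centers.

    Target voxels outside the dose extent are set to 0 (and fall below
    any dose threshold downstream).  Identical grids short-circuit to a
    copy so that resampling is bit-exact in that case.
    """
    if dose.same_grid_as(target):
        return Grid3D(dose.values.astype(float).copy(), target.spacing, target.origin)
    for ax in range(3):
        lo_d, hi_d = dose.axis_coords(ax)[0], dose.axis_coords(ax)[-1]
        lo_t, hi_t = target.axis_coords(ax)[0], target.axis_coords(ax)[-1]
        if hi_d < lo_t or hi_t < lo_d:
            raise ValidationError("dose and target grids do not overlap")
    interp = RegularGridInterpolator(
        tuple(dose.axis_coords(ax) for ax in range(3)),
        dose.values.astype(float),
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    xs, ys, zs = (target.axis_coords(ax) for ax in range(3))
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    vals = interp(pts.reshape(-1, 3)).reshape(target.values.shape)
    return Grid3D(vals, target.spacing, target.origin)


def _displacements(criteria: GammaCriteria, sort: bool) -> tuple[np.ndarray, np.ndarray]:
    """Displacement sample grid (mm) within the search sphere."""
    pitch = criteria.interp_step * criteria.dta
    radius = criteria.search_radius_factor * criteria.dta
    m = int(math.floor(radius / pitch + 1e-9))
    ax = np.arange(-m, m + 1) * pitch
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    disp = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    norm = np.sqrt((disp**2).sum(axis=1))
    keep = norm <= radius + 1e-9
    disp, norm = disp[keep], norm[keep]
    if sort:
        order = np.argsort(norm, kind="stable")
        disp, norm = disp[order], norm[order]
    return np.ascontiguousarray(disp), np.ascontiguousarray(norm)


@numba.njit(cache=False)
def _gamma_fast_kernel(pts, ref_dose, ev, ev_origin, ev_spacing, disp, disp_norm,
                       dose_denom, dta):
    """Radius-sorted displacement search with exact spatial-term pruning."""
    n = pts.shape[0]
    nx, ny, nz = ev.shape
    out = np.empty(n)
    for i in range(n):
        best = np.inf
        for m in range(disp.shape[0]):
            sp = disp_norm[m] / dta
            if sp >= best:
                break  # sorted by radius: no later candidate can improve
            fx = (pts[i, 0] + disp[m, 0] - ev_origin[0]) / ev_spacing[0]
            fy = (pts[i, 1] + disp[m, 1] - ev_origin[1]) / ev_spacing[1]
            fz = (pts[i, 2] + disp[m, 2] - ev_origin[2]) / ev_spacing[2]
            if fx < 0.0 or fx > nx - 1 or fy < 0.0 or fy > ny - 1 or fz < 0.0 or fz > nz - 1:
                continue
            ix = min(int(fx), nx - 2) if nx > 1 else 0
            iy = min(int(fy), ny - 2) if ny > 1 else 0
            iz = min(int(fz), nz - 2) if nz > 1 else 0
            wx, wy, wz = fx - ix, fy - iy, fz - iz
            c00 = ev[ix, iy, iz] * (1 - wx) + ev[ix + 1, iy, iz] * wx
            c10 = ev[ix, iy + 1, iz] * (1 - wx) + ev[ix + 1, iy + 1, iz] * wx
            c01 = ev[ix, iy, iz + 1] * (1 - wx) + ev[ix + 1, iy, iz + 1] * wx
            c11 = ev[ix, iy + 1, iz + 1] * (1 - wx) + ev[ix + 1, iy + 1, iz + 1] * wx
            val = (c00 * (1 - wy) + c10 * wy) * (1 - wz) + (
                c01 * (1 - wy) + c11 * wy
            ) * wz
            dd = (val - ref_dose[i]) / dose_denom[i]
            g = math.sqrt(dd * dd + sp * sp)
            if g < best:
                best = g
        out[i] = best
    return out


@numba.njit(cache=False)
def _gamma_exhaustive_kernel(pts, ref_dose, ev, ev_origin, ev_spacing, disp,
                             disp_norm, dose_denom, dta):
    """Plain full scan of every displacement candidate (no sort, no pruning);
    trilinear interpolation written as an explicit corner loop."""
    n = pts.shape[0]
    nx, ny, nz = ev.shape
    out = np.empty(n)
    for i in range(n):
        best2 = np.inf
        for m in range(disp.shape[0]):
            fx = (pts[i, 0] + disp[m, 0] - ev_origin[0]) / ev_spacing[0]
            fy = (pts[i, 1] + disp[m, 1] - ev_origin[1]) / ev_spacing[1]
            fz = (pts[i, 2] + disp[m, 2] - ev_origin[2]) / ev_spacing[2]
            if fx < 0.0 or fx > nx - 1 or fy < 0.0 or fy > ny - 1 or fz < 0.0 or fz > nz - 1:
                continue
            ix = min(int(fx), nx - 2) if nx > 1 else 0
            iy = min(int(fy), ny - 2) if ny > 1 else 0
            iz = min(int(fz), nz - 2) if nz > 1 else 0
            val = 0.0
            for a in range(2):
                for b in range(2):
                    for c in range(2):
                        w = (
                            (1.0 - abs(fx - ix - a))
                            * (1.0 - abs(fy - iy - b))
                            * (1.0 - abs(fz - iz - c))
                        )
                        val += w * ev[ix + a, iy + b, iz + c]
            dd = (val - ref_dose[i]) / dose_denom[i]
            sp = disp_norm[m] / dta
            g2 = dd * dd + sp * sp
            if g2 < best2:
                best2 = g2
        out[i] = math.sqrt(best2)
    return out


def _gamma_run(reference: Grid3D, evaluated: Grid3D, criteria: GammaCriteria,
               exhaustive: bool) -> GammaResult:
    ref = reference.values.astype(float)
    ref_max = float(np.max(ref))
    if ref_max <= 0:
        raise ValidationError("reference dose has no positive values")
    mask = ref >= criteria.threshold * ref_max

    # Only voxels whose own position lies inside the evaluated extent can
    # be compared (the zero-displacement candidate must exist).
    coords = np.meshgrid(*(reference.axis_coords(a) for a in range(3)), indexing="ij")
    inside = np.ones_like(mask)
    for ax in range(3):
        lo = evaluated.axis_coords(ax)[0] - 1e-9
        hi = evaluated.axis_coords(ax)[-1] + 1e-9
        inside &= (coords[ax] >= lo) & (coords[ax] <= hi)
    mask &= inside
    if not mask.any():
        raise ValidationError("no voxels above threshold inside the evaluated extent")

    pts = np.stack([c[mask] for c in coords], axis=1).astype(float)
    ref_dose = ref[mask]
    if criteria.norm == "global":
        denom = np.full(ref_dose.shape, criteria.dose_tol * ref_max)
    else:
        denom = criteria.dose_tol * ref_dose
    disp, norm = _displacements(criteria, sort=not exhaustive)
    kernel = _gamma_exhaustive_kernel if exhaustive else _gamma_fast_kernel
    g = kernel(
        pts,
        ref_dose,
        np.ascontiguousarray(evaluated.values.astype(float)),
        np.array([evaluated.axis_coords(a)[0] for a in range(3)]),
        np.array(evaluated.spacing, dtype=float),
        disp,
        norm,
        denom,
        criteria.dta,
    )
    gamma_vol = np.full(ref.shape, np.nan)
    gamma_vol[mask] = g
    return GammaResult(
        gamma=Grid3D(gamma_vol, reference.spacing, reference.origin),
        evaluated_mask=Grid3D(mask, reference.spacing, reference.origin),
        gpr_percent=100.0 * float(np.mean(g <= 1.0)),
        mean_gamma=float(np.mean(g)),
    )


def gamma_volume(
    reference: Grid3D, evaluated: Grid3D, criteria: GammaCriteria | None = None
) -> GammaResult:
    """3D gamma of ``evaluated`` against ``reference`` (fast search).

    The threshold mask and voxel positions are defined on the reference
    grid; the evaluated distribution may live on its own (e.g. finer)
    grid and is interpolated trilinearly.
    """
    return _gamma_run(reference, evaluated, criteria or GammaCriteria(), False)


def gamma_volume_exhaustive(
    reference: Grid3D, evaluated: Grid3D, criteria: GammaCriteria | None = None
) -> GammaResult:
    """Brute-force gamma (dense scan, no pruning) — the testing oracle."""
    return _gamma_run(reference, evaluated, criteria or GammaCriteria(), True)


def qa_compare(
    planned: Grid3D,
    recomputed: Grid3D,
    criteria: GammaCriteria | None = None,
    median_filter: bool = True,
    relative: bool = True,
) -> GammaResult:
    """Full QA chain: median-filter the recomputed (noisy) dose, resample
    the planned dose onto its grid, and run gamma with planned as
    reference.

    With ``relative=True`` (default) both distributions are normalized by
    their own maxima before comparison, so a global output-scale
    difference does not register as disagreement; pass ``False`` to
    compare absolute dose.
    """
    criteria = criteria or GammaCriteria()
    ev = median_filter_3x3x3(recomputed) if median_filter else recomputed
    ref = resample_to(planned, ev)
    if relative:
        ref_max = float(np.max(ref.values))
        ev_max = float(np.max(ev.values))
        if ref_max <= 0 or ev_max <= 0:
            raise ValidationError("relative normalization needs positive doses")
        ref = Grid3D(ref.values / ref_max, ref.spacing, ref.origin)
        ev = Grid3D(ev.values / ev_max, ev.spacing, ev.origin)
    return gamma_volume(ref, ev, criteria)
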