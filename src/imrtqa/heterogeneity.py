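"""Tissue-heterogeneity complexity indices THI and DWTHI.

On a 0.35 T MR-linac the electron return effect concentrates dose
perturbations at interfaces between media of different density, so the
amount of tissue heterogeneity inside the irradiated volume is itself a
plan-complexity driver.  The tissue heterogeneity index (THI) sums the
spatial gradient magnitude of the CT Hounsfield units over all voxels
receiving more than a threshold fraction (default 10%) of the maximum
dose; the dose-weighted variant (DWTHI) weights each voxel's gradient by
its relative dose:

    THI   = sum_{D_rel > t} |grad HU|            [HU/mm]
    DWTHI = sum_{D_rel > t} D_rel * |grad HU|    [HU/mm]

Gradients are central differences over the physical voxel spacing
(one-sided at volume borders), exact for linearly varying HU.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .core import Grid3D, ValidationError

__all__ = ["hu_gradient_magnitude", "dose_threshold_mask", "thi", "dwthi"]


def hu_gradient_magnitude(ct: Grid3D) -> Grid3D:
    """Per-voxel magnitude of the HU spatial gradient, HU/mm."""
    if any(s <= 0 for s in ct.spacing):
        raise ValidationError("CT spacing must be strictly positive")
    gx, gy, gz = np.gradient(ct.values.astype(float), *ct.spacing)
    mag = np.sqrt(gx * gx + gy * gy + gz * gz)
    return Grid3D(mag, ct.spacing, ct.origin)


def dose_threshold_mask(
    ct: Grid3D, dose: Grid3D, threshold: float = 0.10
) -> np.ndarray:
    """Boolean mask on the CT grid of voxels with D_rel strictly above
    ``threshold``.

    The dose is trilinearly resampled onto the CT grid when the grids
    differ; CT voxels outside the dose extent count as zero dose.
    """
    if np.max(dose.values) <= 0:
        raise ValidationError("dose has no positive values: threshold undefined")
    if dose.same_grid_as(ct):
        d = dose.values
    else:
        from .gamma import resample_to

        d = resample_to(dose, ct).values
    d_rel = d / np.max(dose.values)
    return d_rel > threshold


def thi(ct: Grid3D, dose: Grid3D, threshold: float = 0.10) -> float:
    """Tissue heterogeneity index: summed |grad HU| over the above-threshold
    dose region, HU/mm."""
    mask = dose_threshold_mask(ct, dose, threshold)
    g = hu_gradient_magnitude(ct).values
    return float(g[mask].sum())


def dwthi(ct: Grid3D, dose: Grid3D, threshold: float = 0.10) -> float:
    """Dose-weighted tissue heterogeneity index, HU/mm."""
    if np.max(dose.values) <= 0:
        raise ValidationError("dose has no positive values: threshold undefined")
    if dose.same_grid_as(ct):
        d = dose.values
    else:
        from .gamma import resample_to

        d = resample_to(dose, ct).values
    d_rel = d / np.max(dose.values)
    mask = d_rel > threshold
    g = hu_gradient_magnitude(ct).values
    return float((d_rel[mask] * g[mask]).sum())


def masked_voxel_count(ct: Grid3D, dose: Grid3D, threshold: float = 0.10) -> int:
    """Number of CT voxels above the relative-dose threshold."""
    return int(dose_threshold_mask(ct, dose, threshold).sum())
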