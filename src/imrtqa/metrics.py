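"""Plan complexity metrics from composite aperture images.

Twenty-one aperture/MU/motion metrics are computed per plan, following
the modulation-complexity literature (McNiven's MCS and its LSV/AAV
factors, Crowe's aperture irregularity, small-aperture scores, leaf
travel, edge metric, ...), plus the two tissue-heterogeneity indices
(THI/DWTHI) delegated to :mod:`imrtqa.heterogeneity`.

Conventions
-----------
* "Leaf positions" are the outermost open pixel edges of each 0.415 cm
  composite row (effective leaf pairs of the dual-stacked machine).
* Per-plan aggregation weights each segment by its MU fraction
  ``w_s = MU_s / sum(MU)``; counting metrics (unique opening index,
  number of active pairs, segment/MU totals) are plain sums.
* ``MAD`` measures displacement of row midpoints from the segment's mean
  midpoint, which makes it invariant under crossline translation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .core import (
    METRIC_NAMES,
    METRIC_UNITS,
    Grid3D,
    MetricReport,
    Plan,
    ValidationError,
    total_mu,
)
from .raster import area_perimeter, connected_openings, rasterize_composite, row_profile

__all__ = [
    "SegmentFeatures",
    "segment_features",
    "aperture_size_metrics",
    "aperture_shape_metrics",
    "leaf_opening_metrics",
    "motion_metrics",
    "mu_metrics",
    "full_report",
]


@dataclass
class SegmentFeatures:
    """Geometric features of one segment's composite aperture."""

    area: float
    perimeter: float
    side_perimeter: float
    tip_perimeter: float
    components: int
    n_active_rows: int
    active_rows: np.ndarray  # composite row indices with any opening
    left: np.ndarray  # outermost left edges per active row, cm
    right: np.ndarray  # outermost right edges per active row, cm
    gaps: np.ndarray  # right - left per active row, cm
    mu: float


def segment_features(plan: Plan) -> List[SegmentFeatures]:
    """Rasterize every segment and extract per-segment aperture features."""
    feats = []
    for seg in plan.segments:
        img = rasterize_composite(seg, plan.geometry)
        area, perim, side, tip = area_perimeter(img)
        profiles = [p for p in row_profile(img) if p.active]
        feats.append(
            SegmentFeatures(
                area=area,
                perimeter=perim,
                side_perimeter=side,
                tip_perimeter=tip,
                components=connected_openings(img),
                n_active_rows=len(profiles),
                active_rows=np.array([p.row for p in profiles], dtype=int),
                left=np.array([p.left for p in profiles]),
                right=np.array([p.right for p in profiles]),
                gaps=np.array([p.gap for p in profiles]),
                mu=seg.mu,
            )
        )
    return feats


def _mu_weights(feats: List[SegmentFeatures]) -> np.ndarray:
    mu = np.array([f.mu for f in feats])
    tot = mu.sum()
    if tot <= 0:
        raise ValidationError("total MU must be positive")
    return mu / tot


def _require_open(feats: List[SegmentFeatures]) -> None:
    if all(f.n_active_rows == 0 for f in feats):
        raise ValidationError("plan has no open segment")


def aperture_size_metrics(
    plan: Plan, feats: Optional[List[SegmentFeatures]] = None
) -> Dict[str, float]:
    """MU-weighted aperture area/perimeter metrics.

    ``edge_metric`` is the MU-weighted side-edge perimeter (leaf-side
    exposure excluding the leaf-tip faces), reported in cm.
    """
    feats = segment_features(plan) if feats is None else feats
    w = _mu_weights(feats)
    area = float(np.dot(w, [f.area for f in feats]))
    perim = float(np.dot(w, [f.perimeter for f in feats]))
    if area <= 0:
        raise ValidationError("all segments closed: perimeter-to-area undefined")
    return {
        "cumulative_area": area,
        "cumulative_perimeter": perim,
        "perimeter_to_area": perim / area,
        "edge_metric": float(np.dot(w, [f.side_perimeter for f in feats])),
    }


def _lsv_one_side(x: np.ndarray) -> float:
    """Leaf-sequence variability of one bank's positions over active rows.

    1 when all positions coincide (pos_max = 0) or a single row is active.
    """
    n = x.size
    if n <= 1:
        return 1.0
    pos_max = float(x.max() - x.min())
    if pos_max == 0.0:
        return 1.0
    return float(np.sum(pos_max - np.abs(np.diff(x))) / ((n - 1) * pos_max))


def aperture_shape_metrics(
    plan: Plan, feats: Optional[List[SegmentFeatures]] = None
) -> Dict[str, float]:
    """Shape-variability metrics: LSV, AAV, MCS, aperture irregularity,
    unique opening index and active-pair count.

    AAV normalizes each segment's summed row gaps by the per-row maximum
    gap across all segments of the plan (union rows), so AAV <= 1.
    """
    feats = segment_features(plan) if feats is None else feats
    _require_open(feats)
    w = _mu_weights(feats)

    # Per-row maximum gap over all segments (rows indexed on the composite grid).
    max_gap: Dict[int, float] = {}
    for f in feats:
        for r, g in zip(f.active_rows, f.gaps):
            max_gap[r] = max(max_gap.get(int(r), 0.0), float(g))
    denom = sum(max_gap.values())

    lsv_s = np.empty(len(feats))
    aav_s = np.empty(len(feats))
    ai_s = np.empty(len(feats))
    for i, f in enumerate(feats):
        lsv_s[i] = _lsv_one_side(f.left) * _lsv_one_side(f.right)
        aav_s[i] = f.gaps.sum() / denom if denom > 0 else 1.0
        ai_s[i] = (
            f.perimeter**2 / (4.0 * math.pi * f.area) if f.area > 0 else np.nan
        )
    # Closed segments carry no aperture shape; they contribute LSV/AAV/AI
    # through their (typically zero-area) features only if open.
    open_mask = np.array([f.n_active_rows > 0 for f in feats])
    if not open_mask.all():
        lsv_s[~open_mask] = 1.0
        aav_s[~open_mask] = 0.0
        ai_s[~open_mask] = 0.0

    return {
        "lsv": float(np.dot(w, lsv_s)),
        "aav": float(np.dot(w, aav_s)),
        "mcs": float(np.dot(w, lsv_s * aav_s)),
        "aperture_irregularity": float(np.dot(w, ai_s)),
        "unique_opening_index": int(sum(f.components for f in feats)),
        "n_active_pairs": int(sum(f.n_active_rows for f in feats)),
    }


def leaf_opening_metrics(
    plan: Plan, feats: Optional[List[SegmentFeatures]] = None
) -> Dict[str, float]:
    """Opening-distance metrics: ALPO, small-aperture scores (5/10/20 mm),
    cross-axis score and mean aperture displacement (MAD).

    Fractions (SAS, cross-axis) are computed per segment over its active
    rows and then MU-weighted across segments.
    """
    feats = segment_features(plan) if feats is None else feats
    _require_open(feats)
    w = _mu_weights(feats)

    alpo = np.zeros(len(feats))
    sas = {0.5: np.zeros(len(feats)), 1.0: np.zeros(len(feats)), 2.0: np.zeros(len(feats))}
    cross = np.zeros(len(feats))
    mad = np.zeros(len(feats))
    for i, f in enumerate(feats):
        if f.n_active_rows == 0:
            continue
        alpo[i] = f.gaps.mean()
        for d_cm in sas:
            sas[d_cm][i] = np.mean(f.gaps < d_cm)
        cross[i] = np.mean((f.left > 0) | (f.right < 0))
        mid = (f.left + f.right) / 2.0
        mad[i] = np.mean(np.abs(mid - mid.mean()))
    return {
        "alpo": float(np.dot(w, alpo)),
        "sas5": float(np.dot(w, sas[0.5])),
        "sas10": float(np.dot(w, sas[1.0])),
        "sas20": float(np.dot(w, sas[2.0])),
        "cross_axis_score": float(np.dot(w, cross)),
        "mad": float(np.dot(w, mad)),
    }


def motion_metrics(
    plan: Plan, feats: Optional[List[SegmentFeatures]] = None
) -> Dict[str, float]:
    """Leaf-travel metrics: LTI (mean per-leaf travel / 100 cm) and
    LTIMCS = (1 - LTI/10) * MCS.

    Travel of composite row r on side L/R is summed over consecutive
    segment pairs in which the row is active in both; rows parked in
    either segment of a pair contribute no transition.
    """
    feats = segment_features(plan) if feats is None else feats
    mcs = aperture_shape_metrics(plan, feats)["mcs"]

    travel: Dict[tuple, float] = {}
    for a, b in zip(feats[:-1], feats[1:]):
        pos_a = {int(r): (l, rt) for r, l, rt in zip(a.active_rows, a.left, a.right)}
        pos_b = {int(r): (l, rt) for r, l, rt in zip(b.active_rows, b.left, b.right)}
        for r in pos_a.keys() & pos_b.keys():
            for side in (0, 1):
                key = (r, side)
                travel[key] = travel.get(key, 0.0) + abs(
                    pos_b[r][side] - pos_a[r][side]
                )
    lti = float(np.mean([t / 100.0 for t in travel.values()])) if travel else 0.0
    return {"lti": lti, "ltimcs": (1.0 - lti / 10.0) * mcs}


def mu_metrics(plan: Plan) -> Dict[str, float]:
    """Segment and MU totals: segment count, mean MU per segment, total MU."""
    s = len(plan.segments)
    tot = total_mu(plan)
    return {"n_segments": s, "mu_per_segment": tot / s, "total_mu": tot}


def full_report(
    plan: Plan,
    ct: Optional[Grid3D] = None,
    dose: Optional[Grid3D] = None,
    dose_threshold: float = 0.10,
) -> MetricReport:
    """All 23 complexity metrics for one plan.

    THI/DWTHI need a CT volume and a dose distribution; when either is
    missing they are reported as NaN with a warning.
    """
    feats = segment_features(plan)
    vals: Dict[str, float] = {}
    size = aperture_size_metrics(plan, feats)
    shape = aperture_shape_metrics(plan, feats)
    opening = leaf_opening_metrics(plan, feats)
    motion = motion_metrics(plan, feats)
    mus = mu_metrics(plan)

    vals["Cumulative area"] = size["cumulative_area"]
    vals["Cumulative perimeter"] = size["cumulative_perimeter"]
    vals["Perimeter-to-area ratio"] = size["perimeter_to_area"]
    vals["Edge metric"] = size["edge_metric"]
    vals["Number of active MLC pairs"] = shape["n_active_pairs"]
    vals["ALPO"] = opening["alpo"]
    vals["LSV"] = shape["lsv"]
    vals["AAV"] = shape["aav"]
    vals["MCS"] = shape["mcs"]
    vals["Aperture irregularity"] = shape["aperture_irregularity"]
    vals["Unique opening index"] = shape["unique_opening_index"]
    vals["Cross-axis score"] = opening["cross_axis_score"]
    vals["Small aperture score 5 mm"] = opening["sas5"]
    vals["Small aperture score 10 mm"] = opening["sas10"]
    vals["Small aperture score 20 mm"] = opening["sas20"]
    vals["MAD"] = opening["mad"]
    vals["LTI"] = motion["lti"]
    vals["LTIMCS"] = motion["ltimcs"]
    vals["Number of segments"] = mus["n_segments"]
    vals["MUs per segment"] = mus["mu_per_segment"]
    vals["Total MUs"] = mus["total_mu"]

    if ct is not None and dose is not None:
        from .heterogeneity import dwthi, thi

        vals["THI"] = thi(ct, dose, threshold=dose_threshold)
        vals["DWTHI"] = dwthi(ct, dose, threshold=dose_threshold)
    else:
        warnings.warn(
            "CT and/or dose volume missing: THI and DWTHI reported as NaN",
            stacklevel=2,
        )
        vals["THI"] = float("nan")
        vals["DWTHI"] = float("nan")

    return MetricReport(
        plan_id=plan.plan_id,
        metrics={name: (vals[name], METRIC_UNITS[name]) for name in METRIC_NAMES},
    )
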