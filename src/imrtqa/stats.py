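"""Pearson correlation of complexity metrics against gamma pass rates.

For a cohort of plans, each complexity metric is correlated with the
per-plan GPR using the sample Pearson coefficient; the two-sided p-value
comes from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
Correlations with p at or below the significance cutoff (default 0.01)
are flagged, and |r| is labelled weak (< 0.5), moderate (0.5-0.7) or
strong (> 0.7).  No multiple-testing correction is applied by default;
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats as sps

from .core import METRIC_NAMES, MetricReport, ValidationError

__all__ = ["CorrelationRow", "pearson", "correlation_table", "strength_label"]


@dataclass
class CorrelationRow:
    metric: str
    r: float
    p: float
    significant: bool
    strength: str
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t distribution, n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1D sequences")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def strength_label(r: float) -> str:
    """Weak |r| < 0.5, moderate 0.5 <= |r| <= 0.7, strong |r| > 0.7."""
    a = abs(r)
    if a > 0.7:
        return "strong"
    if a >= 0.5:
        return "moderate"
    return "weak"


def correlation_table(
    reports: List[MetricReport],
    gprs: Sequence[float],
    alpha: float = 0.01,
    bh_correction: bool = False,
) -> List[CorrelationRow]:
    """One correlation row per metric, in canonical metric order.

    Metrics with non-finite values in any plan (e.g. THI/DWTHI computed
    without a CT) are dropped with a warning.  ``bh_correction`` applies
    Benjamini-Hochberg to the p-values before flagging significance.
    """
    if len(reports) != len(gprs):
        raise ValidationError("reports and gprs must have matching length")
    if len(reports) < 3:
        raise ValidationError("need at least 3 plans")
    g = np.asarray(gprs, dtype=float)

    rows: List[CorrelationRow] = []
    for name in METRIC_NAMES:
        vals = np.array([rep.value(name) for rep in reports], dtype=float)
        if not np.all(np.isfinite(vals)):
            warnings.warn(f"metric {name!r} has non-finite values; dropped",
                          stacklevel=2)
            continue
        if np.std(vals) == 0:
            warnings.warn(f"metric {name!r} is constant across plans; dropped",
                          stacklevel=2)
            continue
        r, p = pearson(vals, g)
        rows.append(CorrelationRow(name, r, p, False, strength_label(r), len(g)))

    pvals = np.array([row.p for row in rows])
    if bh_correction and len(pvals):
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            k = m - rank_from_end
            running = min(running, pvals[idx] * m / k)
            adj[idx] = running
        pvals = adj
    for row, p in zip(rows, pvals):
        row.significant = bool(p <= alpha)
    return rows
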