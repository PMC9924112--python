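"""Independent straightforward recomputation of the aperture/MU metrics
from raw composite masks, written as plain Python loops.

This is the verification oracle for the metrics module: it shares only
the rasterizer (which has its own pixel-level oracles) and re-derives
every per-segment feature and every plan-level aggregate from first
principles, so agreement is meaningful.
"""

import math

from imrtqa import Plan
from imrtqa.raster import rasterize_composite

DX = 0.01
DY = 0.415
PIX_AREA = DX * DY


def mask_features(mask, col_origin):
    """Area, perimeters, components and per-row outermost edges by
    exhaustive pixel/edge scanning."""
    n_rows, n_cols = mask.shape
    area = 0
    tip = 0.0
    side = 0.0
    rows = {}
    for r in range(n_rows):
        if not mask[r].any():
            continue
        first = last = None
        for c in range(n_cols):
            if not mask[r, c]:
                continue
            area += 1
            if first is None:
                first = c
            last = c
            # exposed edges: crossline neighbours share a tip face (0.415),
            # inline neighbours a side face (0.01)
            if c == 0 or not mask[r, c - 1]:
                tip += DY
            if c == n_cols - 1 or not mask[r, c + 1]:
                tip += DY
            if r == 0 or not mask[r - 1, c]:
                side += DX
            if r == n_rows - 1 or not mask[r + 1, c]:
                side += DX
        if first is not None:
            left = col_origin + DX * first
            right = col_origin + DX * (last + 1)
            rows[r] = (left, right)
    return {
        "area": area * PIX_AREA,
        "tip": tip,
        "side": side,
        "perimeter": tip + side,
        "components": flood_fill_components(mask),
        "rows": rows,  # row index -> (outermost left, outermost right) cm
    }


def flood_fill_components(mask):
    """4-connected component count by iterative flood fill."""
    n_rows, n_cols = mask.shape
    seen = [[False] * n_cols for _ in range(n_rows)]
    count = 0
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if not mask[r0, c0] or seen[r0][c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0][c0] = True
            while stack:
                r, c = stack.pop()
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if (
                        0 <= rr < n_rows and 0 <= cc < n_cols
                        and mask[rr, cc] and not seen[rr][cc]
                    ):
                        seen[rr][cc] = True
                        stack.append((rr, cc))
    return count


def _lsv_side(xs):
    n = len(xs)
    if n <= 1:
        return 1.0
    pos_max = max(xs) - min(xs)
    if pos_max == 0:
        return 1.0
    total = 0.0
    for a, b in zip(xs[:-1], xs[1:]):
        total += pos_max - abs(a - b)
    return total / ((n - 1) * pos_max)


def bruteforce_metrics(plan: Plan):
    """The 21 aperture/MU metrics recomputed with explicit loops."""
    feats = []
    for seg in plan.segments:
        img = rasterize_composite(seg, plan.geometry)
        f = mask_features(img.mask, img.col_origin)
        f["mu"] = seg.mu
        feats.append(f)
    tot_mu = sum(f["mu"] for f in feats)
    w = [f["mu"] / tot_mu for f in feats]

    def wsum(vals):
        return sum(wi * v for wi, v in zip(w, vals))

    areas = [f["area"] for f in feats]
    perims = [f["perimeter"] for f in feats]
    cum_area = wsum(areas)
    cum_perim = wsum(perims)

    # per-row maximum gap across segments
    max_gap = {}
    for f in feats:
        for r, (l, rt) in f["rows"].items():
            max_gap[r] = max(max_gap.get(r, 0.0), rt - l)
    denom = sum(max_gap.values())

    lsv_s, aav_s, ai_s = [], [], []
    alpo_s, sas_s, cross_s, mad_s = [], {0.5: [], 1.0: [], 2.0: []}, [], []
    for f in feats:
        order = sorted(f["rows"])
        lefts = [f["rows"][r][0] for r in order]
        rights = [f["rows"][r][1] for r in order]
        gaps = [rt - l for l, rt in zip(lefts, rights)]
        lsv_s.append(_lsv_side(lefts) * _lsv_side(rights))
        aav_s.append(sum(gaps) / denom)
        ai_s.append(f["perimeter"] ** 2 / (4 * math.pi * f["area"]))
        alpo_s.append(sum(gaps) / len(gaps))
        for d in sas_s:
            sas_s[d].append(sum(1 for g in gaps if g < d) / len(gaps))
        cross_s.append(
            sum(1 for l, rt in zip(lefts, rights) if l > 0 or rt < 0) / len(gaps)
        )
        mids = [(l + rt) / 2 for l, rt in zip(lefts, rights)]
        c = sum(mids) / len(mids)
        mad_s.append(sum(abs(m - c) for m in mids) / len(mids))

    # leaf travel: per (row, side), summed over consecutive segments where
    # the row is active in both
    travels = {}
    for fa, fb in zip(feats[:-1], feats[1:]):
        for r in set(fa["rows"]) & set(fb["rows"]):
            for side in (0, 1):
                key = (r, side)
                travels[key] = travels.get(key, 0.0) + abs(
                    fb["rows"][r][side] - fa["rows"][r][side]
                )
    lti = (
        sum(t / 100.0 for t in travels.values()) / len(travels) if travels else 0.0
    )
    mcs = wsum([l * a for l, a in zip(lsv_s, aav_s)])

    n_seg = len(feats)
    return {
        "Cumulative area": cum_area,
        "Cumulative perimeter": cum_perim,
        "Perimeter-to-area ratio": cum_perim / cum_area,
        "Edge metric": wsum([f["side"] for f in feats]),
        "Number of active MLC pairs": sum(len(f["rows"]) for f in feats),
        "ALPO": wsum(alpo_s),
        "LSV": wsum(lsv_s),
        "AAV": wsum(aav_s),
        "MCS": mcs,
        "Aperture irregularity": wsum(ai_s),
        "Unique opening index": sum(f["components"] for f in feats),
        "Cross-axis score": wsum(cross_s),
        "Small aperture score 5 mm": wsum(sas_s[0.5]),
        "Small aperture score 10 mm": wsum(sas_s[1.0]),
        "Small aperture score 20 mm": wsum(sas_s[2.0]),
        "MAD": wsum(mad_s),
        "LTI": lti,
        "LTIMCS": (1 - lti / 10.0) * mcs,
        "Number of segments": n_seg,
        "MUs per segment": tot_mu / n_seg,
        "Total MUs": tot_mu,
    }
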