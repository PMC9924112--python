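"""Shared builders for synthetic segments, plans and volumes."""

import numpy as np
import pytest

from imrtqa import MLCGeometry, Plan, Segment, default_geometry


def segment_all_pairs(left: float, right: float, mu: float = 10.0,
                      gantry: float = 0.0,
                      geometry: MLCGeometry | None = None) -> Segment:
    """Segment with every pair of both stacks open at (left, right); the
    composite is a full-height rectangle (rows covered by both stacks)."""
    g = geometry or default_geometry()
    return Segment(
        gantry, mu,
        np.full(g.top_pairs, left), np.full(g.top_pairs, right),
        np.full(g.bottom_pairs, left), np.full(g.bottom_pairs, right),
    )


def closed_segment(mu: float = 10.0, geometry: MLCGeometry | None = None) -> Segment:
    g = geometry or default_geometry()
    return Segment(
        0.0, mu,
        np.zeros(g.top_pairs), np.zeros(g.top_pairs),
        np.zeros(g.bottom_pairs), np.zeros(g.bottom_pairs),
    )


def rect_plan(left: float = -1.0, right: float = 1.0, mu: float = 10.0,
              n_segments: int = 1, plan_id: str = "rect") -> Plan:
    segs = [segment_all_pairs(left, right, mu=mu) for _ in range(n_segments)]
    return Plan(plan_id, segs)


@pytest.fixture
def geometry() -> MLCGeometry:
    return default_geometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
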