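"""Tissue growth maps from segment-level morphometry.

Local growth between two developmental stages is measured on a panel of
landmark segments (the ratio of each segment's length at the later stage to
the earlier one).  A per-pixel growth map is then interpolated by
inverse-squared-distance weighting of the segment growth factors:

    growth(pixel) = sum_i f_i / d_i^2  /  sum_i 1 / d_i^2

where d_i is the Euclidean distance from the pixel to segment i.  Distances
are floored at 0.5 px so the weights stay finite; a pixel on a segment
therefore takes (essentially) that segment's factor.  Growth maps can be
scored against a raster mask of pattern occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Segment",
    "GrowthMap",
    "segment_growth_factors",
    "interpolate_growth_map",
    "region_growth_contrast",
    "segments_from_frame",
]

#: Distance floor (pixels) that regularizes the 1/d^2 weights on segments.
DISTANCE_EPS = 0.5


@dataclass(frozen=True)
class Segment:
    """A landmark segment with its growth factor (length ratio, later/earlier)."""

    segment_id: str
    p1: tuple[float, float]
    p2: tuple[float, float]
    growth_factor: float

    def __post_init__(self):
        if self.p1 == self.p2:
            raise ValueError(f"segment {self.segment_id}: endpoints must be distinct")
        if not self.growth_factor > 0:
            raise ValueError(f"segment {self.segment_id}: growth factor must be positive")


@dataclass(frozen=True)
class GrowthMap:
    values: np.ndarray
    segments: tuple[Segment, ...]


def segment_growth_factors(
    lengths_stage_a: pd.Series | dict,
    lengths_stage_b: pd.Series | dict,
) -> pd.Series:
    """Per-segment growth factor length_b / length_a, indexed by segment id.

    Both tables must cover the same segment identifiers with positive
    lengths; violations are reported naming the offending segment.
    """
    sa = pd.Series(lengths_stage_a, dtype=float)
    sb = pd.Series(lengths_stage_b, dtype=float)
    missing = sorted(set(sa.index).symmetric_difference(sb.index))
    if missing:
        raise ValueError(f"segments missing from one stage: {missing}")
    for name, s in (("first", sa), ("second", sb)):
        bad = sorted(s.index[(s <= 0) | s.isna()])
        if bad:
            raise ValueError(f"non-positive or missing length in {name} stage for segments: {bad}")
    return (sb / sa).rename("growth_factor")


def _point_segment_distance(yy, xx, p1, x2=None):
    """Euclidean distance from grid points to a line segment."""
    (y1, x1), (y2, x2) = p1 if x2 is None else (p1, x2)
    dy, dx = y2 - y1, x2 - x1
    norm2 = dy * dy + dx * dx
    t = ((yy - y1) * dy + (xx - x1) * dx) / norm2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (y1 + t * dy), xx - (x1 + t * dx))


def interpolate_growth_map(segments: list[Segment], shape: tuple[int, int]) -> GrowthMap:
    """Inverse-squared-distance interpolation of segment growth factors.

    Every pixel value is a weighted mean of the segment factors and is thus
    bounded by their range; the map is linear in the factors.
    """
    if not segments:
        raise ValueError("need at least one segment")
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    num = np.zeros(shape)
    den = np.zeros(shape)
    for seg in segments:
        dist = _point_segment_distance(yy, xx, seg.p1, seg.p2)
        wgt = 1.0 / np.maximum(dist, DISTANCE_EPS) ** 2
        num += seg.growth_factor * wgt
        den += wgt
    return GrowthMap(values=num / den, segments=tuple(segments))


def region_growth_contrast(growth_map: GrowthMap | np.ndarray, mask: np.ndarray) -> dict:
    """Compare growth inside vs outside an occurrence mask.

    Returns mean growth inside and outside the mask, their ratio and the
    point-biserial correlation between growth value and mask membership.
    A degenerate (empty or full) mask yields NaN ratio/correlation plus a
    ``degenerate`` flag rather than an exception.
    """
    values = growth_map.values if isinstance(growth_map, GrowthMap) else np.asarray(growth_map, float)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != values.shape:
        raise ValueError("mask and map shapes differ")
    inside = values[mask]
    outside = values[~mask]
    report = {
        "mean_inside": float(inside.mean()) if inside.size else float("nan"),
        "mean_outside": float(outside.mean()) if outside.size else float("nan"),
        "degenerate": bool(inside.size == 0 or outside.size == 0),
    }
    if report["degenerate"]:
        report["ratio"] = float("nan")
        report["correlation"] = float("nan")
        return report
    report["ratio"] = report["mean_inside"] / report["mean_outside"]
    if values.std() == 0:
        report["correlation"] = 0.0
    else:
        report["correlation"] = float(stats.pointbiserialr(mask.ravel().astype(int), values.ravel())[0])
    return report


def segments_from_frame(df: pd.DataFrame) -> list[Segment]:
    """Build segments from a table with columns id, x1, y1, x2, y2 and either
    growth_factor or the two stage lengths (length_stage_a, length_stage_b)."""
    required = {"id", "x1", "y1", "x2", "y2"}
    if not required.issubset(df.columns):
        raise ValueError(f"segment table must have columns {sorted(required)}")
    if "growth_factor" in df.columns:
        factors = df["growth_factor"]
    elif {"length_stage_a", "length_stage_b"}.issubset(df.columns):
        factors = segment_growth_factors(
            df.set_index("id")["length_stage_a"], df.set_index("id")["length_stage_b"]
        ).loc[df["id"]].to_numpy()
    else:
        raise ValueError("need growth_factor or length_stage_a/length_stage_b columns")
    return [
        Segment(str(row.id), (float(row.y1), float(row.x1)), (float(row.y2), float(row.x2)), float(f))
        for row, f in zip(df.itertuples(), factors)
    ]
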