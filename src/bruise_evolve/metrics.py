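"""Scalar damage measurements from binary masks.

Converts zone/damage masks into the quantities tracked over time: zone
depth below the skin surface and zone width (with the discontinuity rule:
the zone centre of a column is the midpoint of its two furthest segment
boundaries, the width is the summed segment length), plus the damage
extents toward the core and the pericarp measured from the frame-1 zone
centre.  All geometry is 0-based with half-open row intervals; depth grows
with row index (core direction positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


class MeasurementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Surface detection
# ---------------------------------------------------------------------------

def surface_profile(
    frame_or_mask: np.ndarray, tissue_value_max: int = 220
) -> np.ndarray:
    """Per-column row of the skin surface (first tissue row from the top).

    Accepts either a boolean tissue mask or an RGB frame, in which case
    tissue is any pixel whose value (max RGB) falls below
    ``tissue_value_max`` — tissue is darker than the bright slide
    background.  Columns without tissue are linearly interpolated from
    their neighbours.
    """
    arr = np.asarray(frame_or_mask)
    if arr.ndim == 3:
        tissue = arr.max(axis=-1) < tissue_value_max
    elif arr.ndim == 2:
        tissue = arr.astype(bool)
    else:
        raise InputError("expected a 2-D mask or an RGB frame")
    if not tissue.any():
        raise InputError("no tissue found in the image")
    has = tissue.any(axis=0)
    first = tissue.argmax(axis=0).astype(float)
    cols = np.arange(tissue.shape[1])
    if not has.all():
        first = np.interp(cols, cols[has], first[has])
    return first


# ---------------------------------------------------------------------------
# Column rule
# ---------------------------------------------------------------------------

@dataclass
class ColumnScan:
    """Ordered zone segments of one image column along the depth axis.

    ``segments`` are half-open row intervals [start, end); the boundary
    coordinates of the discontinuity rule are start of the first segment
    and end of the last one.
    """

    column: int
    segments: list[tuple[int, int]]
    surface_row: float

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.segments:
            if not (prev_end < s < e):
                raise InputError("segments must be strictly interleaved")
            prev_end = e


def column_segments(col_pixels: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True pixels along one column."""
    col = np.asarray(col_pixels, dtype=bool)
    padded = np.concatenate([[False], col, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def column_measurements(
    scan: ColumnScan, pixel_scale: float
) -> tuple[float, float] | None:
    """(depth mm, width mm) of one column scan, or None without segments.

    Centre = midpoint of the two furthest boundaries; depth = (centre -
    surface row) * scale; width = summed segment length * scale.
    """
    if not scan.segments:
        return None
    first = scan.segments[0][0]
    last = scan.segments[-1][1]
    center = (first + last) / 2.0
    depth = (center - scan.surface_row) * pixel_scale
    width = sum(e - s for s, e in scan.segments) * pixel_scale
    return depth, width


def _mask_scans(mask: np.ndarray, surface: np.ndarray) -> list[ColumnScan]:
    mask = np.asarray(mask, dtype=bool)
    return [
        ColumnScan(column=c, segments=column_segments(mask[:, c]),
                   surface_row=float(surface[c]))
        for c in range(mask.shape[1])
    ]


def zone_summary(
    mask: np.ndarray, surface: np.ndarray, pixel_scale: float
) -> tuple[float, float]:
    """Mean (depth mm, width mm) over all columns with at least one segment."""
    if not np.asarray(mask, dtype=bool).any():
        raise MeasurementError("empty zone mask")
    vals = [
        m
        for scan in _mask_scans(mask, surface)
        if (m := column_measurements(scan, pixel_scale)) is not None
    ]
    depths, widths = zip(*vals)
    return float(np.mean(depths)), float(np.mean(widths))


def zone_center_row(mask: np.ndarray) -> float:
    """Mean zone-centre row over nonempty columns (reference for extents)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MeasurementError("empty zone mask")
    centers = []
    for c in range(mask.shape[1]):
        segs = column_segments(mask[:, c])
        if segs:
            centers.append((segs[0][0] + segs[-1][1]) / 2.0)
    return float(np.mean(centers))


def damage_extents(
    mask: np.ndarray, reference_center_row: float, pixel_scale: float
) -> tuple[float, float]:
    """Mean (core mm, pericarp mm) extents of the damage mask.

    Per column, the core extent is the distance from the fixed reference
    centre (the frame-1 zone centre) to the damage boundary on the core
    side (last row, exclusive end), the pericarp extent the distance to the
    first damage row; both clamped at zero.  Frame values are column means
    over measurable columns.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty damage mask; extents set to zero", stacklevel=2)
        return 0.0, 0.0
    cols = np.flatnonzero(mask.any(axis=0))
    first = mask[:, cols].argmax(axis=0)
    last_end = mask.shape[0] - mask[::-1, cols].argmax(axis=0)  # exclusive
    dc = np.maximum(0.0, (last_end - reference_center_row) * pixel_scale)
    dp = np.maximum(0.0, (reference_center_row - first) * pixel_scale)
    return float(dc.mean()), float(dp.mean())


# ---------------------------------------------------------------------------
# Trace assembly
# ---------------------------------------------------------------------------

def build_trace(
    times: Sequence[float],
    zone_depths: Sequence[float],
    zone_widths: Sequence[float],
    core_extents: Sequence[float],
    pericarp_extents: Sequence[float],
    measurability_floor_mm: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-frame damage trace.

    Columns: time_min, zone_depth_mm, zone_width_mm, core_extent_mm,
    pericarp_extent_mm, total_mm, core_share, excluded.  Frames whose total
    extent falls below the measurability floor are flagged ``excluded`` and
    left out of proportion statistics (their share is noise-dominated).
    """
    lengths = {
        len(times), len(zone_depths), len(zone_widths),
        len(core_extents), len(pericarp_extents),
    }
    if len(lengths) != 1:
        raise InputError("all measurement sequences must have equal length")
    df = pd.DataFrame(
        {
            "time_min": np.asarray(times, dtype=float),
            "zone_depth_mm": np.asarray(zone_depths, dtype=float),
            "zone_width_mm": np.asarray(zone_widths, dtype=float),
            "core_extent_mm": np.asarray(core_extents, dtype=float),
            "pericarp_extent_mm": np.asarray(pericarp_extents, dtype=float),
        }
    )
    if (df[["core_extent_mm", "pericarp_extent_mm"]] < 0).any().any():
        raise InputError("extents must be non-negative")
    df["total_mm"] = df["core_extent_mm"] + df["pericarp_extent_mm"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["core_share"] = np.where(
            df["total_mm"] > 0, df["core_extent_mm"] / df["total_mm"], np.nan
        )
    df["excluded"] = df["total_mm"] < measurability_floor_mm
    return df


def measure_series(
    zone_masks: Sequence[np.ndarray],
    damage_masks: Sequence[np.ndarray],
    surface: np.ndarray,
    times: Sequence[float],
    pixel_scale: float,
    reference_center_row: float | None = None,
    measurability_floor_mm: float = 1.0,
) -> pd.DataFrame:
    """Measure a whole extracted series into a damage trace.

    The reference centre for the core/pericarp split defaults to the
    frame-1 zone centre (the zone centre drifts slightly as the core side
    grows faster, so a fixed anchor is used).
    """
    if reference_center_row is None:
        reference_center_row = zone_center_row(zone_masks[0])
    depths, widths, cores, peris = [], [], [], []
    for zone, damage in zip(zone_masks, damage_masks):
        d, w = zone_summary(zone, surface, pixel_scale)
        dc, dp = damage_extents(damage, reference_center_row, pixel_scale)
        depths.append(d)
        widths.append(w)
        cores.append(dc)
        peris.append(dp)
    return build_trace(
        times, depths, widths, cores, peris,
        measurability_floor_mm=measurability_floor_mm,
    )
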