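"""Cell-death-zone extraction from stained-section frames.

Implements the image chain used to isolate the injury signal in a trypan
blue stained section: HSV saturation channel, control-series baseline
correction of the senescence drift, tri-level thresholding into damage and
zone masks, morphological cleaning, largest connected component, hole
filling, removal of the bottom cutting band via the middle-third rectangle
rule, and width-based correction of the lateral endpoints where the zone
meets the side cutting bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology


class InputError(ValueError):
    """Raised for structurally invalid inputs (wrong shape, dtype, ...)."""


class DegenerateImageError(ValueError):
    """Raised when an operation cannot work on a constant image."""


class SegmentationError(ValueError):
    """Raised when the middle-third segmentation has nothing to work on."""


class MeasurementError(ValueError):
    """Raised when a mask is too sparse to measure."""


class RegionOverlapError(ValueError):
    """Raised (in strict mode) when the reference region overlaps damage."""


# ---------------------------------------------------------------------------
# Channel selection and baseline correction
# ---------------------------------------------------------------------------

def to_saturation_channel(frame: np.ndarray) -> np.ndarray:
    """Saturation channel of an 8-bit RGB frame, scaled to 0-255.

    Standard hexcone HSV: S = (max - min) / max (0 where max = 0).
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise InputError("expected an H x W x 3 RGB image")
    f = frame.astype(float)
    mx = f.max(axis=-1)
    mn = f.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return np.rint(255.0 * s).astype(np.uint8)


@dataclass
class CorrectionOffsets:
    """Per-frame mean-gray offsets d_1..d_n (d_1 = 0 by construction)."""

    offsets: np.ndarray                  # float, one entry per frame
    mode: str                            # "self" | "control"
    region: tuple[int, int, int, int]    # x, y, w, h in pixel coordinates

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.size == 0 or self.offsets[0] != 0.0:
            raise InputError("offset for the first frame must be 0")
        if not np.all(np.isfinite(self.offsets)):
            raise InputError("offsets must be finite")


def default_reference_region(
    shape: tuple[int, int], skin_row: int = 0, margin_px: int = 45
) -> tuple[int, int, int, int]:
    """Non-marginal reference box: the frame inset by ``margin_px`` on the
    sides/bottom and below the skin surface."""
    h, w = shape
    x0, x1 = margin_px, w - margin_px
    y0, y1 = max(skin_row, margin_px // 2) + margin_px // 3, h - margin_px
    if x1 <= x0 or y1 <= y0:
        raise InputError("image too small for the default reference region")
    return (x0, y0, x1 - x0, y1 - y0)


def _region_mean(gray: np.ndarray, region: tuple[int, int, int, int]) -> float:
    x, y, w, h = region
    if x < 0 or y < 0 or x + w > gray.shape[1] or y + h > gray.shape[0]:
        raise InputError("reference region lies outside the image")
    return float(gray[y : y + h, x : x + w].mean())


def compute_offsets(
    gray_frames: Sequence[np.ndarray],
    region: tuple[int, int, int, int],
    mode: str = "control",
    damage_estimate: np.ndarray | None = None,
    strict: bool = False,
) -> CorrectionOffsets:
    """Baseline offsets d_i = mean(region, frame i) - mean(region, frame 1).

    ``mode='control'`` computes the offsets on the paired control (C) series
    for application to the injury (T) frames; ``mode='self'`` uses the T
    series itself, in which case the region must avoid the damage — pass the
    final-frame ``damage_estimate`` mask to have the overlap checked
    (warning, or :class:`RegionOverlapError` when ``strict``).
    """
    if mode not in ("control", "self"):
        raise InputError("mode must be 'control' or 'self'")
    if len(gray_frames) < 2:
        raise InputError("need at least two frames")
    if mode == "self" and damage_estimate is not None:
        x, y, w, h = region
        overlap = damage_estimate[y : y + h, x : x + w].mean()
        if overlap > 0.01:
            msg = (
                f"reference region overlaps the detected damage "
                f"({overlap:.1%} of its pixels)"
            )
            if strict:
                raise RegionOverlapError(msg)
            warnings.warn(msg, stacklevel=2)
    means = np.array([_region_mean(g, region) for g in gray_frames])
    return CorrectionOffsets(offsets=means - means[0], mode=mode, region=region)


def apply_correction(gray: np.ndarray, offset: float) -> np.ndarray:
    """Subtract a real-valued offset, clip to [0, 255], requantize to uint8."""
    out = np.clip(np.asarray(gray, dtype=float) - offset, 0.0, 255.0)
    return np.rint(out).astype(np.uint8)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def three_class_otsu_thresholds(gray: np.ndarray) -> tuple[int, int]:
    """Threshold pair (t1, t2) maximizing the between-class variance of the
    three classes ``g <= t1``, ``t1 < g <= t2`` and ``g > t2``.

    Exhaustive, exact search over all integer pairs on the 0-255 histogram
    (vectorized); ties resolved toward the smallest (t1, t2).
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel().astype(np.uint8), minlength=256).astype(float)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image cannot be thresholded")
    p = hist / total
    levels = np.arange(256, dtype=float)
    cw = np.concatenate([[0.0], np.cumsum(p)])          # cumulative weight
    cm = np.concatenate([[0.0], np.cumsum(p * levels)])  # cumulative mass

    def seg_stats(a, b):
        """weight and mean of levels in (a, b], exclusive-inclusive."""
        w = cw[b + 1] - cw[a + 1]
        m = cm[b + 1] - cm[a + 1]
        return w, m

    t1 = np.arange(256)[:, None]   # (256, 1)
    t2 = np.arange(256)[None, :]   # (1, 256)
    w0, m0 = seg_stats(np.full_like(t1, -1), np.broadcast_to(t1, (256, 256)))
    w1, m1 = seg_stats(np.broadcast_to(t1, (256, 256)), np.broadcast_to(t2, (256, 256)))
    w2, m2 = seg_stats(np.broadcast_to(t2, (256, 256)), np.full_like(t2 + t1, 255))
    mu = cm[256]
    with np.errstate(invalid="ignore", divide="ignore"):
        var_b = (
            np.where(w0 > 0, (m0 - w0 * mu) ** 2 / w0, 0.0)
            + np.where(w1 > 0, (m1 - w1 * mu) ** 2 / w1, 0.0)
            + np.where(w2 > 0, (m2 - w2 * mu) ** 2 / w2, 0.0)
        )
    var_b = np.where(t1 < t2, var_b, -np.inf)
    best = int(np.argmax(var_b))     # first maximum -> smallest (t1, t2)
    return best // 256, best % 256


def binarize_three_class(
    gray: np.ndarray, thresholds: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Split a gray image into damage and zone masks.

    Returns ``(damage, zone, (t1, t2))`` with ``damage = gray > t1``
    (stained tissue of any intensity) and ``zone = gray > t2`` (the densely
    stained cell death zone); ``zone`` is a subset of ``damage`` by
    construction.  Thresholds default to the tri-level Otsu of ``gray``.
    """
    gray = np.asarray(gray)
    if thresholds is None:
        thresholds = three_class_otsu_thresholds(gray)
    t1, t2 = thresholds
    if not t1 < t2:
        raise InputError("thresholds must satisfy t1 < t2")
    damage = gray > t1
    zone = gray > t2
    return damage, zone, (int(t1), int(t2))


# ---------------------------------------------------------------------------
# Mask post-processing
# ---------------------------------------------------------------------------

def morphological_clean(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Opening followed by closing with a disc structuring element.

    Removes speckle smaller than the disc, then seals small gaps; the
    composite is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask.copy()
    footprint = morphology.disk(radius)
    out = morphology.opening(mask, footprint)
    return morphology.closing(out, footprint)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component.

    Size ties are broken toward the component whose first pixel comes
    earliest in row-major order.  Empty input stays empty.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best_size = counts.max()
    tied = np.flatnonzero(counts == best_size)
    if len(tied) == 1:
        keep = tied[0]
    else:
        flat = labels.ravel()
        first = {lab: np.flatnonzero(flat == lab)[0] for lab in tied}
        keep = min(tied, key=lambda lab: first[lab])
    return labels == keep


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def segment_middle_third(
    mask: np.ndarray, min_extent_frac: float = 0.5
) -> np.ndarray:
    """Cut off the bottom cutting-artifact band using the middle third.

    Within the middle third of the columns, the band of interest and the
    bottom artifact band appear as two separate components; their smallest
    enclosing rectangles are computed and every mask pixel below the
    horizontal line midway between the upper rectangle's bottom edge and
    the lower rectangle's top edge is erased.  With fewer than two wide
    candidates (``min_extent_frac`` of the middle-third columns) the mask
    is returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    c0, c1 = w // 3, 2 * w // 3
    sub = mask[:, c0:c1]
    if not sub.any():
        raise SegmentationError("middle third of the image is empty")
    labels, n = measure.label(sub, connectivity=2, return_num=True)
    if n < 2:
        return mask.copy()
    rects = []  # (min_row, max_row_inclusive, col_extent)
    for region in measure.regionprops(labels):
        r0, _, r1, _ = region.bbox
        cols = np.unique(region.coords[:, 1])
        rects.append((r0, r1 - 1, len(cols)))
    wide = [r for r in rects if r[2] >= min_extent_frac * (c1 - c0)]
    if len(wide) < 2:
        return mask.copy()
    wide.sort(key=lambda r: -r[2])
    top_two = sorted(wide[:2], key=lambda r: r[0])
    upper, lower = top_two
    cut = (upper[1] + lower[0]) // 2
    out = mask.copy()
    out[cut + 1 :, :] = False
    return out


def correct_endpoints(
    mask: np.ndarray,
    max_width_factor: float = 2.0,
    min_interior_columns: int = 10,
) -> np.ndarray:
    """Clamp band endpoints that merge into the lateral cutting bands.

    The mean band width is measured over interior columns (width at most
    twice the median, a robust proxy for columns free of side artifacts);
    any column wider than ``max_width_factor`` times that mean is replaced
    by a contiguous run of the mean width centred on the column's current
    span midpoint.
    """
    mask = np.asarray(mask, dtype=bool)
    h, _ = mask.shape
    widths = mask.sum(axis=0)
    nz = np.flatnonzero(widths)
    if len(nz) < min_interior_columns:
        raise MeasurementError(
            f"need at least {min_interior_columns} nonzero columns, got {len(nz)}"
        )
    med = np.median(widths[nz])
    interior = nz[widths[nz] <= 2.0 * med]
    if len(interior) < min_interior_columns:
        raise MeasurementError("too few interior columns to estimate the band width")
    mean_w = float(widths[interior].mean())
    out = mask.copy()
    target = max(1, int(round(mean_w)))
    for col in nz[widths[nz] > max_width_factor * mean_w]:
        rows = np.flatnonzero(mask[:, col])
        mid = (rows[0] + rows[-1]) / 2.0
        start = int(round(mid - target / 2.0))
        start = min(max(start, 0), h - target)
        out[:, col] = False
        out[start : start + target, col] = True
    return out


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class ExtractionResult:
    """Masks and provenance of one extracted series."""

    zone_masks: list[np.ndarray]
    damage_masks: list[np.ndarray]
    offsets: CorrectionOffsets
    thresholds: list[tuple[int, int]]    # per frame (identical under "global")
    settings: dict = field(default_factory=dict)


def _clean_chain(
    mask: np.ndarray, radius: int, min_object_px: int, endpoint: bool = True
) -> np.ndarray:
    out = morphological_clean(mask, radius=radius)
    if min_object_px > 0:
        out = morphology.remove_small_objects(out, min_size=min_object_px)
    out = largest_component(out)
    if not out.any():
        return out
    out = fill_holes(out)
    out = segment_middle_third(out)
    if endpoint:
        try:
            out = correct_endpoints(out)
        except MeasurementError:
            pass  # band too sparse to correct; keep as is
    return out


def extract_series(
    t_frames: Sequence[np.ndarray],
    c_frames: Sequence[np.ndarray] | None = None,
    mode: str = "control",
    reference_region: tuple[int, int, int, int] | None = None,
    skin_row: int = 0,
    threshold_policy: str = "global",
    morphology_radius: int = 2,
    min_object_px: int = 0,
    strict_region_check: bool = False,
) -> ExtractionResult:
    """Run the full extraction chain on an injury series.

    ``mode='control'`` derives the baseline offsets from the paired control
    series (required); ``mode='self'`` derives them from the injury series
    itself using a region verified against a rough final-frame damage
    estimate.  ``threshold_policy='global'`` computes the tri-level
    threshold pair on the final corrected frame and applies it to every
    frame (the series benchmark); ``'per_frame'`` rethresholds each frame.
    """
    if len(t_frames) < 2:
        raise InputError("need at least two frames")
    shapes = {f.shape for f in t_frames}
    if len(shapes) != 1:
        raise InputError("all frames must share the same dimensions")

    gray_t = [to_saturation_channel(f) for f in t_frames]
    region = reference_region or default_reference_region(
        gray_t[0].shape, skin_row=skin_row
    )

    if mode == "control":
        if c_frames is None:
            raise InputError("control mode requires the paired C series")
        if len(c_frames) != len(t_frames):
            raise InputError("T and C series must have the same length")
        gray_c = [to_saturation_channel(f) for f in c_frames]
        offsets = compute_offsets(gray_c, region, mode="control")
    elif mode == "self":
        rough, _, _ = binarize_three_class(gray_t[-1])
        offsets = compute_offsets(
            gray_t,
            region,
            mode="self",
            damage_estimate=rough,
            strict=strict_region_check,
        )
    else:
        raise InputError("mode must be 'control' or 'self'")

    corrected = [
        apply_correction(g, d) for g, d in zip(gray_t, offsets.offsets)
    ]

    if threshold_policy == "global":
        shared = three_class_otsu_thresholds(corrected[-1])
    elif threshold_policy == "per_frame":
        shared = None
    else:
        raise InputError("threshold_policy must be 'global' or 'per_frame'")

    zone_masks, damage_masks, thresholds = [], [], []
    for gray in corrected:
        damage_raw, zone_raw, thr = binarize_three_class(gray, thresholds=shared)
        damage_masks.append(
            _clean_chain(damage_raw, morphology_radius, min_object_px)
        )
        zone_masks.append(_clean_chain(zone_raw, morphology_radius, min_object_px))
        thresholds.append(thr)

    settings = {
        "mode": mode,
        "reference_region": list(region),
        "threshold_policy": threshold_policy,
        "morphology_radius": morphology_radius,
        "min_object_px": min_object_px,
    }
    return ExtractionResult(
        zone_masks=zone_masks,
        damage_masks=damage_masks,
        offsets=offsets,
        thresholds=thresholds,
        settings=settings,
    )
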