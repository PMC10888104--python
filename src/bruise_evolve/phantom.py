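"""Synthetic stained-section phantom generator.

Renders paired injury (T) and cutting-control (C) micrograph time series of
a bruised apple tissue section, together with exact ground truth, so that
the extraction/measurement/analysis chain can be exercised and scored
without any real micrographs.

The model behind the phantom
----------------------------
After an impact, a banded fracture region of concentrated dead cells (the
cell death zone) sits at a fixed depth below the skin.  Damaged tissue then
spreads from the zone centre along the depth axis, asymmetrically: a share
p(t) of the total extent D(t) develops toward the core, 1 - p(t) toward the
pericarp.  D(t) follows a rescaled logistic that starts at 0, has its
maximum rate at ``rate_peak_time`` and levels off at the plateau; p(t)
oscillates gently about its mean.  Trypan blue renders dead tissue as a
high-saturation region on a pale parenchyma background, so the phantom is
built directly in the HSV saturation plane and converted to RGB.

Besides the injury signal the frames carry the two nuisance signals of real
sections: a diffuse dead-cell speckle whose density grows linearly in time
(senescence; identical realization in T and C so the control correction is
exact in expectation) and static cutting-induced bands along the sides and
bottom of the section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ConfigError, PhantomConfig


class ParameterError(ValueError):
    """Raised for invalid growth-law parameters."""


def growth_extent(t, plateau: float, t0: float, k: float):
    """Total damage extent (mm) at time ``t`` minutes.

    Rescaled logistic: ``plateau * (sigma(k (t - t0)) - sigma(-k t0)) /
    (1 - sigma(-k t0))`` with the standard logistic ``sigma``.  It is 0 at
    t = 0, strictly increasing, has its inflection (maximum rate) at ``t0``
    and approaches ``plateau`` as t grows.  Accepts scalars or arrays.
    """
    if plateau <= 0 or k <= 0:
        raise ParameterError("plateau and k must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    s0 = expit(-k * t0)
    out = plateau * (expit(k * (t - t0)) - s0) / (1.0 - s0)
    return float(out) if out.ndim == 0 else out


def core_share(t, config: PhantomConfig | None = None):
    """Core-direction share p(t) of the total damage extent.

    ``p(t) = mean + amplitude * sin(2 pi t / period)``; with the default
    parameters (0.60, 0.03, 90 min) the share stays inside [0.57, 0.63].
    """
    cfg = config if config is not None else PhantomConfig()
    t = np.asarray(t, dtype=float)
    out = cfg.proportion_mean + cfg.proportion_amplitude * np.sin(
        2.0 * np.pi * t / cfg.proportion_period
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class GroundTruth:
    """Exact per-frame truth of one rendered phantom series.

    Masks are boolean HxW grids; the trace is mask-derived (extents measured
    on the drawn pixels with the same boundary conventions the measurement
    module uses), so a perfect extractor reproduces it exactly.
    """

    zone_masks: list[np.ndarray]
    damage_masks: list[np.ndarray]
    speckle_masks: list[np.ndarray]
    bottom_artifact_mask: np.ndarray
    side_artifact_mask: np.ndarray
    trace: pd.DataFrame
    reference_center_row: float      # frame-1 zone centre (pixel row)
    surface_row: int
    realized: dict = field(default_factory=dict)  # jittered specimen parameters


@dataclass
class PhantomSeries:
    """Rendered phantom: T frames, C frames and ground truth."""

    t_frames: list[np.ndarray]
    c_frames: list[np.ndarray]
    truth: GroundTruth
    config: PhantomConfig


def saturation_to_rgb(sat: np.ndarray, value: np.ndarray) -> np.ndarray:
    """Convert a saturation plane (0-255) plus value plane to 8-bit RGB.

    Hue is fixed at the blue primary (trypan blue), for which the hexcone
    model gives R = G = V (1 - S/255), B = V.  The class saturation levels
    used by the phantom survive the 8-bit round trip exactly.
    """
    s01 = np.clip(sat, 0, 255) / 255.0
    v = value.astype(float)
    rg = np.rint(v * (1.0 - s01))
    rgb = np.stack([rg, rg, v], axis=-1)
    return rgb.astype(np.uint8)


def _specimen_params(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    """Draw the between-specimen biological variability for one series."""
    return {
        "zone_depth": cfg.zone_depth + rng.normal(0.0, cfg.depth_jitter_sd),
        "halo_total_plateau": cfg.halo_total_plateau
        * (1.0 + rng.normal(0.0, cfg.plateau_jitter_sd)),
        "zone_width_plateau": max(
            cfg.zone_width_initial,
            cfg.zone_width_plateau * (1.0 + rng.normal(0.0, cfg.width_plateau_jitter_sd)),
        ),
    }


def render_series(config: PhantomConfig) -> PhantomSeries:
    """Render the paired T/C series for one specimen.

    Deterministic given ``config.seed``; per-frame noise uses spawned
    substreams so frames are independent but reproducible.
    """
    cfg = config
    H, W = cfg.image_height_px, cfg.image_width_px
    scale = cfg.pixel_scale
    ea = cfg.edge_artifact_px

    ss = np.random.SeedSequence(cfg.seed)
    specimen_ss, speckle_ss, noise_t_ss, noise_c_ss = ss.spawn(4)
    realized = _specimen_params(cfg, np.random.default_rng(specimen_ss))
    zc_px = cfg.skin_row + realized["zone_depth"] / scale
    plateau = realized["halo_total_plateau"]
    w_plateau = realized["zone_width_plateau"]
    w0 = cfg.zone_width_initial

    times = np.asarray(cfg.times)
    d_total = growth_extent(times, plateau, cfg.rate_peak_time, cfg.growth_rate)
    gw = (
        growth_extent(times, w_plateau - w0, cfg.rate_peak_time, cfg.growth_rate)
        if w_plateau > w0
        else np.zeros_like(times)
    )
    p = core_share(times, cfg)

    # Realized geometry must fit above the bottom artifact band.
    halo_bot_max = zc_px + np.max(p * d_total) / scale
    if halo_bot_max >= H - ea - 1:
        raise ConfigError(
            "geometry overflow: plateau halo reaches the bottom artifact band; "
            "increase image_height_px or reduce halo_total_plateau"
        )

    # --- static scaffolding -------------------------------------------
    tissue = np.zeros((H, W), dtype=bool)
    tissue[cfg.skin_row :, :] = True
    value = np.where(tissue, cfg.tissue_value, cfg.slide_value).astype(float)

    # Cutting-induced bands are irregular in real sections: the left band
    # runs the full tissue height (joining the bottom band), the right one
    # stops partway down.  This irregularity matters — perfectly closed
    # artifact bands would enclose the section interior and defeat hole
    # filling, which never happens in real material.
    side_mask = np.zeros((H, W), dtype=bool)
    bottom_mask = np.zeros((H, W), dtype=bool)
    if ea > 0:
        right_end = cfg.skin_row + int(0.65 * (H - cfg.skin_row))
        side_mask[cfg.skin_row :, :ea] = True
        side_mask[cfg.skin_row : right_end, W - ea :] = True
        bottom_mask[H - ea :, :] = True

    # --- speckle field (shared between T and C) ------------------------
    area_mm2 = (H - cfg.skin_row) * W * scale * scale
    n_final = int(round(cfg.speckle_density_rate * area_mm2 * times[-1]))
    srng = np.random.default_rng(speckle_ss)
    sp_rows = srng.integers(cfg.skin_row, H, size=n_final)
    sp_cols = srng.integers(0, W, size=n_final)
    r = cfg.speckle_radius_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = yy * yy + xx * xx <= r * r
    d_off = np.argwhere(disc) - r

    def speckle_mask(n_blobs: int) -> np.ndarray:
        m = np.zeros((H, W), dtype=bool)
        if n_blobs == 0:
            return m
        rows = (sp_rows[:n_blobs, None] + d_off[None, :, 0]).ravel()
        cols = (sp_cols[:n_blobs, None] + d_off[None, :, 1]).ravel()
        ok = (rows >= cfg.skin_row) & (rows < H) & (cols >= 0) & (cols < W)
        m[rows[ok], cols[ok]] = True
        return m

    noise_t_children = noise_t_ss.spawn(cfg.n_frames)
    noise_c_children = noise_c_ss.spawn(cfg.n_frames)

    t_frames: list[np.ndarray] = []
    c_frames: list[np.ndarray] = []
    zone_masks: list[np.ndarray] = []
    damage_masks: list[np.ndarray] = []
    speckle_masks: list[np.ndarray] = []
    rows_trace: list[dict] = []
    ref_center = np.nan

    for i, t in enumerate(times):
        # zone band: grows asymmetrically, core side takes p(t) of the increment
        z_top_f = zc_px - w0 / (2 * scale) - (1.0 - p[i]) * gw[i] / scale
        z_bot_f = zc_px + w0 / (2 * scale) + p[i] * gw[i] / scale
        z_top, z_bot = int(round(z_top_f)), int(round(z_bot_f))
        z_top = max(z_top, cfg.skin_row)
        # damage halo: [centre - Dp, centre + Dc], clipped at the skin
        dc_px = p[i] * d_total[i] / scale
        dp_px = (1.0 - p[i]) * d_total[i] / scale
        h_top = max(int(round(zc_px - dp_px)), cfg.skin_row)
        h_bot = int(round(zc_px + dc_px))

        zone = np.zeros((H, W), dtype=bool)
        zone[z_top:z_bot, :] = True
        halo = np.zeros((H, W), dtype=bool)
        halo[h_top:h_bot, :] = True
        damage = zone | halo

        if i == 0:
            ref_center = (z_top + z_bot) / 2.0

        n_blobs = int(round(cfg.speckle_density_rate * area_mm2 * t))
        speck = speckle_mask(n_blobs)

        # saturation planes
        sat_c = np.full((H, W), float(cfg.saturation_background))
        sat_c[speck] = cfg.saturation_halo
        sat_t = sat_c.copy()
        sat_t[halo] = cfg.saturation_halo
        sat_t[zone] = cfg.saturation_zone
        for sat in (sat_t, sat_c):
            sat[side_mask] = cfg.saturation_zone
            sat[bottom_mask] = cfg.saturation_zone

        if cfg.noise_sd > 0:
            rng_t = np.random.default_rng(noise_t_children[i])
            rng_c = np.random.default_rng(noise_c_children[i])
            sat_t = sat_t + rng_t.normal(0.0, cfg.noise_sd, size=(H, W))
            sat_c = sat_c + rng_c.normal(0.0, cfg.noise_sd, size=(H, W))
        sat_t = np.rint(np.clip(sat_t, 0, 255))
        sat_c = np.rint(np.clip(sat_c, 0, 255))

        t_frames.append(saturation_to_rgb(sat_t, value))
        c_frames.append(saturation_to_rgb(sat_c, value))
        zone_masks.append(zone)
        damage_masks.append(damage)
        speckle_masks.append(speck)

        d_top_px = min(h_top, z_top)
        d_bot_px = max(h_bot, z_bot)
        rows_trace.append(
            {
                "time_min": float(t),
                "zone_depth_mm": ((z_top + z_bot) / 2.0 - cfg.skin_row) * scale,
                "zone_width_mm": (z_bot - z_top) * scale,
                "core_extent_mm": max(0.0, (d_bot_px - ref_center) * scale),
                "pericarp_extent_mm": max(0.0, (ref_center - d_top_px) * scale),
            }
        )

    trace = pd.DataFrame(rows_trace)
    trace["total_mm"] = trace["core_extent_mm"] + trace["pericarp_extent_mm"]
    with np.errstate(invalid="ignore", divide="ignore"):
        trace["core_share"] = np.where(
            trace["total_mm"] > 0,
            trace["core_extent_mm"] / trace["total_mm"],
            np.nan,
        )

    truth = GroundTruth(
        zone_masks=zone_masks,
        damage_masks=damage_masks,
        speckle_masks=speckle_masks,
        bottom_artifact_mask=bottom_mask,
        side_artifact_mask=side_mask,
        trace=trace,
        reference_center_row=ref_center,
        surface_row=cfg.skin_row,
        realized=realized,
    )
    return PhantomSeries(t_frames=t_frames, c_frames=c_frames, truth=truth, config=cfg)
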