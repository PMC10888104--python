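"""Configuration objects for the bruise-evolution pipeline.

Two configuration layers exist: :class:`PhantomConfig` describes one synthetic
specimen (geometry, growth law, optics, noise), and :class:`RunConfig`
describes a whole pipeline run (scenarios, seeds, extraction and analysis
settings, output paths).  Both validate eagerly so that a bad configuration
fails before any image is rendered.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


#: plateau of the total damage extent for the three impact sites, in mm.
#: Only the upper-site value is anchored to the reference condition (7.0 mm,
#: 125 mm drop); waist > upper > lower ordering reflects the observed
#: anisotropy of the fruit.
SITE_PLATEAUS = {"upper": 7.0, "waist": 7.6, "lower": 6.4}

#: drop heights (mm) of the impact-height study.
STUDY_HEIGHTS_MM = (50, 75, 100, 125, 150, 175, 200)

#: reference drop height for the plateau scaling law.
REFERENCE_HEIGHT_MM = 125.0


@dataclass
class PhantomConfig:
    """Parameters of one synthetic stained-section time series.

    Lengths are mm, times are minutes, intensities are 8-bit saturation
    levels.  The depth axis points from the skin surface toward the core:
    row index increases with depth.
    """

    image_width_px: int = 600
    image_height_px: int = 500
    pixel_scale: float = 0.02          # mm per pixel
    n_frames: int = 30
    frame_interval: float = 6.0        # minutes between frames
    skin_row: int = 25                 # row of the skin surface
    zone_depth: float = 3.0            # skin -> zone centre, mm
    zone_width_initial: float = 0.3    # mm
    zone_width_plateau: float = 1.2    # mm
    halo_total_plateau: float = 7.0    # D_inf, total damage extent at plateau, mm
    rate_peak_time: float = 30.0       # t0, minutes (logistic inflection)
    growth_rate: float = 0.11          # k, per minute
    proportion_mean: float = 0.60      # core share of the damage extent
    proportion_amplitude: float = 0.03
    proportion_period: float = 90.0    # minutes
    saturation_background: int = 40
    saturation_halo: int = 120
    saturation_zone: int = 180
    speckle_density_rate: float = 0.02  # senescence blobs per mm^2 per minute
    speckle_radius_px: int = 1
    edge_artifact_width: float = 0.4   # cutting-induced bands, mm
    noise_sd: float = 6.0              # additive Gaussian noise, gray levels
    # Between-specimen biological variability (drawn once per seed).
    depth_jitter_sd: float = 0.15      # mm
    plateau_jitter_sd: float = 0.03    # fractional, on halo_total_plateau
    width_plateau_jitter_sd: float = 0.03  # fractional, on zone_width_plateau
    # Value (brightness) channel levels used to render RGB frames.
    tissue_value: int = 160
    slide_value: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.pixel_scale <= 0:
            raise ConfigError("pixel_scale must be positive")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be at least 2")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.image_width_px < 30 or self.image_height_px < 30:
            raise ConfigError("image dimensions are implausibly small")
        if not (0 <= self.skin_row < self.image_height_px):
            raise ConfigError("skin_row outside the image")
        if not (
            0
            <= self.saturation_background
            < self.saturation_halo
            < self.saturation_zone
            <= 255
        ):
            raise ConfigError(
                "saturation levels must satisfy background < halo < zone in [0, 255]"
            )
        lo = self.proportion_mean - self.proportion_amplitude
        hi = self.proportion_mean + self.proportion_amplitude
        if not (0.5 < lo and hi < 0.7):
            raise ConfigError(
                "proportion_mean +/- proportion_amplitude must stay inside (0.5, 0.7)"
            )
        if self.proportion_period <= 0:
            raise ConfigError("proportion_period must be positive")
        for name in ("zone_width_initial", "zone_width_plateau",
                     "halo_total_plateau", "zone_depth", "rate_peak_time",
                     "growth_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.zone_width_plateau < self.zone_width_initial:
            raise ConfigError("zone_width_plateau must be >= zone_width_initial")
        if self.noise_sd < 0 or self.speckle_density_rate < 0:
            raise ConfigError("noise_sd and speckle_density_rate must be >= 0")
        if self.edge_artifact_width < 0:
            raise ConfigError("edge_artifact_width must be >= 0")
        # Nominal geometry: zone centre plus core-side plateau halo must fit
        # above the bottom edge artifact.  Realized (jittered) geometry is
        # re-checked at render time.
        core_hi = (self.proportion_mean + self.proportion_amplitude) * self.halo_total_plateau
        bottom = (
            self.skin_row
            + (self.zone_depth + core_hi) / self.pixel_scale
            + self.edge_artifact_width / self.pixel_scale
        )
        if bottom >= self.image_height_px:
            raise ConfigError(
                "zone_depth + plateau halo toward the core does not fit inside the image"
            )

    # -- helpers --------------------------------------------------------
    @property
    def times(self) -> list[float]:
        """Acquisition times in minutes (frame i at i * frame_interval)."""
        return [self.frame_interval * (i + 1) for i in range(self.n_frames)]

    @property
    def edge_artifact_px(self) -> int:
        return int(round(self.edge_artifact_width / self.pixel_scale))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PhantomConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown phantom config fields: {sorted(unknown)}")
        return cls(**data)


def _height_plateau(height_mm: float) -> float:
    """Plateau of total damage extent for a given drop height (mm).

    Monotone square-root scaling anchored at the 125 mm reference condition.
    """
    if height_mm <= 0:
        raise ConfigError("drop height must be positive")
    return SITE_PLATEAUS["upper"] * math.sqrt(height_mm / REFERENCE_HEIGHT_MM)


def scenario_config(scenario: str, seed: int = 0, **overrides: Any) -> PhantomConfig:
    """Build the :class:`PhantomConfig` for a named study scenario.

    ``scenario`` is one of ``upper``, ``waist``, ``lower`` (impact site at a
    125 mm drop) or ``height:<mm>`` (upper site, variable drop height).  The
    image is grown vertically when a large plateau would not fit the default
    frame.
    """
    base = PhantomConfig().to_dict()
    if scenario in SITE_PLATEAUS:
        plateau = SITE_PLATEAUS[scenario]
    elif scenario.startswith("height:"):
        plateau = _height_plateau(float(scenario.split(":", 1)[1]))
    else:
        raise ConfigError(
            f"unknown scenario {scenario!r}; expected upper|waist|lower|height:<mm>"
        )
    base.update(halo_total_plateau=plateau, seed=seed)
    base.update(overrides)
    cfg_probe = dict(base)
    # Vertical room: core-side plateau halo with a 15% variability buffer,
    # a 30 px clearance, and the bottom artifact band.
    scale = cfg_probe["pixel_scale"]
    p_hi = cfg_probe["proportion_mean"] + cfg_probe["proportion_amplitude"]
    needed = math.ceil(
        cfg_probe["skin_row"]
        + (cfg_probe["zone_depth"] + 1.15 * p_hi * plateau) / scale
        + 30
        + cfg_probe["edge_artifact_width"] / scale
    )
    if "image_height_px" not in overrides:
        base["image_height_px"] = max(base["image_height_px"], needed)
    return PhantomConfig.from_dict(base)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end pipeline run."""

    scenarios: list[str] = field(default_factory=lambda: ["upper"])
    seeds: list[int] = field(default_factory=lambda: [1])
    out_dir: str = "bruise_run"
    pixel_scale: float = 0.02
    write_frames: bool = False
    phantom_overrides: dict[str, Any] = field(default_factory=dict)
    # extraction settings
    correction_mode: str = "control"      # "control" | "self"
    reference_region: tuple[int, int, int, int] | None = None  # x, y, w, h
    threshold_policy: str = "global"      # "global" | "per_frame"
    morphology_radius: int = 2
    min_object_px: int = 0
    # analysis settings
    stabilization_frac: float = 0.99
    rate_grid_step: float = 0.1
    measurability_floor_mm: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.scenarios:
            raise ConfigError("at least one scenario is required")
        if not self.seeds:
            raise ConfigError("at least one seed is required")
        if self.pixel_scale is None or self.pixel_scale <= 0:
            raise ConfigError("pixel_scale must be positive")
        if self.correction_mode not in ("control", "self"):
            raise ConfigError("correction_mode must be 'control' or 'self'")
        if self.threshold_policy not in ("global", "per_frame"):
            raise ConfigError("threshold_policy must be 'global' or 'per_frame'")
        if self.morphology_radius < 0:
            raise ConfigError("morphology_radius must be >= 0")
        if not (0 < self.stabilization_frac < 1):
            raise ConfigError("stabilization_frac must lie in (0, 1)")
        if self.rate_grid_step <= 0:
            raise ConfigError("rate_grid_step must be positive")
        if self.measurability_floor_mm < 0:
            raise ConfigError("measurability_floor_mm must be >= 0")
        if self.reference_region is not None:
            x, y, w, h = self.reference_region
            if w <= 0 or h <= 0 or x < 0 or y < 0:
                raise ConfigError("reference_region must be a positive x,y,w,h box")
        for s in self.scenarios:
            if s not in SITE_PLATEAUS and not s.startswith("height:"):
                raise ConfigError(f"unknown scenario {s!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["reference_region"] is not None:
            d["reference_region"] = list(d["reference_region"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown run config fields: {sorted(unknown)}")
        if "reference_region" in data and data["reference_region"] is not None:
            data = dict(data)
            data["reference_region"] = tuple(data["reference_region"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the resolved configuration (carried by all outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
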