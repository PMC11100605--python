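"""Pipeline configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the quantification pipeline.

    Defaults follow the published post-processing constants where they
    exist (3000-px nucleus area floor at a 0.03 um pixel edge, so that
    3000 px corresponds to 2.7 um^2; Tukey fence multiplier 1.5).  The
    remaining parameters are open in the source protocol and must be
    reviewed per dataset; the cell expansion radius in particular is a
    placeholder.
    """

    # --- segmentation post-processing ---
    min_nucleus_area_px: int = 3000
    duplicate_iou_threshold: float = 0.5
    cell_expansion_radius_px: float = 10.0
    watershed_min_distance_px: int = 10

    # --- beta-cell classification ---
    histogram_bin_count: int = 64
    savgol_window_bins: int = 11
    savgol_polyorder: int = 3
    unimodal_fallback: str = "error"  # "error" | "otsu"

    # --- spot detection & deconvolution ---
    log_sigma_min_px: float = 1.0
    log_sigma_max_px: float = 3.0
    log_n_scales: int = 8
    log_threshold: float = 0.2
    aperture_radius_scales: float = 3.0
    background_annulus_px: float = 4.0
    unit_intensity_bin_width: Optional[float] = None  # None -> max/50
    tukey_k: float = 1.5
    count_clamp_min: int = 1

    # --- global ---
    pixel_edge_um: float = 0.03
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_nucleus_area_px < 1:
            raise ValueError("min_nucleus_area_px must be >= 1")
        if not (0 < self.duplicate_iou_threshold <= 1):
            raise ValueError("duplicate_iou_threshold must be in (0, 1]")
        if self.cell_expansion_radius_px < 0:
            raise ValueError("cell_expansion_radius_px must be >= 0")
        if self.savgol_window_bins % 2 != 1:
            raise ValueError("savgol_window_bins must be odd")
        if self.savgol_window_bins <= self.savgol_polyorder:
            raise ValueError("savgol_window_bins must exceed savgol_polyorder")
        if self.unimodal_fallback not in ("error", "otsu"):
            raise ValueError("unimodal_fallback must be 'error' or 'otsu'")
        if not (self.log_sigma_min_px < self.log_sigma_max_px):
            raise ValueError("log_sigma_min_px must be < log_sigma_max_px")
        if self.tukey_k <= 0:
            raise ValueError("tukey_k must be > 0")
        if self.count_clamp_min < 0:
            raise ValueError("count_clamp_min must be >= 0")
        if self.pixel_edge_um <= 0:
            raise ValueError("pixel_edge_um must be > 0")
        if self.unit_intensity_bin_width is not None and self.unit_intensity_bin_width <= 0:
            raise ValueError("unit_intensity_bin_width must be > 0 or None")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file; missing keys fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
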