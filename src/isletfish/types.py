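"""Shared domain types for the quantification pipeline.

All images live in a single coordinate frame: row-major, 0-based, with
pixel centers at integer coordinates.  Sub-pixel focus positions are
continuous in this frame, ``x`` being the column coordinate and ``y``
the row coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "LabelMask",
    "CellRecord",
    "Focus",
    "UnitIntensity",
    "GroupResult",
    "FOCUS_COLUMNS",
    "foci_to_frame",
    "validate_foci",
]


@dataclass
class ImageStack:
    """A calibrated multi-channel 2D fluorescence field.

    Parameters
    ----------
    channels
        Mapping from channel name (``"nucleus"``, ``"insulin"``, gene
        names) to a 2D non-negative intensity array.  All channels must
        share the same height and width.
    pixel_edge_um
        Physical edge length of one pixel in micrometres (> 0).
    field_id
        Free-text identifier for the imaged field.
    """

    channels: Mapping[str, np.ndarray]
    pixel_edge_um: float
    field_id: str = "field"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        if not np.isfinite(self.pixel_edge_um) or self.pixel_edge_um <= 0:
            raise ValueError(f"pixel_edge_um must be > 0, got {self.pixel_edge_um}")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D (ndim={arr.ndim})")
            if not np.isfinite(arr).all():
                raise ValueError(f"channel {name!r} contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} contains negative intensities")
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def gene_names(self) -> list[str]:
        """Channel names other than the nucleus and insulin stains."""
        return [c for c in self.channels if c not in ("nucleus", "insulin")]


@dataclass
class LabelMask:
    """Integer-labeled 2D segmentation; 0 is background.

    ``kind`` distinguishes nucleus masks from (expanded) cell masks.
    """

    labels: np.ndarray
    kind: str = "nucleus"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be >= 0")
        if self.kind not in ("nucleus", "cell"):
            raise ValueError(f"kind must be 'nucleus' or 'cell', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas(self) -> dict[int, int]:
        """Pixel area per positive label."""
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}


@dataclass
class CellRecord:
    """One segmented cell with its insulin measurement and class."""

    cell_id: int
    nucleus_area_px: int
    cell_area_px: int
    insulin_mean_intensity: float
    cell_class: str = "unclassified"

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if self.nucleus_area_px > self.cell_area_px:
            raise ValueError(
                f"nucleus_area_px ({self.nucleus_area_px}) exceeds "
                f"cell_area_px ({self.cell_area_px})"
            )
        if self.insulin_mean_intensity < 0:
            raise ValueError("insulin_mean_intensity must be >= 0")
        if self.cell_class not in ("beta", "non_beta", "unclassified"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")


@dataclass
class Focus:
    """One detected fluorescent focus."""

    focus_id: int
    gene: str
    x: float
    y: float
    intensity: float
    scale: float = float("nan")
    mrna_count: int = 0
    cell_id: Optional[int] = None
    compartment: str = "unassigned"
    outlier: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "cytoplasmic", "unassigned"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.cell_id is not None and self.cell_id <= 0:
            raise ValueError("cell_id must be positive or None")


FOCUS_COLUMNS = [
    "focus_id",
    "gene",
    "x",
    "y",
    "scale",
    "intensity",
    "mrna_count",
    "cell_id",
    "compartment",
    "outlier",
]


def foci_to_frame(foci: list[Focus]) -> pd.DataFrame:
    """Convert a list of :class:`Focus` records to the canonical table."""
    if not foci:
        return pd.DataFrame(columns=FOCUS_COLUMNS)
    rows = [
        {
            "focus_id": f.focus_id,
            "gene": f.gene,
            "x": f.x,
            "y": f.y,
            "scale": f.scale,
            "intensity": f.intensity,
            "mrna_count": f.mrna_count,
            "cell_id": 0 if f.cell_id is None else f.cell_id,
            "compartment": f.compartment,
            "outlier": f.outlier,
        }
        for f in foci
    ]
    return pd.DataFrame(rows, columns=FOCUS_COLUMNS)


def validate_foci(foci: pd.DataFrame, count_clamp_min: int = 1) -> None:
    """Check the focus-table invariants; raise ``ValueError`` on violation.

    Retained foci (non-outlier, assigned to a cell) must carry a
    transcript count of at least ``count_clamp_min``.
    """
    missing = [c for c in FOCUS_COLUMNS if c not in foci.columns]
    if missing:
        raise ValueError(f"focus table missing columns: {missing}")
    if len(foci) == 0:
        return
    retained = (~foci["outlier"].astype(bool)) & (foci["cell_id"] > 0)
    if (foci.loc[retained, "mrna_count"] < count_clamp_min).any():
        raise ValueError("retained focus with mrna_count below count_clamp_min")
    bad = ~foci["compartment"].isin(["nuclear", "cytoplasmic", "unassigned"])
    if bad.any():
        raise ValueError("invalid compartment value in focus table")


@dataclass
class UnitIntensity:
    """Estimated integrated intensity of a single mRNA for one gene."""

    gene: str
    I1: float
    modal_bin: tuple[float, float]
    n_support: int

    def __post_init__(self) -> None:
        if self.I1 <= 0:
            raise ValueError("I1 must be > 0")
        low, high = self.modal_bin
        if not (low <= self.I1 <= high):
            raise ValueError(f"I1={self.I1} outside modal bin [{low}, {high}]")
        if self.n_support < 1:
            raise ValueError("n_support must be >= 1")


@dataclass
class GroupResult:
    """Outcome of one two-group rank comparison."""

    gene: str
    statistic_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U_statistic: float
    p_value: float
    median_a: float
    median_b: float
    method: str = field(default="exact")

    def __post_init__(self) -> None:
        if not (0 <= self.U_statistic <= self.n_a * self.n_b):
            raise ValueError("U outside [0, n_a * n_b]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value outside (0, 1]")
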