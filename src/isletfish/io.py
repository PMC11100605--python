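"""Image and table input/output.

Images are exchanged as TIFF (multi-page or multi-channel); tables as
UTF-8 comma-separated text with a header row, written with a
deterministic column and row order so that identical runs produce
byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CellRecord, FOCUS_COLUMNS, ImageStack, LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "load_image_stack",
    "save_image_stack",
    "load_label_mask",
    "save_label_mask",
    "mask_area_um2",
    "write_tables",
    "write_manifest",
    "cells_to_frame",
]

CELL_COLUMNS = [
    "cell_id",
    "nucleus_area_px",
    "cell_area_px",
    "insulin_mean_intensity",
    "cell_class",
]


def load_image_stack(
    path: str | Path,
    channel_map: Sequence[str],
    pixel_edge_um: float,
    field_id: str | None = None,
) -> ImageStack:
    """Load a multi-plane TIFF and name its planes.

    Planes are taken in page order (axis 0 for a 3D array); planes
    beyond ``channel_map`` are ignored with a logged warning.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file holds fewer planes than ``channel_map`` names, or
        if any plane is not 2D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D planes, got array of ndim {arr.ndim}")
    if arr.shape[0] < len(channel_map):
        raise ValueError(
            f"plane count < channel count: file has {arr.shape[0]} planes, "
            f"channel map names {len(channel_map)}"
        )
    if arr.shape[0] > len(channel_map):
        logger.warning(
            "%s: ignoring %d plane(s) beyond the %d named channels",
            path.name,
            arr.shape[0] - len(channel_map),
            len(channel_map),
        )
    channels = {name: np.asarray(arr[i]) for i, name in enumerate(channel_map)}
    return ImageStack(
        channels=channels,
        pixel_edge_um=pixel_edge_um,
        field_id=field_id if field_id is not None else path.stem,
    )


def save_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF, one page per channel.

    Channel order follows the stack's channel mapping; dtype is
    preserved so a reload is bit-identical.
    """
    planes = np.stack([np.asarray(a) for a in stack.channels.values()])
    tifffile.imwrite(path, planes, photometric="minisblack")


def load_label_mask(path: str | Path, kind: str = "nucleus") -> LabelMask:
    """Read an integer-label TIFF or PNG as a :class:`LabelMask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be 2D, got ndim {arr.ndim}")
    return LabelMask(labels=arr.astype(np.int32), kind=kind)


def save_label_mask(mask: LabelMask, path: str | Path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32))


def mask_area_um2(area_px: float, pixel_edge_um: float) -> float:
    """Convert a pixel area to square micrometres.

    At the default calibration of 0.03 um per pixel edge, 3000 px
    corresponds to 2.7 um^2.
    """
    if area_px < 0:
        raise ValueError("area_px must be >= 0")
    if pixel_edge_um <= 0:
        raise ValueError("pixel_edge_um must be > 0")
    return float(area_px) * pixel_edge_um**2


def cells_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    if not cells:
        return pd.DataFrame(columns=CELL_COLUMNS)
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "nucleus_area_px": c.nucleus_area_px,
                "cell_area_px": c.cell_area_px,
                "insulin_mean_intensity": c.insulin_mean_intensity,
                "cell_class": c.cell_class,
            }
            for c in cells
        ],
        columns=CELL_COLUMNS,
    )


def _counts_from_foci(foci: pd.DataFrame, cell_ids: Sequence[int], genes: Sequence[str]) -> pd.DataFrame:
    """Per-cell per-gene totals with nuclear/cytoplasmic split, recomputed
    from the focus table (retained foci only)."""
    rows = []
    if len(foci):
        retained = foci[(~foci["outlier"].astype(bool)) & (foci["cell_id"] > 0)]
    else:
        retained = foci
    for cid in sorted(cell_ids):
        for gene in genes:
            sub = (
                retained[(retained["cell_id"] == cid) & (retained["gene"] == gene)]
                if len(retained)
                else retained
            )
            nuc = int(sub.loc[sub["compartment"] == "nuclear", "mrna_count"].sum()) if len(sub) else 0
            cyt = int(sub.loc[sub["compartment"] == "cytoplasmic", "mrna_count"].sum()) if len(sub) else 0
            rows.append(
                {
                    "cell_id": cid,
                    "gene": gene,
                    "total": nuc + cyt,
                    "nuclear": nuc,
                    "cytoplasmic": cyt,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "gene", "total", "nuclear", "cytoplasmic"])


def write_tables(
    cells: pd.DataFrame | Sequence[CellRecord],
    foci: pd.DataFrame,
    out_dir: str | Path,
    genes: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write the cell, focus, and per-cell per-gene count tables.

    Rows are sorted (cells by ``cell_id``; foci by ``gene`` then
    ``focus_id``) and columns are in a fixed order, so writing the same
    inputs twice yields byte-identical files.

    Returns a mapping from table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(cells, pd.DataFrame):
        cells = cells_to_frame(cells)
    cells = cells[CELL_COLUMNS].sort_values("cell_id").reset_index(drop=True)
    foci = foci[FOCUS_COLUMNS].sort_values(["gene", "focus_id"]).reset_index(drop=True)
    if genes is None:
        genes = sorted(foci["gene"].unique()) if len(foci) else []
    counts = _counts_from_foci(foci, cells["cell_id"].tolist(), list(genes))

    paths = {
        "cells": out_dir / "cells.csv",
        "foci": out_dir / "foci.csv",
        "counts": out_dir / "counts.csv",
    }
    cells.to_csv(paths["cells"], index=False)
    foci.to_csv(paths["foci"], index=False)
    counts.to_csv(paths["counts"], index=False)
    logger.info(
        "wrote %d cells, %d foci, %d count rows to %s",
        len(cells),
        len(foci),
        len(counts),
        out_dir,
    )
    return paths


def write_manifest(out_dir: str | Path, **entries) -> Path:
    """Write a YAML run manifest (config, seed, library versions)."""
    import scipy
    import skimage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    manifest.update(entries)
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
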