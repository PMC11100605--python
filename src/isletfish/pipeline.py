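"""End-to-end quantification: image stack to per-cell transcript tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import celltype, segment, spots
from .config import PipelineConfig
from .io import cells_to_frame, write_manifest, write_tables
from .types import CellRecord, FOCUS_COLUMNS, ImageStack, LabelMask, UnitIntensity
from .stats import per_cell_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All artifacts of one quantification run."""

    nucleus_mask: LabelMask
    cell_mask: LabelMask
    cells: pd.DataFrame
    foci: pd.DataFrame
    counts: pd.DataFrame
    insulin_threshold: float
    units: dict[str, UnitIntensity]


def run_pipeline(
    stack: ImageStack,
    config: PipelineConfig,
    nucleus_mask: Optional[LabelMask] = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run segmentation, classification, spot counting, and aggregation.

    An externally supplied ``nucleus_mask`` bypasses the built-in
    segmenter but still passes through the duplicate/area filter and
    radial expansion.  With ``out_dir`` set, the cell/focus/count
    tables and a run manifest are written there.
    """
    if "nucleus" not in stack.channels or "insulin" not in stack.channels:
        raise ValueError("stack must contain 'nucleus' and 'insulin' channels")
    genes = stack.gene_names
    if not genes:
        raise ValueError("stack contains no mRNA channels")

    # --- segmentation & geometry ---
    if nucleus_mask is None:
        nucleus_mask = segment.segment_nuclei(stack.channels["nucleus"], config)
    nuclei = segment.filter_masks(
        nucleus_mask, config.min_nucleus_area_px, config.duplicate_iou_threshold
    )
    cells_mask = segment.expand_to_cells(nuclei, config.cell_expansion_radius_px)
    nuc_areas = nuclei.areas()
    cell_areas = cells_mask.areas()

    # --- beta / non-beta classification ---
    intensities = celltype.measure_cell_intensity(cells_mask, stack.channels["insulin"])
    if len(intensities) >= 2:
        threshold = celltype.threshold_from_intensities(
            intensities,
            config.histogram_bin_count,
            config.savgol_window_bins,
            config.savgol_polyorder,
            unimodal_fallback=config.unimodal_fallback,
        )
        classes = celltype.classify_cells(intensities, threshold)
    else:
        threshold = float("nan")
        classes = {cid: "unclassified" for cid in intensities}
    cell_records = [
        CellRecord(
            cell_id=cid,
            nucleus_area_px=nuc_areas.get(cid, 0),
            cell_area_px=cell_areas.get(cid, 0),
            insulin_mean_intensity=intensities[cid],
            cell_class=classes[cid],
        )
        for cid in sorted(intensities)
    ]
    cells_df = cells_to_frame(cell_records)
    n_beta = sum(1 for c in cell_records if c.cell_class == "beta")
    logger.info(
        "classified %d cells: %d beta, %d non-beta (threshold=%.4g)",
        len(cell_records),
        n_beta,
        len(cell_records) - n_beta,
        threshold,
    )

    # --- spot detection, outlier filtering, deconvolution, assignment ---
    all_foci = []
    units: dict[str, UnitIntensity] = {}
    for gene in genes:
        detected = spots.detect_spots(
            stack.channels[gene],
            config.log_sigma_min_px,
            config.log_sigma_max_px,
            config.log_threshold,
            n_scales=config.log_n_scales,
            aperture_radius_scales=config.aperture_radius_scales,
            background_annulus_px=config.background_annulus_px,
        )
        if len(detected) == 0:
            continue
        flagged = spots.tukey_filter(detected, config.tukey_k)
        unit = spots.estimate_unit_intensity(
            flagged, config.unit_intensity_bin_width, gene=gene
        )
        units[gene] = unit
        counted = spots.deconvolve_counts(flagged, unit, clamp_min=config.count_clamp_min)
        assigned = spots.assign_spots(counted, cells_mask, nuclei)
        assigned.insert(1, "gene", gene)
        all_foci.append(assigned)
    if all_foci:
        foci = pd.concat(all_foci, ignore_index=True)
    else:
        foci = pd.DataFrame(columns=FOCUS_COLUMNS)
    foci = foci[FOCUS_COLUMNS]

    counts = per_cell_counts(foci, cells_df)

    result = PipelineResult(
        nucleus_mask=nuclei,
        cell_mask=cells_mask,
        cells=cells_df,
        foci=foci,
        counts=counts,
        insulin_threshold=threshold,
        units=units,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_tables(cells_df, foci, out_dir, genes=genes)
        counts.to_csv(out_dir / "per_cell_counts.csv", index=False)
        write_manifest(
            out_dir,
            config=config.to_dict(),
            field_id=stack.field_id,
            seed=config.random_seed,
            insulin_threshold=None if np.isnan(threshold) else float(threshold),
            unit_intensities={g: float(u.I1) for g, u in units.items()},
        )
    return result
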