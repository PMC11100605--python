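"""mRNA focus detection, intensity deconvolution, and spot assignment.

Foci are detected per mRNA channel with a multi-scale scale-normalized
Laplacian-of-Gaussian (LoG) filter.  Because several mRNAs can overlap
into one bright focus, each focus intensity is divided by the
single-mRNA unit intensity I1 — the median intensity of the modal
intensity bin — to deconvolve the transcript count.  Autofluorescent
outliers are flagged with Tukey's fence on the intensity distribution
before I1 estimation and counting, and each retained focus is assigned
to a cell and to the nuclear or cytoplasmic compartment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import FOCUS_COLUMNS, LabelMask, UnitIntensity

logger = logging.getLogger(__name__)

__all__ = [
    "log_response_cube",
    "detect_spots",
    "estimate_unit_intensity",
    "tukey_filter",
    "deconvolve_counts",
    "assign_spots",
]

DETECT_COLUMNS = ["focus_id", "x", "y", "scale", "response", "intensity"]


def log_response_cube(channel: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Scale-normalized negated LoG responses, one plane per sigma.

    The response at the center of a Gaussian spot of matching sd and
    amplitude A is A/2.
    """
    img = np.asarray(channel, dtype=float)
    return np.stack([-(s**2) * ndi.gaussian_laplace(img, s) for s in sigmas])


def _subpixel_offset(f_minus: float, f0: float, f_plus: float) -> float:
    """One-axis quadratic peak interpolation, clamped to half a pixel."""
    denom = f_minus - 2.0 * f0 + f_plus
    if denom >= 0:
        return 0.0
    off = 0.5 * (f_minus - f_plus) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_spots(
    channel: np.ndarray,
    sigma_min_px: float,
    sigma_max_px: float,
    threshold: float,
    n_scales: int = 8,
    aperture_radius_scales: float = 3.0,
    background_annulus_px: float = 4.0,
) -> pd.DataFrame:
    """Detect diffraction-limited foci in one mRNA channel.

    A focus is a local maximum of the scale-normalized LoG response
    over (row, column, scale) with response above ``threshold``;
    plateaus of tied responses yield one focus (their first voxel in
    scan order).  Position and scale are refined by quadratic
    interpolation.  Focus intensity is the background-subtracted sum
    over a disk of radius ``aperture_radius_scales`` times the refined
    scale (background = median in a surrounding annulus of width
    ``background_annulus_px``), divided by the analytic fraction of a
    Gaussian's mass inside that disk, so it estimates the spot's total
    integrated intensity.

    Returns a table with columns ``focus_id, x, y, scale, response,
    intensity`` sorted by (y, x); deterministic for a fixed input.
    """
    img = np.asarray(channel, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("channel contains non-finite values")
    if sigma_min_px >= sigma_max_px:
        raise ValueError("sigma_min_px must be < sigma_max_px")
    sigmas = np.linspace(sigma_min_px, sigma_max_px, n_scales)
    cube = log_response_cube(img, sigmas)

    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbor_max = ndi.maximum_filter(cube, footprint=footprint, mode="constant", cval=-np.inf)
    candidate = (cube >= neighbor_max) & (cube > threshold)
    # collapse tied plateaus to their first voxel in scan order
    if candidate.any():
        comp, _ = ndi.label(candidate, structure=np.ones((3, 3, 3), dtype=bool))
        ks, rs, cs = np.nonzero(candidate)  # C-order
        _, first = np.unique(comp[ks, rs, cs], return_index=True)
        ks, rs, cs = ks[first], rs[first], cs[first]
    else:
        ks, rs, cs = (np.array([], dtype=int),) * 3

    h, w = img.shape
    # fraction of an isotropic Gaussian's mass inside radius c*sigma
    mass_fraction = 1.0 - np.exp(-0.5 * aperture_radius_scales**2)
    records = []
    for k, r, c in zip(ks, rs, cs):
        resp = cube[k, r, c]
        y = float(r)
        x = float(c)
        if 0 < r < h - 1:
            y += _subpixel_offset(cube[k, r - 1, c], resp, cube[k, r + 1, c])
        if 0 < c < w - 1:
            x += _subpixel_offset(cube[k, r, c - 1], resp, cube[k, r, c + 1])
        scale = float(sigmas[k])
        if 0 < k < len(sigmas) - 1:
            ds = sigmas[1] - sigmas[0]
            scale += ds * _subpixel_offset(cube[k - 1, r, c], resp, cube[k + 1, r, c])
        records.append((x, y, scale, float(resp), r, c))
    records.sort(key=lambda t: (t[1], t[0], t[2]))

    rows = []
    for fid, (x, y, scale, resp, r, c) in enumerate(records, start=1):
        raw = _aperture_intensity(
            img, r, c, aperture_radius_scales * scale, background_annulus_px
        )
        rows.append(
            {
                "focus_id": fid,
                "x": x,
                "y": y,
                "scale": scale,
                "response": resp,
                "intensity": raw / mass_fraction,
            }
        )
    out = pd.DataFrame(rows, columns=DETECT_COLUMNS[:4] + ["response", "intensity"])
    logger.info("detect_spots: %d foci (threshold=%g)", len(out), threshold)
    return out


def _aperture_intensity(
    img: np.ndarray, r: int, c: int, radius: float, annulus_width: float
) -> float:
    """Background-subtracted disk sum around pixel (r, c)."""
    h, w = img.shape
    r_out = radius + annulus_width
    ext = int(np.ceil(r_out))
    r0, r1 = max(0, r - ext), min(h, r + ext + 1)
    c0, c1 = max(0, c - ext), min(w, c + ext + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - r) ** 2 + (xx - c) ** 2
    patch = img[r0:r1, c0:c1]
    disk = d2 <= radius**2
    annulus = (d2 > radius**2) & (d2 <= r_out**2)
    bg = float(np.median(patch[annulus])) if annulus.any() else 0.0
    return float(patch[disk].sum() - disk.sum() * bg)


def estimate_unit_intensity(
    foci: pd.DataFrame, bin_width: float | None, gene: str = ""
) -> UnitIntensity:
    """Estimate the single-mRNA intensity I1 from the focus population.

    Foci are binned into half-open intensity intervals
    ``[i*w, (i+1)*w)`` from zero; the modal bin is the one holding the
    most foci (ties resolve to the lower-intensity bin), and I1 is the
    median intensity of the foci in it.  Outlier-flagged foci are
    ignored.  ``bin_width=None`` uses 1/50 of the maximum intensity.
    """
    if len(foci) and "outlier" in foci.columns:
        foci = foci[~foci["outlier"].astype(bool)]
    inten = np.asarray(foci["intensity"], dtype=float) if len(foci) else np.array([])
    inten = inten[inten > 0]
    if inten.size == 0:
        raise ValueError("no positive-intensity foci to estimate unit intensity from")
    if bin_width is None:
        bin_width = float(inten.max()) / 50.0
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    idx = np.floor(inten / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    modal = int(np.argmax(counts))  # argmax -> first -> lower-intensity bin on ties
    in_modal = inten[idx == modal]
    i1 = float(np.median(in_modal))
    unit = UnitIntensity(
        gene=gene,
        I1=i1,
        modal_bin=(modal * bin_width, (modal + 1) * bin_width),
        n_support=int(in_modal.size),
    )
    logger.info(
        "estimate_unit_intensity[%s]: I1=%.3g from %d foci in bin [%.3g, %.3g)",
        gene,
        i1,
        unit.n_support,
        *unit.modal_bin,
    )
    return unit


def tukey_filter(foci: pd.DataFrame, k: float) -> pd.DataFrame:
    """Flag bright autofluorescent outliers with Tukey's upper fence.

    Q1 and Q3 are the linear-interpolation quartiles of the focus
    intensities; foci with intensity strictly above ``Q3 + k * IQR``
    are flagged.  The lower fence is deliberately not applied — dim
    foci are governed by the detection threshold.
    """
    if len(foci) == 0:
        raise ValueError("tukey_filter requires at least one focus")
    if k <= 0:
        raise ValueError("k must be > 0")
    out = foci.copy()
    inten = np.asarray(out["intensity"], dtype=float)
    q1, q3 = np.percentile(inten, [25, 75], method="linear")
    fence = q3 + k * (q3 - q1)
    out["outlier"] = inten > fence
    logger.info(
        "tukey_filter: flagged %d of %d foci above fence %.3g (Q1=%.3g, Q3=%.3g, k=%g)",
        int(out["outlier"].sum()),
        len(out),
        fence,
        q1,
        q3,
        k,
    )
    return out


def deconvolve_counts(
    foci: pd.DataFrame, unit: UnitIntensity, clamp_min: int = 1
) -> pd.DataFrame:
    """Convert focus intensities to mRNA counts by dividing by I1.

    Counts are rounded half-to-even and clamped below at ``clamp_min``
    (a detected non-outlier focus represents at least one mRNA).
    Outlier foci get a count of 0 and are excluded downstream.
    """
    if unit.I1 <= 0:
        raise ValueError("unit.I1 must be > 0")
    out = foci.copy()
    if "outlier" not in out.columns:
        out["outlier"] = False
    ratio = np.asarray(out["intensity"], dtype=float) / unit.I1
    counts = np.maximum(clamp_min, np.rint(ratio).astype(np.int64))
    counts[np.asarray(out["outlier"], dtype=bool)] = 0
    out["mrna_count"] = counts
    return out


def assign_spots(foci: pd.DataFrame, cells: LabelMask, nuclei: LabelMask) -> pd.DataFrame:
    """Assign each focus to a cell and a subcellular compartment.

    The focus pixel is ``(round(y), round(x))``; its cell is the cell
    label there (0 leaves the focus unassigned and excluded from
    per-cell statistics), and the compartment is nuclear when the
    nucleus label at that pixel matches the cell label, cytoplasmic
    otherwise.
    """
    if cells.shape != nuclei.shape:
        raise ValueError("cell and nucleus masks must share shape")
    out = foci.copy()
    if len(out) == 0:
        out["cell_id"] = pd.Series(dtype=np.int64)
        out["compartment"] = pd.Series(dtype=object)
        return out
    rr = np.rint(np.asarray(out["y"], dtype=float)).astype(np.int64)
    cc = np.rint(np.asarray(out["x"], dtype=float)).astype(np.int64)
    h, w = cells.shape
    if (rr < 0).any() or (rr >= h).any() or (cc < 0).any() or (cc >= w).any():
        raise ValueError("focus coordinates out of image bounds")
    cell_ids = cells.labels[rr, cc].astype(np.int64)
    nuc_ids = nuclei.labels[rr, cc].astype(np.int64)
    compartment = np.where(
        cell_ids == 0,
        "unassigned",
        np.where(nuc_ids == cell_ids, "nuclear", "cytoplasmic"),
    )
    out["cell_id"] = cell_ids
    out["compartment"] = compartment
    return out
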