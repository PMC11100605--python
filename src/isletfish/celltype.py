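"""Beta / non-beta cell classification from insulin intensity.

Per-cell mean insulin intensity is histogrammed, the histogram is
smoothed with a Savitzky-Golay filter, and the local minimum between
the two dominant modes of the smoothed histogram sets the intensity
threshold: cells above it are called beta, cells at or below it
non-beta.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import savgol_filter

from .types import LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "measure_cell_intensity",
    "smooth_histogram",
    "find_threshold",
    "classify_cells",
    "ThresholdError",
]


class ThresholdError(ValueError):
    """Raised when the smoothed histogram has no valley between two modes."""


def measure_cell_intensity(cells: LabelMask, insulin_channel: np.ndarray) -> dict[int, float]:
    """Arithmetic mean insulin intensity over each cell's pixels."""
    img = np.asarray(insulin_channel, dtype=float)
    if img.shape != cells.shape:
        raise ValueError(
            f"shape mismatch: cells {cells.shape} vs insulin channel {img.shape}"
        )
    ids = cells.ids
    if ids.size == 0:
        return {}
    means = ndi.mean(img, labels=cells.labels, index=ids)
    return {int(i): float(m) for i, m in zip(ids, means)}


def smooth_histogram(
    values, bin_count: int, window_bins: int, polyorder: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram ``values`` and Savitzky-Golay-smooth the counts.

    The histogram spans ``[min(values), max(values)]`` with
    ``bin_count`` equal-width bins.  Each smoothed count is the central
    value of the least-squares polynomial of degree ``polyorder``
    fitted over ``window_bins`` consecutive bins; edge windows use the
    polynomial fitted at the boundary evaluated off-center, avoiding
    artificial boundary minima.

    Returns ``(bin_centers, smoothed_counts)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("need at least 2 distinct values to histogram")
    if window_bins % 2 != 1 or window_bins <= polyorder:
        raise ValueError("window_bins must be odd and greater than polyorder")
    if window_bins > bin_count:
        raise ValueError(
            f"window ({window_bins} bins) larger than histogram ({bin_count} bins)"
        )
    counts, edges = np.histogram(values, bins=bin_count)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = savgol_filter(
        counts.astype(float), window_length=window_bins, polyorder=polyorder, mode="interp"
    )
    return centers, smoothed


def _local_max_runs(s: np.ndarray) -> list[int]:
    """First index of every plateau that is a strict local maximum,
    boundaries compared one-sided."""
    n = s.size
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left_ok = i == 0 or s[i - 1] < s[i]
        right_ok = j == n - 1 or s[j + 1] < s[i]
        if left_ok and right_ok:
            maxima.append(i)
        i = j + 1
    return maxima


def _prominence(s: np.ndarray, m: int) -> float:
    """Topographic prominence of the local maximum at index ``m``:
    height above the higher of the two bases (the minimum between the
    peak and the nearest higher point, or the signal edge, per side)."""
    v = s[m]
    bases = []
    for step in (-1, 1):
        i = m + step
        side_min = None
        while 0 <= i < s.size:
            side_min = min(side_min, s[i]) if side_min is not None else s[i]
            if s[i] > v:
                break
            i += step
        if side_min is not None:
            bases.append(side_min)
    return float(v - max(bases)) if bases else float(v)


def find_threshold(
    bin_centers: np.ndarray,
    smoothed_counts: np.ndarray,
    min_prominence_frac: float = 0.05,
) -> float:
    """Locate the valley between the two dominant modes.

    Negative smoothed counts (a Savitzky-Golay artifact at sharp
    edges) are clipped to zero first.  Local maxima whose topographic
    prominence is below ``min_prominence_frac`` of the histogram
    maximum are discarded as smoothing ripples; of the rest, the two
    with the highest counts are the modes, and the bin center of the
    lowest count strictly between them is returned (ties resolve to
    the lower intensity).

    Raises
    ------
    ThresholdError
        If the smoothed histogram is unimodal (fewer than two
        prominent local maxima, or no bin strictly between the modes).
    """
    s = np.clip(np.asarray(smoothed_counts, dtype=float), 0, None)
    centers = np.asarray(bin_centers, dtype=float)
    if s.size != centers.size:
        raise ValueError("bin_centers and smoothed_counts must have equal length")
    floor = min_prominence_frac * s.max()
    maxima = [m for m in _local_max_runs(s) if _prominence(s, m) >= floor]
    if len(maxima) < 2:
        raise ThresholdError(
            f"smoothed histogram is unimodal ({len(maxima)} prominent local "
            "maximum); no beta/non-beta separation found"
        )
    # two highest modes; ties -> lower index
    order = sorted(maxima, key=lambda i: (-s[i], i))
    m1, m2 = sorted(order[:2])
    if m2 - m1 < 2:
        raise ThresholdError("dominant modes are adjacent; no bin between them")
    between = s[m1 + 1 : m2]
    k = int(np.argmin(between)) + m1 + 1  # argmin returns first -> lower intensity
    return float(centers[k])


def classify_cells(intensities: dict[int, float], threshold: float) -> dict[int, str]:
    """Cells above ``threshold`` are beta; at or below it, non-beta."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return {
        cid: ("beta" if v > threshold else "non_beta") for cid, v in intensities.items()
    }


def threshold_from_intensities(
    intensities: dict[int, float],
    bin_count: int,
    window_bins: int,
    polyorder: int,
    unimodal_fallback: str = "error",
) -> float:
    """Full threshold pipeline on a per-cell intensity mapping.

    ``unimodal_fallback="otsu"`` substitutes an Otsu threshold (with a
    logged warning) when the smoothed histogram has no valley.
    """
    values = np.array(list(intensities.values()), dtype=float)
    try:
        centers, smoothed = smooth_histogram(values, bin_count, window_bins, polyorder)
        return find_threshold(centers, smoothed)
    except ThresholdError:
        if unimodal_fallback == "otsu":
            from skimage.filters import threshold_otsu

            logger.warning("unimodal insulin histogram; falling back to Otsu threshold")
            return float(threshold_otsu(values))
        raise
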