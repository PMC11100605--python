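"""Nucleus segmentation, mask cleanup, and cell-boundary prediction.

The built-in segmenter is a classical fallback (Otsu threshold plus
distance-transform watershed); externally produced label masks are
accepted everywhere a nucleus mask is consumed and bypass it entirely.
Downstream post-processing — duplicate removal, the 3000-pixel area
floor, and radial expansion of the nuclear boundary into a predicted
cell boundary — is independent of the mask source.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .config import PipelineConfig
from .types import LabelMask

logger = logging.getLogger(__name__)

__all__ = ["segment_nuclei", "filter_masks", "expand_to_cells", "masks_to_list"]


def segment_nuclei(nucleus_channel: np.ndarray, params: PipelineConfig) -> LabelMask:
    """Segment nuclei from the DAPI channel by threshold + watershed.

    Foreground is the Otsu-thresholded smoothed channel; touching
    nuclei are split by marker-based watershed on the Euclidean
    distance transform.  Deterministic for a fixed input.  An all-zero
    (or constant) image yields an empty mask rather than an error.
    """
    img = np.asarray(nucleus_channel, dtype=float)
    if not np.isfinite(img).all() or (img < 0).any():
        raise ValueError("nucleus channel must be finite and non-negative")
    if img.max() == img.min():
        return LabelMask(labels=np.zeros(img.shape, dtype=np.int32), kind="nucleus")
    smoothed = gaussian(img, sigma=1, preserve_range=True)
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    fg = ndi.binary_fill_holes(fg)
    # drop specks far below any plausible nucleus before watershed
    floor = max(16, params.min_nucleus_area_px // 50)
    pre = cc_label(fg, connectivity=2)
    sizes = np.bincount(pre.ravel())
    small = sizes < floor
    small[0] = False
    fg[small[pre]] = False
    if not fg.any():
        return LabelMask(labels=np.zeros(img.shape, dtype=np.int32), kind="nucleus")
    dist = ndi.distance_transform_edt(fg)
    peak_coords = peak_local_max(
        dist,
        min_distance=params.watershed_min_distance_px,
        labels=cc_label(fg, connectivity=2),
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peak_coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(fg, connectivity=2).astype(np.int32)
    else:
        labels = watershed(-dist, markers=markers, mask=fg).astype(np.int32)
    labels = _renumber(labels)
    logger.info("segment_nuclei: %d candidate nuclei", labels.max())
    return LabelMask(labels=labels, kind="nucleus")


def masks_to_list(nuclei: LabelMask | Sequence[np.ndarray]) -> list[np.ndarray]:
    """Normalize a label array or a sequence of binary masks to a list
    of boolean masks, ordered by label id / sequence position.

    The list form can represent overlapping (duplicate) masks, which a
    single label image cannot.
    """
    if isinstance(nuclei, LabelMask):
        return [nuclei.labels == lab for lab in nuclei.ids]
    out = []
    for m in nuclei:
        m = np.asarray(m)
        if m.dtype != bool:
            m = m > 0
        out.append(m)
    return out


def filter_masks(
    nuclei: LabelMask | Sequence[np.ndarray],
    min_area_px: int,
    duplicate_iou_threshold: float,
) -> LabelMask:
    """Remove undersized and duplicate nucleus masks.

    Masks with area strictly below ``min_area_px`` are removed (a
    3000-px object survives a 3000-px floor; a 2999-px one does not).
    Of any pair with IoU >= ``duplicate_iou_threshold`` the
    smaller-area mask is removed; on an exact area tie the
    earlier-numbered mask is kept.  Survivors are renumbered
    consecutively from 1, preserving their original order.

    Accepts either a :class:`LabelMask` or a sequence of boolean masks
    (the latter can hold overlapping duplicates, e.g. from an external
    segmenter).
    """
    if isinstance(nuclei, LabelMask):
        shape = nuclei.labels.shape
        crops = []
        slices = ndi.find_objects(nuclei.labels)
        for lab in nuclei.ids:
            sl = slices[int(lab) - 1]
            if sl is None:
                continue
            crops.append((sl[0].start, sl[1].start, nuclei.labels[sl] == lab))
    else:
        crops = []
        shape = None
        for m in nuclei:
            m = np.asarray(m)
            if m.dtype != bool:
                m = m > 0
            shape = m.shape
            rows = np.flatnonzero(m.any(axis=1))
            if rows.size == 0:
                crops.append((0, 0, np.zeros((0, 0), dtype=bool)))
                continue
            cols = np.flatnonzero(m.any(axis=0))
            r0, r1 = rows[0], rows[-1] + 1
            c0, c1 = cols[0], cols[-1] + 1
            crops.append((r0, c0, m[r0:r1, c0:c1]))
        if shape is None:
            return LabelMask(labels=np.zeros((0, 0), dtype=np.int32), kind="nucleus")
    if not crops:
        return LabelMask(labels=np.zeros(shape, dtype=np.int32), kind="nucleus")

    areas = [int(m.sum()) for _, _, m in crops]
    keep = [a >= min_area_px for a in areas]

    def _intersection(i: int, j: int) -> int:
        ri, ci, mi = crops[i]
        rj, cj, mj = crops[j]
        r0 = max(ri, rj)
        c0 = max(ci, cj)
        r1 = min(ri + mi.shape[0], rj + mj.shape[0])
        c1 = min(ci + mi.shape[1], cj + mj.shape[1])
        if r0 >= r1 or c0 >= c1:
            return 0
        a = mi[r0 - ri : r1 - ri, c0 - ci : c1 - ci]
        b = mj[r0 - rj : r1 - rj, c0 - cj : c1 - cj]
        return int(np.logical_and(a, b).sum())

    # duplicate removal among survivors of the area filter
    idx = [i for i, k in enumerate(keep) if k]
    for ai in range(len(idx)):
        i = idx[ai]
        if not keep[i]:
            continue
        for aj in range(ai + 1, len(idx)):
            j = idx[aj]
            if not keep[j]:
                continue
            inter = _intersection(i, j)
            if inter == 0:
                continue
            union = areas[i] + areas[j] - inter
            if union > 0 and inter / union >= duplicate_iou_threshold:
                # drop the smaller; tie -> keep the lower-numbered mask
                drop = i if areas[i] < areas[j] else j
                keep[drop] = False
                if drop == i:
                    break

    labels = np.zeros(shape, dtype=np.int32)
    new_id = 0
    for i, (r0, c0, m) in enumerate(crops):
        if keep[i]:
            new_id += 1
            labels[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]][m] = new_id
    logger.info(
        "filter_masks: kept %d of %d masks (min_area=%d, iou>=%.2f)",
        new_id,
        len(crops),
        min_area_px,
        duplicate_iou_threshold,
    )
    return LabelMask(labels=labels, kind="nucleus")


def expand_to_cells(nuclei: LabelMask, radius_px: float) -> LabelMask:
    """Extend each nuclear boundary radially to predict the cell boundary.

    Every background pixel within Euclidean distance <= ``radius_px``
    of some nucleus pixel is assigned the label of the nearest nucleus;
    equidistant pixels go to the lower label id.  Nucleus pixels keep
    their own label, so each nucleus is a subset of its cell.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    labels = nuclei.labels
    ids = nuclei.ids
    if ids.size == 0:
        return LabelMask(labels=labels.copy(), kind="cell")

    # Exact squared distances per label, computed on a bounding box
    # padded by the radius (a label cannot claim pixels farther away).
    # The running strict-< update over increasing label ids makes
    # equidistant ties resolve to the lowest label id.
    h, w = labels.shape
    pad = int(np.ceil(radius_px)) + 1
    best_d2 = np.full(labels.shape, np.iinfo(np.int64).max, dtype=np.int64)
    best_lab = np.zeros(labels.shape, dtype=np.int32)
    slices = ndi.find_objects(labels)
    for lab in ids:
        sl = slices[int(lab) - 1]
        if sl is None:
            continue
        r0 = max(0, sl[0].start - pad)
        r1 = min(h, sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(w, sl[1].stop + pad)
        crop = labels[r0:r1, c0:c1]
        d = ndi.distance_transform_edt(crop != lab)
        d2 = np.rint(d * d).astype(np.int64)
        view_d2 = best_d2[r0:r1, c0:c1]
        view_lab = best_lab[r0:r1, c0:c1]
        closer = d2 < view_d2
        view_d2[closer] = d2[closer]
        view_lab[closer] = lab

    r2 = int(np.floor(radius_px * radius_px + 1e-9))
    out = np.where(best_d2 <= r2, best_lab, 0).astype(np.int32)
    out[labels > 0] = labels[labels > 0]
    return LabelMask(labels=out, kind="cell")


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel positive ids consecutively from 1, preserving order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels]
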