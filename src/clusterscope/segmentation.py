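"""Cell and nucleus segmentation from maximum-intensity projections.

Cells are found on the smoothed max projection by Otsu thresholding, hole
filling, small-object removal and watershed splitting seeded by local maxima
at least 40 px apart.  Within each cell the nucleus is the region above an
Otsu threshold computed on the brightest 75% of that cell's nonzero pixels.

Degenerate inputs (constant or empty images, cells too small to threshold)
yield empty masks with flags rather than errors, replacing the manual mask
curation of interactive workflows with auditable QC flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as skseg

logger = logging.getLogger(__name__)

__all__ = ["LabelMask", "segment_cells", "segment_nuclei", "cell_table"]


@dataclass
class LabelMask:
    """2D integer label image (0 = background).

    ``kind`` is "cell" or "nucleus"; for nuclei, ``parent`` maps each nucleus
    label to its cell label.  ``flags`` records per-label QC notes.
    """

    labels: np.ndarray
    kind: str = "cell"
    parent: dict[int, int] = field(default_factory=dict)
    flags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def label_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


def _project(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 3:
        return stack.max(axis=0)
    if stack.ndim == 2:
        return stack
    raise ValueError("expected a 2D image or 3D z-stack")


def _otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold over the observed range with a fixed bin count."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0 or values.min() == values.max():
        raise ValueError("degenerate intensity distribution")
    return float(filters.threshold_otsu(values, nbins=nbins))


def _select_seeds(image: np.ndarray, mask: np.ndarray, min_distance: int) -> np.ndarray:
    """Local maxima of ``image`` inside ``mask``, greedily thinned so kept
    maxima are >= min_distance apart.

    Candidates are ordered by (-intensity, y, x): among equal-intensity maxima
    within min_distance, the one with smaller (y, x) wins — deterministic.
    """
    maxfilt = ndimage.maximum_filter(image, size=3, mode="nearest")
    cand = np.argwhere((image >= maxfilt) & mask)
    if cand.size == 0:
        return np.empty((0, 2), dtype=int)
    vals = image[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -vals))
    cand = cand[order]
    kept: list[np.ndarray] = []
    md2 = float(min_distance) ** 2
    for p in cand:
        if all(((p - q) ** 2).sum() >= md2 for q in kept):
            kept.append(p)
    return np.array(kept, dtype=int)


def segment_cells(stack: np.ndarray, smooth_sigma: float = 2.5,
                  min_area: int = 200, seed_min_distance: int = 40) -> LabelMask:
    """Segment cells on the max-intensity projection of a single-channel stack.

    Pipeline: max z-projection -> Gaussian smooth (sigma 2.5 px) -> Otsu
    threshold (256 bins) -> fill holes -> remove objects below ``min_area``
    px -> watershed split seeded by local maxima >= ``seed_min_distance``
    px apart.
    """
    image = _project(stack)
    smoothed = ndimage.gaussian_filter(image, smooth_sigma)
    try:
        thr = _otsu(smoothed)
    except ValueError:
        logger.warning("constant or empty image: returning empty cell mask")
        return LabelMask(np.zeros(image.shape, dtype=np.int32), kind="cell",
                         flags={0: "degenerate_image"})
    mask = smoothed > thr
    mask = ndimage.binary_fill_holes(mask)
    # remove features smaller than min_area px (max_size is inclusive)
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        logger.warning("no features above threshold: empty cell mask")
        return LabelMask(np.zeros(image.shape, dtype=np.int32), kind="cell")

    seeds = _select_seeds(smoothed, mask, seed_min_distance)
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = i
    if len(seeds) == 0:
        labels, _ = ndimage.label(mask)
        return LabelMask(labels.astype(np.int32), kind="cell")
    labels = skseg.watershed(-smoothed, markers=markers, mask=mask,
                             connectivity=1)
    labels, _, _ = skseg.relabel_sequential(labels)
    return LabelMask(labels.astype(np.int32), kind="cell")


def segment_nuclei(stack: np.ndarray, cells: LabelMask,
                   min_cell_pixels: int = 50) -> LabelMask:
    """Per-cell nucleus segmentation on the projected intensities.

    For each cell: take its projected pixel intensities, keep the brightest
    75% of the nonzero values, Otsu-threshold that subset; the nucleus is the
    largest connected component above the threshold.  Cells that are too
    small or have a degenerate intensity distribution get no nucleus and a
    flag.
    """
    image = _project(stack)
    nuclei = np.zeros_like(cells.labels, dtype=np.int32)
    parent: dict[int, int] = {}
    flags: dict[int, str] = {}
    for lab in cells.label_ids():
        sel = cells.labels == lab
        if sel.sum() < min_cell_pixels:
            flags[int(lab)] = "cell_too_small"
            continue
        vals = image[sel]
        vals = vals[vals > 0]
        if vals.size < 4:
            flags[int(lab)] = "no_nonzero_pixels"
            continue
        cut = np.quantile(vals, 0.25)
        bright = vals[vals >= cut]
        try:
            thr = _otsu(bright)
        except ValueError:
            flags[int(lab)] = "degenerate_intensity"
            continue
        region = sel & (image > thr)
        if not region.any():
            flags[int(lab)] = "empty_nucleus"
            continue
        comp, n = ndimage.label(region)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, n + 1))
            region = comp == (1 + int(np.argmax(sizes)))
        nuclei[region] = lab
        parent[int(lab)] = int(lab)
    return LabelMask(nuclei, kind="nucleus", parent=parent, flags=flags)


def cell_table(cells: LabelMask) -> pd.DataFrame:
    """Per-cell summary (label, area, centroid, flags) for CSV export."""
    rows = []
    for region in measure.regionprops(cells.labels):
        rows.append(dict(label=region.label, area=region.area,
                         centroid_y=region.centroid[0],
                         centroid_x=region.centroid[1],
                         flag=cells.flags.get(region.label, "")))
    return pd.DataFrame(rows, columns=["label", "area", "centroid_y",
                                       "centroid_x", "flag"])
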