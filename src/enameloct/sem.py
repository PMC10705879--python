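"""Segmentation of SEM micrographs of demineralized enamel.

The five-step pipeline produces the reference labels used to calibrate the
OCT colormap: (1) normalize to the maximum intensity and remove the
background with a multi-level Otsu threshold, (2) take the first non-zero
pixel per column as the enamel surface, (3) isolate fine bright structure
(the demineralized area, Ia + Ie, plus cracks) as the binarized top-hat
residual of a grayscale opening with a 10-pixel-diameter disk, (4) find the
Intra-prismatic (Ia) zone by a 10x10-pixel census of pixels in an
automatically selected quantized intensity interval (the second-highest
peak of a 10-bin histogram), a window counting if it holds more than 25
such pixels, and (5) find the Inter-prismatic (Ie) zone as strong Sobel
edges (after small-object removal) inside the demineralized mask.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import filters, morphology

from .io import LABEL_AIR, LABEL_IA, LABEL_IE, LABEL_SOUND

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised for images that cannot be normalized (constant intensity)."""


class CalibrationError(ValueError):
    """Raised when the quantized histogram has no usable second peak."""


@dataclass
class SEMLabelMap:
    """Zone labels of a segmented SEM frame plus per-column landmarks.

    ``surface_row`` is the first tissue row per column; the interfaces are
    the last Ia row (Ia/Ie interface) and last Ie row (Ie/sound interface)
    per column, -1 where undefined.
    """

    labels: np.ndarray
    surface_row: np.ndarray
    ia_ie_interface: np.ndarray
    ie_sound_interface: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _first_nonzero_rows(mask: np.ndarray) -> np.ndarray:
    has = mask.any(axis=0)
    return np.where(has, mask.argmax(axis=0), -1)


def interfaces_from_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column surface row, last Ia row and last Ie row of a label map."""
    labels = np.asarray(labels)
    n_rows = labels.shape[0]
    row_idx = np.arange(n_rows)[:, None]
    surface = _first_nonzero_rows(labels != LABEL_AIR)
    last_ia = np.where(labels == LABEL_IA, row_idx, -1).max(axis=0)
    last_ie = np.where(labels == LABEL_IE, row_idx, -1).max(axis=0)
    return surface, last_ia, last_ie


def sem_normalize_clean(
    frame: np.ndarray, classes: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize to the maximum intensity and blank the background class.

    Multi-level Otsu with ``classes`` levels is applied to the normalized
    image and the lowest class (background) is set to 0.  Returns the
    cleaned image in [0, 1] and the per-column surface row (-1 where the
    column is entirely background).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.max() <= frame.min():
        raise NormalizationError("constant image cannot be normalized")
    norm = frame / frame.max()
    thresholds = filters.threshold_multiotsu(norm, classes=classes)
    cleaned = norm.copy()
    cleaned[norm <= thresholds[0]] = 0.0
    surface = _first_nonzero_rows(cleaned > 0)
    return cleaned, surface


def sem_demineralized_mask(
    normalized: np.ndarray, disk_diameter: int = 10
) -> np.ndarray:
    """Binary mask of the demineralized area (Ia + Ie plus cracks/noise).

    Top-hat residual: the grayscale opening with a disk of the given
    diameter is subtracted from the image (isolating bright structure finer
    than the disk) and the residual is binarized with Otsu's threshold on
    its non-zero values.
    """
    normalized = np.asarray(normalized, dtype=float)
    footprint = morphology.disk(disk_diameter // 2)
    opened = morphology.opening(normalized, footprint)
    residual = normalized - opened  # opening is anti-extensive: >= 0
    positive = residual[residual > 0]
    if positive.size == 0:
        return np.zeros(normalized.shape, dtype=bool)
    if positive.min() == positive.max():
        # constant residual (e.g. isolated specks of one amplitude): all of
        # it is structure
        return residual > 0
    return residual > filters.threshold_otsu(positive)


def sem_intra_mask(
    normalized: np.ndarray,
    tile: int = 10,
    min_count: int = 25,
    n_bins: int = 10,
) -> np.ndarray:
    """Binary Ia mask by a tiled census of an auto-selected intensity band.

    The tissue intensities (non-zero pixels) are histogrammed into
    ``n_bins`` equal intervals of one tenth of the maximum intensity; the
    target interval is the bin with the second-highest count.  The frame is
    tiled into non-overlapping ``tile x tile`` windows and a window is kept
    when it holds more than ``min_count`` pixels inside the target
    interval.
    """
    normalized = np.asarray(normalized, dtype=float)
    tissue_vals = normalized[normalized > 0]
    if tissue_vals.size == 0:
        raise CalibrationError("no tissue pixels")
    top = float(tissue_vals.max())
    edges = np.linspace(0.0, top, n_bins + 1)
    counts, _ = np.histogram(tissue_vals, bins=edges)
    if np.count_nonzero(counts) < 2:
        raise CalibrationError(
            "quantized histogram has no second peak (uniform tissue)"
        )
    order = np.argsort(counts)[::-1]
    target = order[1]
    lo, hi = edges[target], edges[target + 1]
    if target == n_bins - 1:
        in_band = (normalized >= lo) & (normalized <= hi)
    else:
        in_band = (normalized >= lo) & (normalized < hi)
    mask = np.zeros(normalized.shape, dtype=bool)
    n_rows, n_cols = normalized.shape
    for r0 in range(0, n_rows, tile):
        for c0 in range(0, n_cols, tile):
            window = in_band[r0:r0 + tile, c0:c0 + tile]
            if int(window.sum()) > min_count:
                mask[r0:r0 + tile, c0:c0 + tile] = True
    return mask


def sem_inter_mask(
    normalized: np.ndarray,
    demin_mask: np.ndarray,
    ia_mask: np.ndarray | None = None,
    min_object_px: int = 30,
) -> np.ndarray:
    """Binary Ie mask: strong Sobel edges inside the demineralized area.

    Edge strength is binarized with Otsu's threshold, connected components
    smaller than ``min_object_px`` are removed as noise, and the result is
    intersected with the demineralized mask (and cleared of Ia pixels when
    an Ia mask is supplied).
    """
    normalized = np.asarray(normalized, dtype=float)
    edges = filters.sobel(normalized)
    if edges.max() <= edges.min():
        return np.zeros(normalized.shape, dtype=bool)
    strong = edges > filters.threshold_otsu(edges)
    strong = morphology.remove_small_objects(strong, max_size=min_object_px - 1)
    ie = strong & np.asarray(demin_mask, dtype=bool)
    if ia_mask is not None:
        ie &= ~np.asarray(ia_mask, dtype=bool)
    return ie


def sem_compose(
    normalized: np.ndarray,
    ia_mask: np.ndarray,
    ie_mask: np.ndarray,
) -> SEMLabelMap:
    """Compose the masks into a full label map with precedence Ia > Ie > sound.

    Tissue (non-zero normalized pixels) outside both masks is sound;
    everything else is background.  Per-column interface rows are the last
    Ia and last Ie rows.
    """
    normalized = np.asarray(normalized, dtype=float)
    tissue = normalized > 0
    labels = np.full(normalized.shape, LABEL_AIR, dtype=int)
    labels[tissue] = LABEL_SOUND
    labels[tissue & np.asarray(ie_mask, dtype=bool)] = LABEL_IE
    labels[tissue & np.asarray(ia_mask, dtype=bool)] = LABEL_IA
    surface, last_ia, last_ie = interfaces_from_labels(labels)
    return SEMLabelMap(
        labels=labels,
        surface_row=surface,
        ia_ie_interface=last_ia,
        ie_sound_interface=last_ie,
    )


def sem_segment(
    frame: np.ndarray,
    tile: int = 10,
    min_count: int = 25,
    disk_diameter: int = 10,
    min_object_px: int = 30,
) -> SEMLabelMap:
    """Full five-step SEM segmentation of a raw grayscale micrograph."""
    normalized, _ = sem_normalize_clean(frame)
    demin = sem_demineralized_mask(normalized, disk_diameter=disk_diameter)
    ia = sem_intra_mask(normalized, tile=tile, min_count=min_count)
    ie = sem_inter_mask(normalized, demin, ia_mask=ia,
                        min_object_px=min_object_px)
    return sem_compose(normalized, ia, ie)
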