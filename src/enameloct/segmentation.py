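"""Background removal, enamel-surface detection and zone labeling of OCT
B-scans.

The pipeline mirrors the global-threshold + quantized-intensity-threshold
strategy: air is removed with a fixed dB threshold, the first remaining
pixel of every A-scan is the enamel surface, and sub-surface pixels are
labeled sound / Ie / Ia by the calibrated colormap intervals.  No speckle
denoising is applied before segmentation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import (
    BScan,
    ColorMap,
    LABEL_AIR,
    LABEL_IA,
    LABEL_IE,
    LABEL_SOUND,
)

log = logging.getLogger(__name__)

ABSENT = -1  # marker for columns without a detected surface


class NoTissueError(ValueError):
    """Raised when no column of the frame contains a surface."""


class ContractError(ValueError):
    """Raised when inputs of one operation come from inconsistent frames."""


@dataclass
class SurfaceProfile:
    """Per-column axial index of the detected enamel surface.

    ``surface_row[j]`` is the smallest axial index of tissue in column ``j``
    or :data:`ABSENT` where the column holds no tissue.
    """

    surface_row: np.ndarray

    def __post_init__(self) -> None:
        self.surface_row = np.asarray(self.surface_row, dtype=int)

    @property
    def valid(self) -> np.ndarray:
        return self.surface_row != ABSENT

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @property
    def width(self) -> int:
        return self.surface_row.size


@dataclass
class ZoneLimits:
    """Per-column deepest-pixel counts of each demineralization zone.

    ``delta_ia[j]`` (``delta_ie[j]``) is the pixel count from the surface
    row down to the deepest Ia (Ie) pixel of column ``j``, inclusive; 0 if
    the zone is absent in the column.  ``valid`` marks columns that carry a
    surface at all.
    """

    delta_ia: np.ndarray
    delta_ie: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.delta_ia = np.asarray(self.delta_ia, dtype=int)
        self.delta_ie = np.asarray(self.delta_ie, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


def remove_background(frame: BScan, threshold_db: float | None = None) -> BScan:
    """Zero out background: pixels at or below the air threshold become 0.

    The default threshold is the frame-independent 5 dB air maximum.  The
    operation is idempotent; 0 is reserved as the background marker.
    """
    if threshold_db is None:
        threshold_db = 5.0
    if not np.isfinite(threshold_db):
        raise ValueError("background threshold must be finite")
    values = frame.intensity_db.copy()
    values[values <= threshold_db] = 0.0
    return frame.with_values(values)


def detect_surface(frame: BScan) -> SurfaceProfile:
    """Locate the first non-zero pixel of every A-scan as the enamel surface.

    ``frame`` must be background-removed.  Columns with no non-zero pixel
    are marked absent; if every column is absent a :class:`NoTissueError`
    is raised.
    """
    tissue = frame.intensity_db > 0
    has_tissue = tissue.any(axis=0)
    rows = np.where(has_tissue, tissue.argmax(axis=0), ABSENT)
    profile = SurfaceProfile(rows)
    if profile.n_valid == 0:
        raise NoTissueError("no tissue detected in any column")
    return profile


def label_zones(frame: BScan, surface: SurfaceProfile, cmap: ColorMap) -> np.ndarray:
    """Label every pixel air / sound / Ie / Ia by the colormap intervals.

    Pixels above the surface row (and whole absent columns) are air.  At or
    below the surface the partition is exhaustive: Ia for intensities at or
    above the Ia floor (values past the Ia ceiling are specular glare and
    are clamped into Ia with a logged count), Ie inside the Ie interval,
    sound otherwise.
    """
    if surface.width != frame.shape[1]:
        raise ContractError(
            f"surface width {surface.width} != frame width {frame.shape[1]}"
        )
    db = frame.intensity_db
    n_rows = db.shape[0]
    row_idx = np.arange(n_rows)[:, None]
    below = (surface.surface_row[None, :] != ABSENT) & (
        row_idx >= surface.surface_row[None, :]
    )
    labels = np.full(db.shape, LABEL_AIR, dtype=int)
    labels[below] = LABEL_SOUND
    labels[below & (db >= cmap.ie_range[0]) & (db < cmap.ie_range[1])] = LABEL_IE
    labels[below & (db >= cmap.ia_range[0])] = LABEL_IA
    n_glare = int(np.count_nonzero(below & (db > cmap.ia_range[1])))
    if n_glare:
        log.info("clamped %d pixels above %.1f dB into Ia", n_glare, cmap.ia_range[1])
    return labels


def zone_limits(labels: np.ndarray, surface: SurfaceProfile) -> ZoneLimits:
    """Deepest-pixel counts of the Ia and Ie zones per A-line.

    For each column with a surface, the zone limit is the axial pixel count
    from the surface row to the deepest pixel carrying that zone label
    (inclusive); 0 where the zone is absent.
    """
    labels = np.asarray(labels)
    if surface.width != labels.shape[1]:
        raise ContractError(
            f"surface width {surface.width} != label width {labels.shape[1]}"
        )
    n_rows, n_cols = labels.shape
    row_idx = np.arange(n_rows)[:, None]
    delta = {}
    for name, lab in (("ia", LABEL_IA), ("ie", LABEL_IE)):
        is_zone = labels == lab
        deepest = np.where(is_zone, row_idx, -1).max(axis=0)
        d = deepest - surface.surface_row + 1
        d[(deepest < 0) | ~surface.valid] = 0
        delta[name] = d
    return ZoneLimits(delta["ia"], delta["ie"], surface.valid.copy())


def segment_frame(
    frame: BScan,
    cmap: ColorMap,
    background_db: float | None = None,
) -> tuple[BScan, SurfaceProfile, np.ndarray, ZoneLimits]:
    """Full segmentation of one raw frame.

    Returns the background-removed frame, the surface profile, the zone
    label map and the per-column zone limits.
    """
    clean = remove_background(frame, background_db)
    surface = detect_surface(clean)
    labels = label_zones(clean, surface, cmap)
    limits = zone_limits(labels, surface)
    return clean, surface, labels, limits
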